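"""Functional-connectivity graph construction.

The connectome representation used throughout the package: per-subject
Fisher-z connectivity matrices, harmonization by site regression, the shared
population K-NN graph built from training-fold mean connectivity, and the
renormalized adjacency operator of a first-order graph convolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeries",
    "ConnectivityMatrix",
    "SubjectRecord",
    "MultiSiteDataset",
    "KnnGraph",
    "NormalizedAdjacency",
    "pearson_fisher_connectivity",
    "regress_out_site",
    "mean_connectivity",
    "build_knn_graph",
    "normalize_adjacency",
    "node_features",
]

#: |r| is clipped here before atanh so self- or duplicate-signal correlations
#: stay finite; artifactual |r| > 1 values are assumed excluded upstream.
R_CLIP = 0.999999

SYMMETRY_TOL = 1e-10

LABELS = ("patient", "control")


@dataclass
class TimeSeries:
    """ROI time series for one subject: ``values`` is T x N (timepoints x ROIs)."""

    values: np.ndarray
    roi_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D (T x N) array")
        t, n = self.values.shape
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if n < 2:
            raise ValueError(f"need at least 2 ROIs, got {n}")
        if len(self.roi_ids) != n:
            raise ValueError("roi_ids length must match number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Fisher-z functional connectivity: symmetric N x N, zero diagonal."""

    z: np.ndarray
    roi_ids: list[str]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.shape != (n, n):
            raise ValueError("connectivity must be square")
        if len(self.roi_ids) != n:
            raise ValueError("roi_ids length must match matrix size")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("connectivity contains non-finite values")
        if np.max(np.abs(self.z - self.z.T)) > SYMMETRY_TOL:
            raise ValueError("connectivity matrix is not symmetric")
        if np.any(np.diag(self.z) != 0.0):
            raise ValueError("connectivity diagonal must be exactly 0")

    @property
    def n_rois(self) -> int:
        return self.z.shape[0]


@dataclass
class SubjectRecord:
    """One labeled, site-tagged subject."""

    subject_id: str
    site: str
    label: str
    conn: ConnectivityMatrix

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if not self.site:
            raise ValueError("site must be non-empty")

    @property
    def y(self) -> int:
        """Class index: patient = 1, control = 0."""
        return 1 if self.label == "patient" else 0


@dataclass
class MultiSiteDataset:
    """An ordered collection of subjects spanning one or more sites."""

    subjects: list[SubjectRecord]
    site_index: dict[str, list[int]] = field(init=False)

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("dataset must contain at least one subject")
        roi_ids = self.subjects[0].conn.roi_ids
        for s in self.subjects:
            if s.conn.roi_ids != roi_ids:
                raise ValueError(f"subject {s.subject_id} has mismatched roi_ids")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject_ids must be unique")
        self.site_index = {}
        for i, s in enumerate(self.subjects):
            self.site_index.setdefault(s.site, []).append(i)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def roi_ids(self) -> list[str]:
        return self.subjects[0].conn.roi_ids

    @property
    def n_rois(self) -> int:
        return self.subjects[0].conn.n_rois

    @property
    def sites(self) -> list[str]:
        return sorted(self.site_index)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    def labels(self) -> np.ndarray:
        return np.array([s.y for s in self.subjects], dtype=int)

    def stack(self) -> np.ndarray:
        """All connectivity matrices as one (n_subjects, N, N) array."""
        return np.stack([s.conn.z for s in self.subjects])

    def subset(self, ids: list[str] | set[str]) -> "MultiSiteDataset":
        wanted = set(ids)
        subs = [s for s in self.subjects if s.subject_id in wanted]
        if len(subs) != len(wanted):
            missing = wanted - {s.subject_id for s in subs}
            raise KeyError(f"unknown subject ids: {sorted(missing)}")
        return MultiSiteDataset(subs)

    def by_id(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


@dataclass
class KnnGraph:
    """Population K-NN graph over ROIs (shared by all subjects)."""

    adjacency: np.ndarray
    k: int
    edge_weights: str = "binary"

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if np.any(self.adjacency < 0):
            raise ValueError("adjacency must be nonnegative")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.max(np.abs(self.adjacency - self.adjacency.T)) > SYMMETRY_TOL:
            raise ValueError("adjacency must be symmetric")
        if self.edge_weights not in ("binary", "similarity"):
            raise ValueError("edge_weights must be 'binary' or 'similarity'")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))


@dataclass
class NormalizedAdjacency:
    """The renormalized propagation operator A_hat = D^-1/2 (A + I) D^-1/2."""

    a_hat: np.ndarray

    def __post_init__(self) -> None:
        self.a_hat = np.asarray(self.a_hat, dtype=float)
        n = self.a_hat.shape[0]
        if self.a_hat.shape != (n, n):
            raise ValueError("a_hat must be square")
        if np.max(np.abs(self.a_hat - self.a_hat.T)) > 1e-8:
            raise ValueError("a_hat must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.a_hat.shape[0]


def pearson_fisher_connectivity(ts: TimeSeries) -> ConnectivityMatrix:
    """Pearson correlation between all ROI pairs, Fisher z-transformed.

    ``z[i, j] = atanh(r_ij)`` for i != j, with |r| clipped to ``R_CLIP`` so
    perfectly (anti)correlated pairs remain finite; the diagonal is fixed at 0
    by convention (atanh(1) diverges).
    """
    x = ts.values
    sd = x.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = [ts.roi_ids[i] for i in bad]
        raise ValueError(f"zero-variance ROI time series: {names}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -R_CLIP, R_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(z=z, roi_ids=list(ts.roi_ids))


def regress_out_site(
    ds: MultiSiteDataset, fit_ids: set[str] | list[str]
) -> MultiSiteDataset:
    """Remove per-edge additive site effects estimated on ``fit_ids`` only.

    For every edge an ordinary-least-squares fit of z on one-hot site
    indicators is estimated on the fit subjects; the fitted site effect
    (per-site mean minus the grand mean over fit subjects) is subtracted from
    every subject of that site, including held-out ones. Fitting on training
    subjects only prevents test-set leakage.
    """
    fit_ids = set(fit_ids)
    fit_mask = np.array([s.subject_id in fit_ids for s in ds.subjects])
    if fit_mask.sum() == 0:
        raise ValueError("fit_ids selects no subjects")
    fit_sites = {s.site for s, m in zip(ds.subjects, fit_mask) if m}
    if len(fit_sites) < 2:
        raise ValueError("site regression needs fit subjects from >= 2 sites")
    missing = set(ds.site_index) - fit_sites
    if missing:
        raise ValueError(
            f"sites {sorted(missing)} have no subjects in fit_ids; "
            "their site effect cannot be estimated"
        )

    zs = ds.stack()
    grand = zs[fit_mask].mean(axis=0)
    effects: dict[str, np.ndarray] = {}
    for site, idx in ds.site_index.items():
        site_fit = [i for i in idx if fit_mask[i]]
        effects[site] = zs[site_fit].mean(axis=0) - grand

    out = []
    for s in ds.subjects:
        z = s.conn.z - effects[s.site]
        np.fill_diagonal(z, 0.0)
        z = (z + z.T) / 2.0
        out.append(
            SubjectRecord(
                subject_id=s.subject_id,
                site=s.site,
                label=s.label,
                conn=ConnectivityMatrix(z=z, roi_ids=list(s.conn.roi_ids)),
            )
        )
    return MultiSiteDataset(out)


def mean_connectivity(
    ds: MultiSiteDataset, ids: set[str] | list[str]
) -> ConnectivityMatrix:
    """Elementwise mean connectivity over the selected subjects."""
    ids = set(ids)
    if not ids:
        raise ValueError("ids must be non-empty")
    sel = [s for s in ds.subjects if s.subject_id in ids]
    if len(sel) != len(ids):
        missing = ids - {s.subject_id for s in sel}
        raise KeyError(f"unknown subject ids: {sorted(missing)}")
    z = np.mean([s.conn.z for s in sel], axis=0)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return ConnectivityMatrix(z=z, roi_ids=list(ds.roi_ids))


def _masked_row_correlation(z: np.ndarray, i: int, j: int) -> float:
    """Pearson correlation of rows i, j with the self-connection entries masked."""
    keep = np.ones(z.shape[0], dtype=bool)
    keep[[i, j]] = False
    a, b = z[i, keep], z[j, keep]
    if a.size < 2:  # N <= 3: too few entries for a correlation
        return 0.0
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def build_knn_graph(
    mean_conn: ConnectivityMatrix, k: int = 10, edge_weights: str = "binary"
) -> KnnGraph:
    """K-nearest-neighbour graph over ROIs from mean training connectivity.

    Node distance is the correlation distance ``1 - pearson(row_i, row_j)``
    between connectivity profiles, with the two self-connection entries
    masked out of both rows. Each node selects its ``k`` smallest-distance
    neighbours (ties broken by lower node index) and the edge set is
    union-symmetrized. ``edge_weights='similarity'`` stores
    ``max(0, 1 - distance)`` instead of 1.
    """
    n = mean_conn.n_rois
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < N (= {n}), got {k}")
    z = mean_conn.z
    dist = np.empty((n, n))
    for i in range(n):
        dist[i, i] = np.inf
        for j in range(i + 1, n):
            d = 1.0 - _masked_row_correlation(z, i, j)
            dist[i, j] = dist[j, i] = d
    adj = np.zeros((n, n))
    order = np.arange(n)
    for i in range(n):
        # lexsort: primary key distance, secondary key node index (determinism)
        nbrs = np.lexsort((order, dist[i]))[:k]
        for j in nbrs:
            w = 1.0 if edge_weights == "binary" else max(0.0, 1.0 - dist[i, j])
            adj[i, j] = max(adj[i, j], w)
    adj = np.maximum(adj, adj.T)  # union symmetrization
    np.fill_diagonal(adj, 0.0)
    return KnnGraph(adjacency=adj, k=k, edge_weights=edge_weights)


def normalize_adjacency(g: KnnGraph) -> NormalizedAdjacency:
    """Renormalized adjacency A_hat = D^-1/2 (A + I) D^-1/2.

    D is the degree matrix of A + I; the spectrum of A_hat lies in [-1, 1],
    which keeps repeated graph convolutions numerically stable.
    """
    a = g.adjacency
    a_tilde = a + np.eye(a.shape[0])
    d = a_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(d)
    a_hat = a_tilde * np.outer(d_inv_sqrt, d_inv_sqrt)
    a_hat = (a_hat + a_hat.T) / 2.0
    return NormalizedAdjacency(a_hat=a_hat)


def node_features(conn: ConnectivityMatrix) -> np.ndarray:
    """Node feature matrix X: row i is node i's connectivity profile (X = z)."""
    return conn.z.copy()
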