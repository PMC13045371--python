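"""Interpretability: feature maps, class activation maps, group statistics.

Because the dense head has no bias, the pre-softmax class score decomposes
exactly over the graph embedding: S_c = sum_x w_x^c * z_g[x]. That identity
anchors the embedding-level class activation map (CAM); node-level maps are
obtained by backprojecting through the transposed (purely linear) pooling
chain, and edge-level attributions by gradient-times-input on the input
connectivity, which is exact for a network operating in its linear regime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectome import KnnGraph, NormalizedAdjacency
from .model import GCNSPParams, forward, input_gradient
from .synthdata import NetworkPartition

__all__ = [
    "FeatureMapSet",
    "ClassActivationMap",
    "GroupDiffDistribution",
    "extract_feature_maps",
    "network_overlap",
    "cam_embedding",
    "cam_nodes",
    "cam_edges",
    "top_edges",
    "network_weights",
    "group_ttest",
    "kde_density",
    "shuffle_adjacency",
]

CLASS_INDEX = {"patient": 1, "control": 0}


@dataclass
class FeatureMapSet:
    """Per-channel node activations of one layer, averaged over subjects."""

    layer: str  # "gcn1" or "gcn2"
    maps: np.ndarray  # (n_channels, n_nodes)
    subject_count: int


@dataclass
class ClassActivationMap:
    class_id: int
    embedding_scores: np.ndarray  # contributions over z_g
    class_score: float  # S_c (pre-softmax logit)
    node_scores: np.ndarray | None = None
    edge_scores: np.ndarray | None = None


@dataclass
class GroupDiffDistribution:
    t_values: np.ndarray
    grid: np.ndarray
    density: np.ndarray


def extract_feature_maps(
    params: GCNSPParams,
    graph: NormalizedAdjacency,
    subjects,
    layer: str = "gcn2",
) -> FeatureMapSet:
    """Channel-wise node activations of a GCN layer, averaged over subjects.

    ``subjects`` is a MultiSiteDataset or list of SubjectRecord; evaluation
    mode (no dropout).
    """
    if layer not in ("gcn1", "gcn2"):
        raise ValueError("layer must be 'gcn1' or 'gcn2'")
    subs = list(subjects.subjects) if hasattr(subjects, "subjects") \
        else list(subjects)
    if not subs:
        raise ValueError("empty subject set")
    acc = None
    for s in subs:
        _, _, acts = forward(graph, s.conn.z, params)
        m = acts[layer]
        acc = m if acc is None else acc + m
    mean = acc / len(subs)
    return FeatureMapSet(layer=layer, maps=mean.T.copy(),
                         subject_count=len(subs))


def network_overlap(
    fm: FeatureMapSet,
    part: NetworkPartition,
    top_fraction: float = 0.1,
    roi_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Associate every channel with a functional network; tabulate shares.

    For each channel the ``top_fraction`` nodes by absolute activation form
    its discriminative region. A network's raw share is the fraction of
    those nodes it holds; the size-corrected share divides the raw share by
    the network's node-count fraction, so large networks are not favoured by
    construction. The channel is associated with the network of the largest
    corrected share, and the table reports, per network, the percentage of
    channels associated under the raw and under the corrected rule.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    n_ch, n_nodes = fm.maps.shape
    if roi_ids is None:
        roi_ids = sorted(part.roi_to_network)[:n_nodes]
    labels = np.array(part.labels_for(roi_ids))
    nets = part.networks
    size_frac = {net: (labels == net).sum() / n_nodes for net in nets}
    n_top = max(1, int(np.ceil(top_fraction * n_nodes)))

    assoc_raw = {net: 0 for net in nets}
    assoc_corr = {net: 0 for net in nets}
    for ch in range(n_ch):
        scores = np.abs(fm.maps[ch])
        order = np.lexsort((np.arange(n_nodes), -scores))
        top = labels[order[:n_top]]
        raw = {net: (top == net).sum() / n_top for net in nets}
        corr = {net: (raw[net] / size_frac[net]) if size_frac[net] > 0
                else 0.0 for net in nets}
        assoc_raw[max(nets, key=lambda n: (raw[n], -nets.index(n)))] += 1
        assoc_corr[max(nets, key=lambda n: (corr[n], -nets.index(n)))] += 1
    return pd.DataFrame({
        "network": nets,
        "pct_channels_raw": [100.0 * assoc_raw[n] / n_ch for n in nets],
        "pct_channels_corrected": [100.0 * assoc_corr[n] / n_ch
                                   for n in nets],
        "n_nodes": [(labels == n).sum() for n in nets],
    })


def cam_embedding(
    params: GCNSPParams,
    z_g: np.ndarray,
    class_id: int | str = "patient",
) -> ClassActivationMap:
    """Embedding-level CAM: per-entry contribution w_x^c * z_g[x].

    The bias-free head makes the conservation identity exact:
    sum_x embedding_scores[x] = logit_c = S_c.
    """
    c = CLASS_INDEX.get(class_id, class_id)
    z_g = np.asarray(z_g, dtype=float)
    if z_g.shape[0] != params.dense_w.shape[0]:
        raise ValueError("embedding length does not match dense head")
    scores = params.dense_w[:, c] * z_g
    return ClassActivationMap(class_id=int(c), embedding_scores=scores,
                              class_score=float(scores.sum()))


def cam_nodes(cam: ClassActivationMap,
              theta_list: list[np.ndarray]) -> np.ndarray:
    """Backproject embedding scores to original nodes through Theta^T chain.

    Each pooled layer's score block (n_i x D2) is propagated back through
    the transposes of the linear pooling maps and the per-layer, per-channel
    contributions are summed, yielding one score per original node.
    """
    if not theta_list:
        raise ValueError("no pooling layers to backproject through")
    d2 = None
    sizes = [t.shape[0] for t in theta_list]
    total = cam.embedding_scores.shape[0]
    d2 = total // sum(sizes)
    if d2 * sum(sizes) != total:
        raise ValueError("embedding length inconsistent with pooling sizes")
    n0 = theta_list[0].shape[1]
    node_scores = np.zeros(n0)
    offset = 0
    for i, n_i in enumerate(sizes):
        block = cam.embedding_scores[offset: offset + n_i * d2]
        offset += n_i * d2
        g = block.reshape(n_i, d2)
        for j in range(i, -1, -1):
            g = theta_list[j].T @ g
        node_scores += g.sum(axis=1)
    return node_scores


def cam_edges(
    params: GCNSPParams,
    graph: NormalizedAdjacency,
    subject,
    class_id: int | str = "patient",
    method: str = "grad_x_input",
) -> np.ndarray:
    """Edge-level attribution: d S_c / d X[i,j] * X[i,j], symmetrized.

    Exact for a model in its linear regime (gradient-times-input sums to
    S_c there); the diagonal is zeroed.
    """
    if method != "grad_x_input":
        raise ValueError("only 'grad_x_input' is implemented")
    c = CLASS_INDEX.get(class_id, class_id)
    x = subject.conn.z if hasattr(subject, "conn") else np.asarray(subject)
    g = input_gradient(graph, x, params, int(c))
    attr = g * x
    attr = (attr + attr.T) / 2.0
    np.fill_diagonal(attr, 0.0)
    return attr


def top_edges(edge_scores: np.ndarray, fraction: float = 0.01) -> pd.DataFrame:
    """Top-scoring upper-triangle edges.

    Ranked by score descending, ties by (i, j) lexicographic; the top
    ceil(fraction * E) edges are returned, E = N(N-1)/2.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n = edge_scores.shape[0]
    iu = np.triu_indices(n, 1)
    scores = edge_scores[iu]
    n_top = int(np.ceil(fraction * len(scores)))
    order = np.lexsort((iu[1], iu[0], -scores))
    sel = order[:n_top]
    return pd.DataFrame({
        "roi_i": iu[0][sel], "roi_j": iu[1][sel], "score": scores[sel],
    })


def network_weights(
    edge_scores: np.ndarray,
    part: NetworkPartition,
    edges: pd.DataFrame | None = None,
    roi_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Mean attribution within and between networks.

    Averages the scores of the selected edges (default: all upper-triangle
    edges) per network-pair block; blocks containing no selected edge are
    NaN — flagged missing rather than silently zero.
    """
    n = edge_scores.shape[0]
    if roi_ids is None:
        roi_ids = sorted(part.roi_to_network)[:n]
    labels = part.labels_for(roi_ids)
    nets = part.networks
    idx = {net: i for i, net in enumerate(nets)}
    sums = np.zeros((len(nets), len(nets)))
    counts = np.zeros((len(nets), len(nets)))
    if edges is None:
        iu = np.triu_indices(n, 1)
        pairs = zip(iu[0], iu[1], edge_scores[iu])
    else:
        pairs = zip(edges["roi_i"], edges["roi_j"], edges["score"])
    for i, j, s in pairs:
        a, b = idx[labels[int(i)]], idx[labels[int(j)]]
        a, b = min(a, b), max(a, b)
        sums[a, b] += s
        counts[a, b] += 1
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    il = np.tril_indices(len(nets), -1)
    means[il] = means.T[il]  # mirror upper triangle
    return pd.DataFrame(means, index=nets, columns=nets)


def group_ttest(maps_patients: np.ndarray,
                maps_controls: np.ndarray) -> GroupDiffDistribution:
    """Elementwise pooled-variance two-sample t (patients minus controls).

    Inputs are stacks with subjects on the first axis; elements with zero
    pooled variance get t = 0 with a warning. The returned distribution
    carries a kernel-density estimate of the t values.
    """
    a = np.asarray(maps_patients, dtype=float)
    b = np.asarray(maps_controls, dtype=float)
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 subjects per group")
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = np.zeros(denom.shape)
    ok = denom > 0
    if not np.all(ok):
        warnings.warn("zero pooled variance in some elements; t set to 0",
                      stacklevel=2)
    diff = a.mean(axis=0) - b.mean(axis=0)
    t[ok] = diff[ok] / denom[ok]
    if t.size >= 2:
        grid, dens = kde_density(t.ravel())
    else:  # a density estimate needs at least two elements
        grid = dens = np.empty(0)
    return GroupDiffDistribution(t_values=np.atleast_1d(t), grid=grid,
                                 density=dens)


def kde_density(
    t_values: np.ndarray,
    grid: np.ndarray | None = None,
    bw_floor: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate with Scott's-rule bandwidth.

    The bandwidth is floored at ``bw_floor`` so constant inputs degrade to a
    narrow spike instead of dividing by zero. The returned curve integrates
    to 1 (trapezoidal) on an adequate grid.
    """
    x = np.asarray(t_values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need >= 2 values for a density estimate")
    sd = x.std(ddof=1)
    bw = max(bw_floor, sd * x.size ** (-1.0 / 5.0))
    if grid is None:
        lo, hi = x.min() - 4 * bw, x.max() + 4 * bw
        grid = np.linspace(lo, hi, 512)
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - x[None, :]) / bw
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (x.size * bw *
                                               np.sqrt(2 * np.pi))
    return grid, dens


def shuffle_adjacency(graph: KnnGraph, mode: str, seed: int) -> KnnGraph:
    """Destructive graph controls.

    ``adjacency`` permutes the upper-triangle entries (destroys the degree
    sequence, preserves the edge count); ``node_order`` applies one random
    node permutation to rows and columns (preserves the degree multiset).
    """
    rng = np.random.default_rng(seed)
    a = graph.adjacency
    n = a.shape[0]
    if mode == "adjacency":
        iu = np.triu_indices(n, 1)
        vals = a[iu].copy()
        rng.shuffle(vals)
        out = np.zeros_like(a)
        out[iu] = vals
        out = out + out.T
    elif mode == "node_order":
        p = rng.permutation(n)
        out = a[np.ix_(p, p)]
    else:
        raise ValueError("mode must be 'adjacency' or 'node_order'")
    return KnnGraph(adjacency=out, k=graph.k, edge_weights=graph.edge_weights)
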