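"""Reading and writing the on-disk formats.

A dataset on disk is a manifest CSV (subject_id, site, label, path), one
delimited matrix file per subject (either an N x N connectivity matrix, or a
T x N ROI time-series table whose header row carries the ROI ids), an
ROI -> functional-network partition CSV and, for synthetic data, a
ground-truth JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import (
    ConnectivityMatrix,
    MultiSiteDataset,
    SubjectRecord,
    TimeSeries,
    pearson_fisher_connectivity,
    LABELS,
)
from .synthdata import GroundTruth, NetworkPartition

MANIFEST_COLUMNS = ["subject_id", "site", "label", "path"]


def write_dataset(ds: MultiSiteDataset, outdir, gt: GroundTruth | None = None,
                  fmt: str = "%.10g") -> Path:
    """Write manifest + per-subject matrices (+ partition and ground truth)."""
    outdir = Path(outdir)
    (outdir / "matrices").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in ds.subjects:
        rel = f"matrices/{s.subject_id}.txt"
        np.savetxt(outdir / rel, s.conn.z, fmt=fmt)
        rows.append({"subject_id": s.subject_id, "site": s.site,
                     "label": s.label, "path": rel})
    pd.DataFrame(rows).to_csv(outdir / "manifest.csv", index=False)
    if gt is not None:
        part_rows = [{"roi_id": r, "network_name": n}
                     for r, n in gt.partition.roi_to_network.items()]
        pd.DataFrame(part_rows).to_csv(outdir / "partition.csv", index=False)
        (outdir / "ground_truth.json").write_text(gt.to_json())
    return outdir / "manifest.csv"


def read_partition(path) -> NetworkPartition:
    df = pd.read_csv(path)
    missing = {"roi_id", "network_name"} - set(df.columns)
    if missing:
        raise ValueError(f"partition table missing columns: {sorted(missing)}")
    return NetworkPartition(roi_to_network=dict(
        zip(df["roi_id"].astype(str), df["network_name"].astype(str))))


def _load_matrix(path: Path, roi_ids: list[str] | None):
    """Load one subject file; header row of ROI ids marks a time series."""
    with open(path) as f:
        first = f.readline()
    has_header = any(not _is_number(tok)
                     for tok in first.replace(",", " ").split())
    if has_header:
        df = pd.read_csv(path, sep=None, engine="python")
        ts = TimeSeries(values=df.to_numpy(dtype=float),
                        roi_ids=[str(c) for c in df.columns])
        return pearson_fisher_connectivity(ts)
    z = np.loadtxt(path)
    if roi_ids is None:
        roi_ids = [f"roi{i:04d}" for i in range(z.shape[0])]
    return ConnectivityMatrix(z=z, roi_ids=list(roi_ids))


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def load_dataset(manifest_path, partition_path=None) -> MultiSiteDataset:
    """Load a dataset from a manifest; paths are relative to the manifest."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    roi_ids = None
    if partition_path is not None:
        part = read_partition(partition_path)
        roi_ids = list(part.roi_to_network)
    base = manifest_path.parent
    subjects = []
    for _, row in df.iterrows():
        conn = _load_matrix(base / row["path"], roi_ids)
        subjects.append(SubjectRecord(
            subject_id=str(row["subject_id"]), site=str(row["site"]),
            label=str(row["label"]), conn=conn))
    return MultiSiteDataset(subjects)


def validate_manifest(manifest_path, symmetry_tol: float = 1e-6) -> list[str]:
    """Schema and content checks; returns one message per violation."""
    manifest_path = Path(manifest_path)
    violations: list[str] = []
    try:
        df = pd.read_csv(manifest_path)
    except Exception as e:  # unreadable file
        raise OSError(f"cannot read manifest {manifest_path}: {e}") from e
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            violations.append(f"missing column: {col}")
    if violations:
        return violations
    bad_labels = set(df["label"]) - set(LABELS)
    if bad_labels:
        violations.append(f"labels outside {LABELS}: {sorted(bad_labels)}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        violations.append(f"duplicate subject_ids: {dups}")
    base = manifest_path.parent
    shape = None
    for _, row in df.iterrows():
        p = base / str(row["path"])
        if not p.exists():
            violations.append(f"{row['subject_id']}: file not found: {p}")
            continue
        try:
            m = np.loadtxt(p)
        except ValueError:
            continue  # header row: time-series file, shape checked on load
        if m.ndim != 2:
            violations.append(f"{row['subject_id']}: matrix is not 2-D")
            continue
        if shape is None:
            shape = m.shape
        elif m.shape != shape:
            violations.append(
                f"{row['subject_id']}: shape {m.shape} != first {shape}")
        if m.shape[0] == m.shape[1]:
            asym = float(np.max(np.abs(m - m.T)))
            if asym > symmetry_tol:
                violations.append(
                    f"{row['subject_id']}: asymmetric beyond tolerance "
                    f"(max |z - z.T| = {asym:.2e})")
    return violations


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())
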