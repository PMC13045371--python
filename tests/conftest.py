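import numpy as np
import pytest

from gcnsp.connectome import (
    ConnectivityMatrix,
    KnnGraph,
    MultiSiteDataset,
    SubjectRecord,
    build_knn_graph,
    mean_connectivity,
    normalize_adjacency,
    regress_out_site,
)
from gcnsp.model import Hyperparams, init_params, train_epochs
from gcnsp.synthdata import GeneratorConfig, generate_dataset


def make_conn(z, roi_ids=None):
    z = np.asarray(z, dtype=float)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    ids = roi_ids or [f"roi{i:04d}" for i in range(z.shape[0])]
    return ConnectivityMatrix(z=z, roi_ids=ids)


def random_symmetric(n, rng, scale=1.0):
    a = rng.normal(scale=scale, size=(n, n))
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


def make_dataset(n_subjects, n_rois, rng, sites=("S1",), labels=None):
    subs = []
    for i in range(n_subjects):
        label = (labels[i] if labels is not None
                 else ("patient" if i % 2 == 0 else "control"))
        subs.append(SubjectRecord(
            subject_id=f"sub{i:04d}", site=sites[i % len(sites)],
            label=label, conn=make_conn(random_symmetric(n_rois, rng))))
    return MultiSiteDataset(subs)


@pytest.fixture(scope="session")
def toy_separable():
    """Small two-site dataset with a strong planted effect, plus its graph."""
    cfg = GeneratorConfig(
        n_rois=20, n_networks=2, n_sites=2,
        n_patients_per_site=10, n_controls_per_site=10,
        within_block_r=0.3, between_block_r=0.05,
        planted_edges=("network", 0), effect_delta=0.5,
        site_shift_sd=0.05, site_scale_sd=0.02, subject_noise_sd=0.15,
        seed=11,
    )
    ds, gt = generate_dataset(cfg)
    ids = ds.subject_ids
    ds_r = regress_out_site(ds, ids)
    graph = normalize_adjacency(
        build_knn_graph(mean_connectivity(ds_r, ids), 5))
    return ds_r, graph, gt


@pytest.fixture(scope="session")
def trained_toy(toy_separable):
    """A quickly trained small model for interpretability tests."""
    ds, graph, gt = toy_separable
    hyper = Hyperparams(hidden_size=8, epochs=40, seed=5, batch_size=16)
    params, history = train_epochs(ds, graph, hyper)
    return ds, graph, gt, params, hyper, history
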