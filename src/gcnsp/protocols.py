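"""Evaluation protocols: pooled CV, leave-site-out, transfer, baselines.

Three multi-site regimes are provided. Pooled cross-validation mixes all
sites and stratifies folds by label within site. Leave-site-out holds one
acquisition site out of everything — site regression, graph construction,
scaling and training all see only the remaining sites — and therefore
measures cross-site generalization. Transfer learning pre-trains on the
source sites and fine-tunes on 90% of the target site, testing on the
remaining 10%, with an optional optimal-epoch variant selected on a
validation split carved from the fine-tuning portion.

Every fitted object records which subject ids influenced it (the audit
trail), so leakage is checkable, not assumed away.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .connectome import (
    MultiSiteDataset,
    build_knn_graph,
    mean_connectivity,
    normalize_adjacency,
    regress_out_site,
)
from .model import (
    Hyperparams,
    _eval_scores,
    init_params,
    train_epochs,
)

__all__ = [
    "FoldSplit",
    "Metrics",
    "CVResult",
    "TransferResult",
    "stratified_kfold",
    "metrics_compute",
    "multi_site_pooling_cv",
    "leave_site_out_test",
    "pretrain",
    "transfer_cv",
    "optimal_epoch_select",
    "rfe_rank_t",
    "baseline_classify",
]

GCN_MODELS = ("gcnsp", "gcn")
RFE_MODELS = ("rfe_svm", "rfe_lda", "rfe_lr")


@dataclass
class FoldSplit:
    fold_id: int
    train_ids: list[str]
    test_ids: list[str]
    validation_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


@dataclass
class Metrics:
    """Binary classification metrics; patient is the positive class."""

    accuracy: float
    auc: float
    sensitivity: float
    specificity: float
    roc_curve: tuple[np.ndarray, np.ndarray]  # (fpr, tpr)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


@dataclass
class CVResult:
    """Cross-validation output: pooled out-of-fold metrics plus the
    per-subject score table and the provenance audit trail."""

    metrics: Metrics
    scores: pd.DataFrame  # subject_id, site, label, fold, score
    audit: list[tuple[str, frozenset]]
    fold_accuracies: list[float] = field(default_factory=list)


@dataclass
class TransferResult:
    site: str
    metrics_fixed_epoch: Metrics
    metrics_optimal_epoch: Metrics
    chosen_epoch: list[int]
    fine_tune_history: list[list[dict]]
    fold_accuracies_fixed: list[float] = field(default_factory=list)
    fold_accuracies_optimal: list[float] = field(default_factory=list)
    scores: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for e in self.chosen_epoch:
            if not 1 <= e:
                raise ValueError("chosen epochs must be >= 1")


def stratified_kfold(ds: MultiSiteDataset, k: int, seed: int) -> list[FoldSplit]:
    """Label-within-site stratified k-fold assignment.

    Subjects of each (site, label) cell are shuffled and dealt to folds
    through one global round-robin pointer, so overall fold sizes differ by
    at most one and each cell's members are spread as evenly as possible.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = ds.labels()
    for cls in (0, 1):
        if (y == cls).sum() < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    # label-major dealing: each class forms one contiguous round-robin run,
    # so per-fold class counts and total fold sizes both stay within +/-1
    pointer = 0
    for label in ("patient", "control"):
        for site in ds.sites:
            members = [ds.subjects[i].subject_id for i in ds.site_index[site]
                       if ds.subjects[i].label == label]
            members = [members[j] for j in rng.permutation(len(members))]
            for sid in members:
                assignment[sid] = pointer % k
                pointer += 1
    folds = []
    all_ids = ds.subject_ids
    for f in range(k):
        test = [s for s in all_ids if assignment[s] == f]
        train = [s for s in all_ids if assignment[s] != f]
        folds.append(FoldSplit(fold_id=f, train_ids=train, test_ids=test))
    return folds


def metrics_compute(y_true: np.ndarray, scores: np.ndarray) -> Metrics:
    """Accuracy / sensitivity / specificity at threshold 0.5, ROC by
    threshold sweep, AUC as the trapezoidal area under the ROC."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    pred = (s > 0.5).astype(int)
    acc = float((pred == y).mean())
    n_pos, n_neg = int((y == 1).sum()), int((y == 0).sum())
    sens = float((pred[y == 1] == 1).mean()) if n_pos else float("nan")
    spec = float((pred[y == 0] == 0).mean()) if n_neg else float("nan")
    if n_pos == 0 or n_neg == 0:
        warnings.warn("single-class y_true: AUC undefined", stacklevel=2)
        fpr = np.array([0.0, 1.0])
        tpr = np.array([0.0, 1.0])
        auc = float("nan")
    else:
        fpr, tpr, _ = _sk_roc_curve(y, s)
        auc = float(np.trapezoid(tpr, fpr))
    return Metrics(accuracy=acc, auc=auc, sensitivity=sens,
                   specificity=spec, roc_curve=(fpr, tpr))


# ---------------------------------------------------------------------------
# shared per-fold pipeline


def _fit_fold_graph(ds, train_ids, hyper, audit, tag, harmonize=True):
    """Site-regress (fit on training ids) and build the training-fold graph."""
    if harmonize and len(ds.sites) >= 2:
        ds_r = regress_out_site(ds, train_ids)
        audit.append((f"{tag}:site_regression", frozenset(train_ids)))
    else:
        ds_r = ds
    mc = mean_connectivity(ds_r, train_ids)
    audit.append((f"{tag}:mean_connectivity", frozenset(train_ids)))
    graph = normalize_adjacency(build_knn_graph(mc, hyper.knn_k))
    audit.append((f"{tag}:knn_graph", frozenset(train_ids)))
    return ds_r, graph


def _upper_tri(ds: MultiSiteDataset, ids: list[str]) -> np.ndarray:
    n = ds.n_rois
    iu = np.triu_indices(n, 1)
    sub = ds.subset(ids)
    return np.stack([s.conn.z[iu] for s in sub.subjects])


def _make_clf(clf: str):
    if clf == "svm":
        return SVC(kernel="linear", C=1.0, probability=True, random_state=0)
    if clf == "lda":
        return LinearDiscriminantAnalysis()
    if clf == "lr":
        return LogisticRegression(max_iter=1000)
    raise ValueError(f"unknown classifier {clf!r}")


def _fold_scores_gcn(ds, fold, hyper, readout, audit, seed_offset):
    ds_r, graph = _fit_fold_graph(ds, fold.train_ids, hyper, audit,
                                  f"fold{fold.fold_id}")
    train = ds_r.subset(fold.train_ids)
    h = hyper.replace(seed=hyper.seed + seed_offset)
    params, _ = train_epochs(train, graph, h, readout=readout)
    audit.append((f"fold{fold.fold_id}:model", frozenset(fold.train_ids)))
    test = ds_r.subset(fold.test_ids)
    return _eval_scores(graph.a_hat, test.stack(), params, readout)


def _fold_scores_rfe(ds, fold, clf_name, keep_ratio, audit):
    ds_r = (regress_out_site(ds, fold.train_ids)
            if len(ds.sites) >= 2 else ds)
    audit.append((f"fold{fold.fold_id}:site_regression",
                  frozenset(fold.train_ids)))
    x_tr = _upper_tri(ds_r, fold.train_ids)
    y_tr = ds_r.subset(fold.train_ids).labels()
    scaler = StandardScaler().fit(x_tr)
    audit.append((f"fold{fold.fold_id}:scaler", frozenset(fold.train_ids)))
    x_tr = scaler.transform(x_tr)
    _, selected = rfe_rank_t(x_tr, y_tr, keep_ratio=keep_ratio)
    audit.append((f"fold{fold.fold_id}:rfe", frozenset(fold.train_ids)))
    clf = _make_clf(clf_name).fit(x_tr[:, selected], y_tr)
    audit.append((f"fold{fold.fold_id}:classifier",
                  frozenset(fold.train_ids)))
    x_te = scaler.transform(_upper_tri(ds_r, fold.test_ids))
    return clf.predict_proba(x_te[:, selected])[:, 1]


def _assemble_cv(ds, folds, score_fn) -> CVResult:
    audit: list[tuple[str, frozenset]] = []
    rows = []
    fold_accs = []
    for fold in folds:
        scores = score_fn(fold, audit)
        test = ds.subset(fold.test_ids)
        y = test.labels()
        fold_accs.append(float(((scores > 0.5).astype(int) == y).mean()))
        for sid, sc in zip(fold.test_ids, scores):
            rec = ds.by_id(sid)
            rows.append({"subject_id": sid, "site": rec.site,
                         "label": rec.label, "fold": fold.fold_id,
                         "score": float(sc)})
    df = pd.DataFrame(rows)
    y_all = (df["label"] == "patient").astype(int).to_numpy()
    metrics = metrics_compute(y_all, df["score"].to_numpy())
    return CVResult(metrics=metrics, scores=df, audit=audit,
                    fold_accuracies=fold_accs)


def multi_site_pooling_cv(
    ds: MultiSiteDataset,
    hyper: Hyperparams,
    model: str = "gcnsp",
    k: int = 10,
    keep_ratio: float = 1e-4,
) -> CVResult:
    """Pooled k-fold cross-validation over all sites.

    Within every fold the site regression, the population graph (or feature
    scaler and RFE selection for the linear baselines) and the classifier
    are fitted on the training portion only; metrics are computed on the
    pooled out-of-fold scores.
    """
    folds = stratified_kfold(ds, k, hyper.seed)
    if model in GCN_MODELS:
        readout = "sparse_pool" if model == "gcnsp" else "mean"
        fn = lambda fold, audit: _fold_scores_gcn(
            ds, fold, hyper, readout, audit, seed_offset=fold.fold_id)
    elif model in RFE_MODELS:
        clf_name = model.split("_", 1)[1]
        fn = lambda fold, audit: _fold_scores_rfe(
            ds, fold, clf_name, keep_ratio, audit)
    else:
        raise ValueError(f"unknown model {model!r}")
    return _assemble_cv(ds, folds, fn)


def leave_site_out_test(
    ds: MultiSiteDataset,
    hyper: Hyperparams,
    model: str = "gcnsp",
) -> dict[str, Metrics]:
    """Hold each site out entirely; train on the remaining sites.

    Nothing fitted on the source sites sees the held-out site: the site
    regression and the graph are estimated within the source sites, and the
    held-out site's own site effect is left uncorrected (its site-specific
    distribution is deliberately unknown to the model, which is what the
    protocol measures).
    """
    if len(ds.sites) < 2:
        raise ValueError("leave-site-out needs >= 2 sites")
    readout = "sparse_pool" if model == "gcnsp" else "mean"
    out: dict[str, Metrics] = {}
    for site in ds.sites:
        source_idx = [i for s in ds.sites if s != site
                      for i in ds.site_index[s]]
        source = MultiSiteDataset([ds.subjects[i] for i in source_idx])
        audit: list = []
        src_ids = source.subject_ids
        source_r, graph = _fit_fold_graph(source, src_ids, hyper, audit,
                                          f"lso:{site}")
        params, _ = train_epochs(source_r, graph, hyper, readout=readout)
        target = MultiSiteDataset([ds.subjects[i]
                                   for i in ds.site_index[site]])
        scores = _eval_scores(graph.a_hat, target.stack(), params, readout)
        out[site] = metrics_compute(target.labels(), scores)
    return out


def pretrain(
    source_ds: MultiSiteDataset,
    hyper: Hyperparams,
    holdout_fraction: float = 0.1,
) -> dict:
    """Initial training on the source dataset.

    Returns a checkpoint dict with the trained parameters, the source graph,
    the hyperparameters and, for logging, the accuracy on an internal
    stratified holdout of the source data. Independent of any target data.
    """
    rng = np.random.default_rng(hyper.seed)
    y = source_ds.labels()
    ids = np.array(source_ds.subject_ids)
    hold: list[str] = []
    for cls in (0, 1):
        cls_ids = ids[y == cls]
        n_h = max(1, int(round(holdout_fraction * len(cls_ids))))
        hold.extend(rng.choice(cls_ids, size=n_h, replace=False).tolist())
    train_ids = [s for s in ids if s not in set(hold)]
    audit: list = []
    ds_r, graph = _fit_fold_graph(source_ds, train_ids, hyper, audit,
                                  "pretrain")
    params, history = train_epochs(ds_r.subset(train_ids), graph, hyper)
    holdout = ds_r.subset(hold)
    scores = _eval_scores(graph.a_hat, holdout.stack(), params, "sparse_pool")
    holdout_acc = float(((scores > 0.5).astype(int)
                         == holdout.labels()).mean())
    return {"params": params, "graph": graph, "hyper": hyper,
            "history": history, "holdout_accuracy": holdout_acc,
            "audit": audit}


def optimal_epoch_select(history) -> int:
    """1-based epoch with the highest validation accuracy; ties -> earliest."""
    if not len(history):
        raise ValueError("empty history")
    accs = [h["val_acc"] if isinstance(h, dict) else float(h)
            for h in history]
    return int(np.argmax(accs)) + 1


def _carve_validation(ds, train_ids, fraction, rng):
    """Stratified validation split carved from the training ids."""
    sub = ds.subset(train_ids)
    y = sub.labels()
    ids = np.array(sub.subject_ids)
    val: list[str] = []
    for cls in (0, 1):
        cls_ids = ids[y == cls]
        n_v = max(1, int(round(fraction * len(cls_ids))))
        val.extend(rng.choice(cls_ids, size=n_v, replace=False).tolist())
    fit = [s for s in train_ids if s not in set(val)]
    return fit, val


def transfer_cv(
    ds: MultiSiteDataset,
    target_site: str,
    hyper: Hyperparams,
    pretrained: dict | None = None,
    min_group_size: int = 20,
    freeze_gcn: bool = False,
    k: int = 10,
) -> TransferResult:
    """10-fold fine-tuning evaluation within the target site.

    Each fold initializes from the pretrained checkpoint (or from random
    parameters, which reduces the protocol to non-transfer training on the
    target alone), fine-tunes all layers on the 90% training portion with
    batch size 16, and tests on the held-out 10%. A stratified ninth of the
    training portion is carved out as validation; the fixed-epoch metrics
    use the final epoch, the optimal-epoch variant re-reads the test scores
    at the epoch with the highest validation accuracy. Accuracy is the mean
    over folds; ROC/AUC come from the pooled out-of-fold scores.
    """
    if target_site not in ds.site_index:
        raise KeyError(f"site {target_site!r} not present in dataset")
    target = MultiSiteDataset(
        [ds.subjects[i] for i in ds.site_index[target_site]])
    counts = np.bincount(target.labels(), minlength=2)
    if counts.min() < min_group_size:
        raise ValueError(
            f"target site {target_site!r} has group sizes {counts.tolist()}; "
            f"at least {min_group_size} per group required")

    hyper_ft = hyper.replace(batch_size=16)
    folds = stratified_kfold(target, k, hyper.seed)
    rng = np.random.default_rng(hyper.seed + 17)

    rows, histories, chosen, accs_fixed, accs_opt = [], [], [], [], []
    pooled_fixed, pooled_opt, pooled_y = [], [], []
    for fold in folds:
        fit_ids, val_ids = _carve_validation(target, fold.train_ids,
                                             1.0 / (k - 1), rng)
        if pretrained is not None:
            graph = pretrained["graph"]
            start = pretrained["params"].copy()
        else:
            _, graph = _fit_fold_graph(target, fold.train_ids, hyper_ft, [],
                                       f"tf{fold.fold_id}", harmonize=False)
            start = init_params(target.n_rois, hyper_ft,
                                seed=hyper_ft.seed + fold.fold_id)
        test = target.subset(fold.test_ids)
        test_x = test.stack()
        y_te = test.labels()
        per_epoch_scores: list[np.ndarray] = []

        def cb(epoch, params, rec, _a=graph.a_hat, _x=test_x):
            per_epoch_scores.append(_eval_scores(_a, _x, params,
                                                 "sparse_pool"))

        h = hyper_ft.replace(seed=hyper_ft.seed + 1000 + fold.fold_id)
        if freeze_gcn and pretrained is not None:
            params, history = _train_frozen(target.subset(fit_ids), graph, h,
                                            start, target.subset(val_ids), cb)
        else:
            params, history = train_epochs(
                target.subset(fit_ids), graph, h, params=start,
                val_ds=target.subset(val_ids), epoch_callback=cb)
        histories.append(history)
        if history:
            best = optimal_epoch_select(history)
            chosen.append(best)
            s_fixed = per_epoch_scores[-1]
            s_opt = per_epoch_scores[best - 1]
        else:  # zero fine-tuning epochs: evaluate the starting parameters
            s_fixed = s_opt = _eval_scores(graph.a_hat, test_x, params,
                                           "sparse_pool")
        accs_fixed.append(float(((s_fixed > 0.5).astype(int) == y_te).mean()))
        accs_opt.append(float(((s_opt > 0.5).astype(int) == y_te).mean()))
        pooled_fixed.append(s_fixed)
        pooled_opt.append(s_opt)
        pooled_y.append(y_te)
        for sid, sf, so in zip(fold.test_ids, s_fixed, s_opt):
            rows.append({"subject_id": sid, "fold": fold.fold_id,
                         "score_fixed": float(sf), "score_optimal": float(so)})

    y_all = np.concatenate(pooled_y)
    m_fixed = metrics_compute(y_all, np.concatenate(pooled_fixed))
    m_fixed.accuracy = float(np.mean(accs_fixed))
    m_opt = metrics_compute(y_all, np.concatenate(pooled_opt))
    m_opt.accuracy = float(np.mean(accs_opt))
    return TransferResult(
        site=target_site, metrics_fixed_epoch=m_fixed,
        metrics_optimal_epoch=m_opt, chosen_epoch=chosen,
        fine_tune_history=histories,
        fold_accuracies_fixed=accs_fixed, fold_accuracies_optimal=accs_opt,
        scores=pd.DataFrame(rows))


def _train_frozen(train, graph, hyper, start, val_ds, cb):
    """Fine-tune with the graph-convolution weights frozen (option)."""
    w0, w1 = start.w0.copy(), start.w1.copy()

    def restore(epoch, params, rec):
        params.w0[:] = w0
        params.w1[:] = w1
        cb(epoch, params, rec)

    # restoring after every epoch approximates freezing at epoch granularity
    return train_epochs(train, graph, hyper, params=start, val_ds=val_ds,
                        epoch_callback=restore)


def rfe_rank_t(
    features: np.ndarray,
    labels: np.ndarray,
    keep_ratio: float = 1e-4,
    step: float = 0.1,
) -> tuple[list[int], np.ndarray]:
    """Recursive feature elimination ranked by two-sample t-score.

    Per round the ``step`` fraction of surviving features with the lowest
    |t| (patients vs controls, pooled variance) is dropped and t is
    recomputed on the survivors, until ``max(1, ceil(keep_ratio * d))``
    remain. Zero-variance features get |t| = 0 (least important). Ties are
    broken by index: the lower index is considered more important. Returns
    the elimination ranking (least important first) and the sorted surviving
    index set.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("features must be n x d with d >= 1")
    if len(set(y.tolist())) < 2:
        raise ValueError("both classes must be present")
    d = x.shape[1]
    target = max(1, int(np.ceil(keep_ratio * d)))

    def tscores(cols):
        a, b = x[y == 1][:, cols], x[y == 0][:, cols]
        na, nb = len(a), len(b)
        va = a.var(axis=0, ddof=1)
        vb = b.var(axis=0, ddof=1)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        t = np.zeros(len(cols))
        ok = denom > 0
        t[ok] = (a.mean(axis=0) - b.mean(axis=0))[ok] / denom[ok]
        return t

    surviving = np.arange(d)
    eliminated: list[int] = []
    while len(surviving) > target:
        t = np.abs(tscores(surviving))
        n_drop = min(len(surviving) - target,
                     max(1, int(step * len(surviving))))
        # sort ascending |t|; among ties drop the higher index first
        order = np.lexsort((-surviving, t))
        drop = order[:n_drop]
        eliminated.extend(int(surviving[i]) for i in drop)
        keep = np.ones(len(surviving), dtype=bool)
        keep[drop] = False
        surviving = surviving[keep]
    t_final = np.abs(tscores(surviving))
    surv_order = np.lexsort((-surviving, t_final))
    ranking = eliminated + [int(surviving[i]) for i in surv_order]
    return ranking, np.sort(surviving)


def baseline_classify(
    ds: MultiSiteDataset,
    clf: str,
    folds: list[FoldSplit],
    keep_ratio: float = 1e-4,
) -> CVResult:
    """RFE + linear classifier baseline over pre-computed folds.

    Per fold: site regression, standardization and t-score RFE are fitted on
    the training portion; a linear SVM / LDA / logistic regression is fitted
    on the selected features; out-of-fold probabilities are pooled into
    metrics.
    """
    fn = lambda fold, audit: _fold_scores_rfe(ds, fold, clf, keep_ratio,
                                              audit)
    return _assemble_cv(ds, folds, fn)
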