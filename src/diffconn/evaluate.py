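"""Cross-validation schemes and classification metrics.

Two schemes: site-stratified k-fold (subjects of each acquisition site
dealt evenly across folds, so every fold mirrors the site mix) and
leave-one-site-out (each fold is one entire site, probing cross-site
generalization).  Metrics are sensitivity, specificity and accuracy in
percent, computed per fold and aggregated as mean +- SD.

By default the differential-edge mask is re-estimated on each fold's
training subjects only, so the test fold never influences
residualization, the t-tests or training; whole-cohort selection is
available behind a flag for protocol comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import select as sel
from .connectivity import FCMatrix
from .graph import build_graph
from .nn import LABEL_TO_CLASS, AttentionGCN, ModelConfig, stack_samples
from .synth import SubjectRecord

__all__ = ["FoldAssignment", "MetricReport", "CVResult", "make_folds",
           "confusion_metrics", "run_cv", "accuracy_vs_p", "permutation_null"]


@dataclass
class FoldAssignment:
    scheme: str                       # "stratified-10-fold" or "leave-one-site-out"
    fold_of_subject: dict[str, int]
    strata: dict[str, str]            # subject -> site
    n_folds: int

    def test_indices(self, records: list[SubjectRecord], fold: int) -> np.ndarray:
        return np.array([k for k, r in enumerate(records)
                         if self.fold_of_subject[r.subject_id] == fold], dtype=int)

    def train_indices(self, records: list[SubjectRecord], fold: int) -> np.ndarray:
        return np.array([k for k, r in enumerate(records)
                         if self.fold_of_subject[r.subject_id] != fold], dtype=int)


@dataclass
class MetricReport:
    """SEN/SPE/ACC (percent), mean +- SD over folds."""

    sensitivity: tuple[float, float]
    specificity: tuple[float, float]
    accuracy: tuple[float, float]
    per_fold: list[dict] = field(default_factory=list)

    def summary(self) -> str:
        rows = [
            ("SEN", self.sensitivity), ("SPE", self.specificity),
            ("ACC", self.accuracy),
        ]
        lines = ["metric\tmean\tsd"]
        for name, (m, s) in rows:
            lines.append(f"{name}\t{m:.2f}\t{s:.2f}")
        return "\n".join(lines)


@dataclass
class CVResult:
    report: MetricReport
    fold_predictions: list[dict]          # per fold: subject ids, true, pred
    fold_masks: list                      # per fold DifferentialEdgeSet
    fold_models: list                     # per fold trained classifier (or sklearn est.)
    folds: FoldAssignment
    fold_train_indices: list[np.ndarray]


def make_folds(records: list[SubjectRecord], scheme: str = "stratified-10-fold",
               k: int = 10, seed: int = 0) -> FoldAssignment:
    """Deterministic fold assignment.

    Stratified k-fold shuffles within each site and deals subjects
    round-robin, so fold sizes differ by at most one within every site
    stratum.  Leave-one-site-out assigns each site its own fold
    (ignoring k).
    """
    sites = {r.subject_id: r.site for r in records}
    if scheme == "leave-one-site-out":
        site_names = sorted({r.site for r in records})
        fold_of = {r.subject_id: site_names.index(r.site) for r in records}
        return FoldAssignment(scheme, fold_of, sites, len(site_names))
    if scheme != "stratified-10-fold":
        raise ValueError(f"unknown scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    fold_of: dict[str, int] = {}
    for site in sorted({r.site for r in records}):
        members = [r.subject_id for r in records if r.site == site]
        if k > len(members):
            raise ValueError(
                f"k={k} exceeds the {len(members)} subjects of site {site}"
            )
        members = list(np.asarray(members)[rng.permutation(len(members))])
        for pos, sid in enumerate(members):
            fold_of[sid] = pos % k
    return FoldAssignment(scheme, fold_of, sites, k)


def confusion_metrics(true_labels, predicted_labels, positive: str = "ADHD") -> dict:
    """SEN/SPE/ACC in percent from label vectors.

    A fold with no positives (or no negatives) leaves the undefined
    metric as None with a warning; callers exclude None from means.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.size == 0:
        raise ValueError("empty label vectors")
    if t.shape != p.shape:
        raise ValueError("label vectors differ in length")
    pos = t == positive
    tp = int(np.sum(pos & (p == positive)))
    fn = int(np.sum(pos & (p != positive)))
    tn = int(np.sum(~pos & (p != positive)))
    fp = int(np.sum(~pos & (p == positive)))
    sen = 100.0 * tp / (tp + fn) if (tp + fn) else None
    spe = 100.0 * tn / (tn + fp) if (tn + fp) else None
    if sen is None:
        warnings.warn("no positive subjects: sensitivity undefined", stacklevel=2)
    if spe is None:
        warnings.warn("no negative subjects: specificity undefined", stacklevel=2)
    acc = 100.0 * (tp + tn) / t.size
    return {"sensitivity": sen, "specificity": spe, "accuracy": acc,
            "tp": tp, "fn": fn, "tn": tn, "fp": fp}


def _aggregate(per_fold: list[dict]) -> MetricReport:
    def ms(key):
        vals = [f[key] for f in per_fold if f[key] is not None]
        if not vals:
            return (float("nan"), float("nan"))
        return (float(np.mean(vals)), float(np.std(vals, ddof=0)))

    return MetricReport(sensitivity=ms("sensitivity"), specificity=ms("specificity"),
                        accuracy=ms("accuracy"), per_fold=per_fold)


def _fit_predict(train_samples, test_samples, classifier: str, cfg: ModelConfig,
                 mask, fc_stack, train_idx, test_idx):
    """Train one classifier and predict the test fold; returns
    (predicted label strings, fitted estimator)."""
    if classifier in ("agcn", "gcn"):
        use_cfg = cfg if classifier == "agcn" else ModelConfig(
            **{**cfg.__dict__, "attention": False})
        Xtr, ytr, A = stack_samples(train_samples)
        model = AttentionGCN(Xtr.shape[2], use_cfg).fit(Xtr, ytr, A)
        Xte = np.stack([s.node_features for s in test_samples])
        pred = model.predict(Xte, A)
        classes = np.array(sorted(LABEL_TO_CLASS, key=LABEL_TO_CLASS.get))
        return classes[pred], model
    if classifier == "svm":
        from sklearn.svm import SVC

        pairs = mask.edge_pairs
        ii = np.array([e[0] for e in pairs])
        jj = np.array([e[1] for e in pairs])
        feats = np.stack([fc.values[ii, jj] for fc in fc_stack])
        est = SVC(kernel="rbf")
        ytrain = np.array([s.graph_label for s in train_samples])
        est.fit(feats[train_idx], ytrain)
        return est.predict(feats[test_idx]), est
    raise ValueError(f"unknown classifier {classifier!r}")


def run_cv(fc_stack: list[FCMatrix], records: list[SubjectRecord],
           model_config: ModelConfig = ModelConfig(), scheme: str = "stratified-10-fold",
           k: int = 10, p_threshold: float = 0.03,
           covariates=sel.DEFAULT_COVARIATES, classifier: str = "agcn",
           per_fold_selection: bool = True, seed: int = 0,
           feature_mode: str = "edges") -> CVResult:
    """Cross-validated selection + training + evaluation.

    Per fold: select differential edges (on training subjects only
    unless ``per_fold_selection`` is off), build shared-topology graphs,
    train the classifier, predict the held-out fold.
    """
    folds = make_folds(records, scheme, k, seed)
    groups = np.array([r.group for r in records])

    whole_mask = None
    if not per_fold_selection:
        whole_mask, _ = sel.differential_edges(fc_stack, records, p_threshold, covariates)

    per_fold, preds, masks, models, train_sets = [], [], [], [], []
    for fold in range(folds.n_folds):
        tr = folds.train_indices(records, fold)
        te = folds.test_indices(records, fold)
        train_sets.append(tr)
        if per_fold_selection:
            mask, _ = sel.differential_edges(
                [fc_stack[i] for i in tr], [records[i] for i in tr],
                p_threshold, covariates)
        else:
            mask = whole_mask
        samples = [build_graph(fc_stack[i], mask, graph_index=i,
                               graph_label=records[i].group, feature_mode=feature_mode)
                   for i in range(len(records))]
        fold_cfg = ModelConfig(**{**model_config.__dict__,
                                  "seed": model_config.seed + fold})
        pred, est = _fit_predict([samples[i] for i in tr], [samples[i] for i in te],
                                 classifier, fold_cfg, mask, fc_stack, tr, te)
        per_fold.append(confusion_metrics(groups[te], pred))
        preds.append({"fold": fold,
                      "subjects": [records[i].subject_id for i in te],
                      "true": list(groups[te]), "pred": list(map(str, pred))})
        masks.append(mask)
        models.append(est)
    return CVResult(report=_aggregate(per_fold), fold_predictions=preds,
                    fold_masks=masks, fold_models=models, folds=folds,
                    fold_train_indices=train_sets)


def accuracy_vs_p(fc_stack, records, p_grid=sel.P_GRID, **cv_kwargs):
    """Mean CV accuracy at each selection threshold (the p sweep)."""
    rows = []
    for p in p_grid:
        res = run_cv(fc_stack, records, p_threshold=p, **cv_kwargs)
        rows.append({"p": p, "accuracy": res.report.accuracy[0],
                     "accuracy_sd": res.report.accuracy[1],
                     "n_edges": int(np.mean([len(m) for m in res.fold_masks]))})
    return rows


def permutation_null(fc_stack, records, n_permutations: int = 100, seed: int = 0,
                     **cv_kwargs) -> np.ndarray:
    """Null accuracy distribution from label-shuffled re-runs.

    Group labels are permuted over subjects, the full pipeline
    (selection included) is re-run, and the mean CV accuracy recorded.
    """
    import dataclasses

    rng = np.random.default_rng(seed)
    out = np.empty(n_permutations)
    groups = [r.group for r in records]
    for b in range(n_permutations):
        shuffled = [dataclasses.replace(r, group=groups[int(j)])
                    for r, j in zip(records, rng.permutation(len(records)))]
        res = run_cv(fc_stack, shuffled, seed=seed + b + 1, **cv_kwargs)
        out[b] = res.report.accuracy[0]
    return out
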