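"""Model interpretation: node contributions, inattention correlation,
and their intersection.

Node contribution quantifies how much each ROI's connectivity drives
the classifier.  The primary mode is gradient saliency: for each
correctly classified held-out subject, the absolute gradient of the
case-minus-control logit margin with respect to the feature entries of
every selected edge is averaged over subjects and folds, summed over
each node's incident edges, and normalized to percentages.  A second,
literal mode sums absolute first-layer weights reaching each node's
feature entries, weighted by how often attention pooling retains the
node on held-out data.

The inattention analysis works in the case group only: per subject and
node, the absolute Fisher-Z values of incident selected edges are
summed separately for the case>control and case<control directions (so
strengthened and weakened connections cannot cancel), and each sum is
correlated with the inattention score.  Edge-level correlations use the
signed Fisher-Z value.  p-values are uncorrected by default (an
exploratory-screening choice); Benjamini-Hochberg FDR is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import FCMatrix
from .graph import build_graph
from .nn import LABEL_TO_CLASS, AttentionGCN
from .select import DifferentialEdgeSet

__all__ = ["ContributionTable", "AttentionCorrelation", "node_contributions",
           "attention_correlation", "intersect_discriminative"]


@dataclass
class ContributionTable:
    """Per-ROI classification-contribution percentages."""

    contributions: np.ndarray           # percent, sums to 100
    ranks: np.ndarray                   # 1 = largest contribution
    retained_frequency: np.ndarray      # pooling retention rate across folds
    roi_labels: list[str] | None = None
    threshold: float = 2.0

    def __post_init__(self):
        c = np.asarray(self.contributions, dtype=float)
        if np.any(c < 0) or abs(c.sum() - 100.0) > 1e-6:
            raise ValueError("contributions must be >= 0 and sum to 100")
        self.contributions = c

    @property
    def high_contribution_nodes(self) -> np.ndarray:
        """Nodes above the contribution threshold (percent)."""
        return np.flatnonzero(self.contributions > self.threshold)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.contributions)
        labels = self.roi_labels or [str(i) for i in range(n)]
        return pd.DataFrame({
            "roi": np.arange(n), "label": labels,
            "contribution_pct": self.contributions, "rank": self.ranks,
            "retained_freq": self.retained_frequency,
        }).sort_values("rank").reset_index(drop=True)


@dataclass
class AttentionCorrelation:
    """Correlation of directional node strength / edge values with the
    inattention score in the case group."""

    node_table: pd.DataFrame    # roi, direction, r, p, strength_mean
    edge_table: pd.DataFrame    # i, j, direction, r, p, sign
    p_threshold: float = 0.05
    fdr: bool = False

    @property
    def significant_edges(self) -> pd.DataFrame:
        return self.edge_table[self.edge_table["p"] < self.p_threshold]

    def edge_sign_counts(self) -> dict[str, int]:
        sig = self.significant_edges
        return {"total": len(sig),
                "positive": int((sig["sign"] > 0).sum()),
                "negative": int((sig["sign"] < 0).sum())}

    def significant_nodes(self) -> pd.DataFrame:
        return self.node_table[self.node_table["p"] < self.p_threshold]


def _pearson_columns(x: np.ndarray, Y: np.ndarray):
    """Pearson r and two-sided p of x against every column of Y."""
    n = len(x)
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((Yc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ Yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    valid = np.isfinite(r) & (sy > 0)
    p = np.ones_like(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1 - r ** 2))
    p[valid] = 2 * stats.t.sf(np.abs(t[valid]), n - 2)
    r[~valid] = np.nan
    return r, p


def node_contributions(cv_result, fc_stack: list[FCMatrix], records,
                       threshold: float = 2.0, mode: str = "saliency",
                       roi_labels=None) -> ContributionTable:
    """Aggregate per-fold trained models into a ContributionTable.

    mode="saliency": mean |d(margin)/d(edge feature entries)| over folds
    and correctly classified test subjects, summed to nodes.
    mode="weights": sum of |first-layer weight| rows per feature entry,
    weighted by the node's pooling-retention frequency on test data.
    If every importance is zero (e.g. a head that ignores features) the
    table falls back to the uniform distribution, by convention.
    """
    n_rois = fc_stack[0].n_rois
    node_imp = np.zeros(n_rois)
    retained = np.zeros(n_rois)
    retained_norm = 0
    groups = np.array([r.group for r in records])

    for fold, model in enumerate(cv_result.fold_models):
        if not isinstance(model, AttentionGCN):
            raise ValueError("node contributions require trained GCN fold models")
        if not model.loss_trace:
            raise ValueError("fold model has not been trained")
        mask = cv_result.fold_masks[fold]
        te = cv_result.folds.test_indices(records, fold)
        samples = [build_graph(fc_stack[i], mask, graph_index=i,
                               graph_label=records[i].group) for i in te]
        X = np.stack([s.node_features for s in samples])
        A = samples[0].adjacency()
        pred = model.predict(X, A)
        truth = np.array([LABEL_TO_CLASS[g] for g in groups[te]])

        if model.config.attention:
            _, cache = model.forward(X, A, cache=True)
            for b in range(len(te)):
                kept1 = cache["idx1"][b]
                np.add.at(retained, kept1, 1.0)
            retained_norm += len(te)
        else:
            retained += 1.0
            retained_norm += 1

        if mode == "saliency":
            correct = pred == truth
            if not np.any(correct):
                continue
            dX = model.input_saliency(X[correct], A)
            for (i, j) in mask.edge_pairs:
                imp = np.abs(dX[:, i, j]).mean() + np.abs(dX[:, j, i]).mean()
                node_imp[i] += imp
                node_imp[j] += imp
        elif mode == "weights":
            w_in = np.abs(model.params["W1"]).sum(axis=1)
            node_imp += w_in
        else:
            raise ValueError(f"unknown mode {mode!r}")

    retained_freq = retained / max(retained_norm, 1)
    if mode == "weights":
        node_imp = node_imp * retained_freq
    total = node_imp.sum()
    if total <= 0:
        warnings.warn("all importances zero; falling back to uniform contributions",
                      stacklevel=2)
        contrib = np.full(n_rois, 100.0 / n_rois)
    else:
        contrib = 100.0 * node_imp / total
    order = np.argsort(-contrib, kind="stable")
    ranks = np.empty(n_rois, dtype=int)
    ranks[order] = np.arange(1, n_rois + 1)
    return ContributionTable(contributions=contrib, ranks=ranks,
                             retained_frequency=retained_freq,
                             roi_labels=roi_labels, threshold=threshold)


def attention_correlation(fc_stack: list[FCMatrix], records,
                          mask: DifferentialEdgeSet, method: str = "pearson",
                          p_threshold: float = 0.05, fdr: bool = False,
                          roi_labels=None) -> AttentionCorrelation:
    """Correlate directional node strength and edge values with the
    inattention score, in the case group only."""
    idx = [k for k, r in enumerate(records)
           if r.group == "ADHD" and r.inattention is not None]
    if len(idx) < 3:
        raise ValueError("need at least 3 case subjects with inattention scores")
    scores = np.array([records[k].inattention for k in idx], dtype=float)
    if np.allclose(scores, scores[0]):
        raise ValueError("inattention scores have zero variance")
    if method == "spearman":
        scores = stats.rankdata(scores)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")

    n_rois = fc_stack[0].n_rois
    z = np.stack([fc_stack[k].values for k in idx])      # (n_case, R, R)

    directions = ("ADHD>TD", "ADHD<TD")
    S = np.zeros((len(idx), n_rois, 2))
    edge_rows = []
    pairs, dirs = [], []
    for e in mask.edges:
        i, j = e.edge
        d = directions.index(e.direction)
        S[:, i, d] += np.abs(z[:, i, j])
        S[:, j, d] += np.abs(z[:, i, j])
        pairs.append((i, j))
        dirs.append(e.direction)

    # edge-level correlations on signed z
    ev = np.stack([z[:, i, j] for (i, j) in pairs], axis=1) if pairs else np.zeros((len(idx), 0))
    if method == "spearman" and ev.size:
        ev = np.apply_along_axis(stats.rankdata, 0, ev)
    er, ep = _pearson_columns(scores, ev) if pairs else (np.array([]), np.array([]))
    if fdr and len(ep):
        from statsmodels.stats.multitest import multipletests

        ep = multipletests(ep, method="fdr_bh")[1]
    edge_df = pd.DataFrame({
        "i": [i for i, _ in pairs], "j": [j for _, j in pairs],
        "direction": dirs, "r": er, "p": ep, "sign": np.sign(er),
    })

    node_rows = []
    labels = roi_labels or [str(i) for i in range(n_rois)]
    for d, dname in enumerate(directions):
        Sv = S[:, :, d]
        if method == "spearman":
            Sv = np.apply_along_axis(stats.rankdata, 0, Sv)
        r, p = _pearson_columns(scores, Sv)
        if fdr:
            from statsmodels.stats.multitest import multipletests

            ok = np.isfinite(r)
            if ok.any():
                p[ok] = multipletests(p[ok], method="fdr_bh")[1]
        for roi in range(n_rois):
            node_rows.append({"roi": roi, "label": labels[roi], "direction": dname,
                              "r": r[roi], "p": p[roi],
                              "strength_mean": S[:, roi, d].mean()})
    node_df = pd.DataFrame(node_rows)
    return AttentionCorrelation(node_table=node_df, edge_table=edge_df,
                                p_threshold=p_threshold, fdr=fdr)


def intersect_discriminative(contrib: ContributionTable,
                             corr: AttentionCorrelation,
                             contrib_threshold: float = 2.0,
                             p_threshold: float = 0.05) -> pd.DataFrame:
    """Nodes that both contribute strongly to classification and
    correlate with inattention; tagged with correlation sign and the
    direction class of the most significant correlation."""
    high = set(np.flatnonzero(contrib.contributions > contrib_threshold).tolist())
    nt = corr.node_table
    sig = nt[(nt["p"] < p_threshold) & nt["roi"].isin(high)]
    rows = []
    for roi, grp in sig.groupby("roi"):
        best = grp.loc[grp["p"].idxmin()]
        rows.append({
            "roi": int(roi), "label": best["label"],
            "contribution_pct": contrib.contributions[int(roi)],
            "direction": best["direction"], "r": best["r"], "p": best["p"],
            "correlation_sign": "positive" if best["r"] > 0 else "negative",
        })
    return pd.DataFrame(rows, columns=["roi", "label", "contribution_pct",
                                       "direction", "r", "p", "correlation_sign"])
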