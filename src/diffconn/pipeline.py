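"""Model/Results facade over the full analysis.

``ConnectomeClassificationModel`` bundles the data (per-subject FC
matrices + phenotype records) with the analysis settings; ``fit()``
runs covariate-adjusted edge selection and cross-validated training of
the attention-pooled GCN (or a baseline) and returns a
``ConnectomeClassificationResults`` carrying fold metrics,
per-fold edge masks and trained states, with interpretation
(node contributions, inattention correlation, discriminative-region
intersection), plotting and export methods hanging off it.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evaluate, interpret, io as dcio, select as sel
from .atlas import aal116_labels
from .connectivity import fisher_z, pearson_fc
from .nn import ModelConfig

__all__ = ["ConnectomeClassificationModel", "ConnectomeClassificationResults"]


class ConnectomeClassificationModel:
    """Case-control connectome classification analysis.

    Parameters
    ----------
    fc_matrices : list of FCMatrix
        Per-subject Fisher-Z connectivity.
    records : list of SubjectRecord
        Phenotype rows aligned with ``fc_matrices``.
    p_threshold : float
        Edge-selection threshold on the two-sided p-value.
    covariates : sequence of str
        Nuisance covariates regressed out before the edge t-tests.
    classifier : {"agcn", "gcn", "svm"}
        Attention-pooled GCN (default), plain GCN, or RBF-SVM baseline.
    per_fold_selection : bool
        Re-estimate the edge mask inside each training fold (default)
        rather than once on the whole cohort.
    """

    def __init__(self, fc_matrices, records, p_threshold: float = 0.03,
                 covariates=sel.DEFAULT_COVARIATES,
                 model_config: ModelConfig | None = None,
                 classifier: str = "agcn", per_fold_selection: bool = True):
        if len(fc_matrices) != len(records):
            raise ValueError("fc_matrices and records length mismatch")
        self.fc_matrices = list(fc_matrices)
        self.records = list(records)
        self.p_threshold = p_threshold
        self.covariates = tuple(covariates)
        self.model_config = model_config or ModelConfig()
        self.classifier = classifier
        self.per_fold_selection = per_fold_selection

    # ------------------------------------------------------------ constructors

    @classmethod
    def from_time_series(cls, series_list, records, roi_labels=None, **kwargs):
        """Build FC matrices (Pearson + Fisher Z) from ROI time series."""
        labels = roi_labels
        if labels is None and len(series_list) and series_list[0].shape[0] == 116:
            labels = aal116_labels()
        fcs = [fisher_z(pearson_fc(ts), roi_labels=labels,
                        subject_id=r.subject_id)
               for ts, r in zip(series_list, records)]
        return cls(fcs, records, **kwargs)

    @classmethod
    def from_directory(cls, directory, **kwargs):
        """Load a cohort written by :func:`diffconn.synth.write_cohort`."""
        directory = pathlib.Path(directory)
        records = dcio.read_phenotype(directory / "phenotype.tsv")
        series = [dcio.read_series(directory / f"{r.subject_id}_timeseries.txt")
                  for r in records]
        return cls.from_time_series(series, records, **kwargs)

    # ------------------------------------------------------------------- fit

    def fit(self, scheme: str = "stratified-10-fold", k: int = 10, seed: int = 0):
        cv = evaluate.run_cv(
            self.fc_matrices, self.records, model_config=self.model_config,
            scheme=scheme, k=k, p_threshold=self.p_threshold,
            covariates=self.covariates, classifier=self.classifier,
            per_fold_selection=self.per_fold_selection, seed=seed,
        )
        return ConnectomeClassificationResults(self, cv, scheme)

    def select_whole_cohort(self):
        """Differential edges from the entire cohort (paper-literal mode);
        returns (DifferentialEdgeSet, all EdgeStat)."""
        return sel.differential_edges(self.fc_matrices, self.records,
                                      self.p_threshold, self.covariates)

    def sweep(self, p_grid=sel.P_GRID, **cv_kwargs):
        """Accuracy-vs-p curve (cross-validated) over the threshold grid."""
        return evaluate.accuracy_vs_p(
            self.fc_matrices, self.records, p_grid=p_grid,
            model_config=self.model_config, covariates=self.covariates,
            classifier=self.classifier,
            per_fold_selection=self.per_fold_selection, **cv_kwargs)


@dataclass
class ConnectomeClassificationResults:
    """Fitted-analysis container returned by ``fit()``."""

    model: ConnectomeClassificationModel
    cv: evaluate.CVResult
    scheme: str

    # -------------------------------------------------------------- metrics

    @property
    def metrics(self) -> evaluate.MetricReport:
        return self.cv.report

    def summary(self) -> str:
        rep = self.cv.report
        lines = [
            "Connectome classification results",
            "=" * 45,
            f"scheme:            {self.scheme} ({self.cv.folds.n_folds} folds)",
            f"classifier:        {self.model.classifier}",
            f"p threshold:       {self.model.p_threshold}",
            f"edges per fold:    {np.mean([len(m) for m in self.cv.fold_masks]):.1f} (mean)",
            f"covariates:        {', '.join(self.model.covariates)}",
            "-" * 45,
            f"sensitivity (%):   {rep.sensitivity[0]:6.2f} +- {rep.sensitivity[1]:.2f}",
            f"specificity (%):   {rep.specificity[0]:6.2f} +- {rep.specificity[1]:.2f}",
            f"accuracy (%):      {rep.accuracy[0]:6.2f} +- {rep.accuracy[1]:.2f}",
        ]
        return "\n".join(lines)

    def per_site_table(self) -> pd.DataFrame:
        """Leave-one-site-out style table: one row per fold/site."""
        rows = []
        site_of_fold = {}
        for r in self.model.records:
            site_of_fold.setdefault(self.cv.folds.fold_of_subject[r.subject_id], r.site)
        for f, stats_ in enumerate(self.cv.report.per_fold):
            rows.append({"fold": f,
                         "site": site_of_fold.get(f, "") if self.scheme == "leave-one-site-out" else "",
                         "SEN": stats_["sensitivity"], "SPE": stats_["specificity"],
                         "ACC": stats_["accuracy"]})
        return pd.DataFrame(rows)

    # -------------------------------------------------------- interpretation

    def node_contributions(self, threshold: float = 2.0, mode: str = "saliency"):
        labels = self.model.fc_matrices[0].roi_labels
        return interpret.node_contributions(
            self.cv, self.model.fc_matrices, self.model.records,
            threshold=threshold, mode=mode, roi_labels=labels)

    def attention_correlation(self, mask=None, **kwargs):
        if mask is None:
            mask, _ = self.model.select_whole_cohort()
        labels = self.model.fc_matrices[0].roi_labels
        return interpret.attention_correlation(
            self.model.fc_matrices, self.model.records, mask,
            roi_labels=labels, **kwargs)

    def discriminative_regions(self, contrib_threshold: float = 2.0,
                               p_threshold: float = 0.05, mode: str = "saliency"):
        contrib = self.node_contributions(threshold=contrib_threshold, mode=mode)
        corr = self.attention_correlation(p_threshold=p_threshold)
        return interpret.intersect_discriminative(contrib, corr,
                                                  contrib_threshold, p_threshold)

    # ---------------------------------------------------------------- output

    def export_brainnet(self, directory, contrib_threshold: float = 2.0):
        """Write .node/.edge files: contribution-sized nodes and the
        signed mean group-difference on selected edges."""
        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        contrib = self.node_contributions(threshold=contrib_threshold)
        mask, stats_ = self.model.select_whole_cohort()
        n = self.model.fc_matrices[0].n_rois
        diff = np.zeros((n, n))
        for e in mask.edges:
            i, j = e.edge
            diff[i, j] = diff[j, i] = e.mean_diff
        dcio.write_node_file(directory / "contribution.node",
                             sizes=contrib.contributions,
                             colors=(contrib.contributions > contrib_threshold) + 1,
                             labels=contrib.roi_labels)
        dcio.write_edge_file(directory / "differential.edge", diff)
        return directory

    def plot_loss(self, ax=None):
        """Smoothed per-fold training-loss traces."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for f, m in enumerate(self.cv.fold_models):
            if hasattr(m, "smoothed_loss_trace"):
                ax.plot(m.smoothed_loss_trace(), label=f"fold {f}")
        ax.set_xlabel("epoch")
        ax.set_ylabel("training loss (running min)")
        ax.legend(fontsize="small")
        return ax
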