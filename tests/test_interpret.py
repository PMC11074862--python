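"""Interpretation: node contributions, inattention correlation, intersection."""

import numpy as np
import pandas as pd
import pytest

from diffconn.connectivity import FCMatrix
from diffconn.evaluate import run_cv
from diffconn.interpret import (AttentionCorrelation, ContributionTable,
                                attention_correlation, intersect_discriminative,
                                node_contributions)
from diffconn.nn import ModelConfig
from diffconn.select import DifferentialEdgeSet, EdgeStat
from tests.test_select import make_record


def edge_set(pairs, directions=None):
    directions = directions or ["ADHD>TD"] * len(pairs)
    return DifferentialEdgeSet(
        edges=[EdgeStat(edge=(i, j), t_stat=3.0, p_value=0.01, p_tail=0.005,
                        direction=d, mean_diff=0.2 if d == "ADHD>TD" else -0.2)
               for (i, j), d in zip(pairs, directions)],
        p_threshold=0.03)


def case_stack(rng, n_subj=30, n_rois=8):
    recs, fcs = [], []
    for s in range(n_subj):
        a = rng.normal(0.3, 0.15, size=(n_rois, n_rois))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 0.0)
        fcs.append(FCMatrix(values=m))
        recs.append(make_record(f"s{s}", "ADHD", inattention=0.0))
    return recs, fcs


class TestNodeContributions:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted(planted_cohort):
        res = run_cv(planted_cohort["fcs"], planted_cohort["records"],
                     model_config=ModelConfig(epochs=40, seed=0), k=4,
                     p_threshold=0.03, seed=2)
        return res

    def test_normalization_and_rank_permutation(self, fitted, planted_cohort):
        ct = node_contributions(fitted, planted_cohort["fcs"],
                                planted_cohort["records"])
        assert ct.contributions.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(ct.contributions >= 0)
        assert sorted(ct.ranks) == list(range(1, 61))

    def test_planted_hubs_rank_highly(self, fitted, planted_cohort):
        ct = node_contributions(fitted, planted_cohort["fcs"],
                                planted_cohort["records"])
        top10 = set(np.argsort(-ct.contributions, kind="stable")[:10].tolist())
        hubs = set(planted_cohort["hubs"].tolist())
        assert len(top10 & hubs) / len(hubs) >= 0.5

    def test_weight_mode_also_favours_hubs(self, fitted, planted_cohort):
        ct = node_contributions(fitted, planted_cohort["fcs"],
                                planted_cohort["records"], mode="weights")
        assert ct.contributions.sum() == pytest.approx(100.0, abs=1e-6)
        hubs = planted_cohort["hubs"]
        med = np.median(ct.contributions)
        assert np.mean(ct.contributions[hubs] > med) >= 0.5

    def test_zero_weight_model_falls_back_to_uniform(self, fitted,
                                                     planted_cohort):
        import copy

        res = copy.copy(fitted)
        res.fold_models = [copy.deepcopy(m) for m in fitted.fold_models]
        for m in res.fold_models:
            for k in m.params:
                m.params[k] = np.zeros_like(m.params[k])
        with pytest.warns(UserWarning, match="uniform"):
            ct = node_contributions(res, planted_cohort["fcs"],
                                    planted_cohort["records"])
        assert np.allclose(ct.contributions, 100.0 / 60)

    def test_untrained_model_rejected(self, planted_cohort, fitted):
        import copy

        from diffconn.nn import AttentionGCN

        res = copy.copy(fitted)
        res.fold_models = [AttentionGCN(60, ModelConfig())
                           for _ in fitted.fold_models]
        with pytest.raises(ValueError, match="train"):
            node_contributions(res, planted_cohort["fcs"],
                               planted_cohort["records"])


class TestAttentionCorrelation:
    def test_exact_linear_score_gives_r_one(self, rng):
        recs, fcs = case_stack(rng)
        mask = edge_set([(3, 5), (3, 6)])
        for r, fc in zip(recs, fcs):
            r.inattention = float(abs(fc.values[3, 5]) + abs(fc.values[3, 6]))
        corr = attention_correlation(fcs, recs, mask)
        row = corr.node_table.query("roi == 3 and direction == 'ADHD>TD'").iloc[0]
        assert row.r == pytest.approx(1.0, abs=1e-10)
        assert row.p < 1e-10

    def test_directional_sums_conserve_total_strength(self, rng):
        recs, fcs = case_stack(rng)
        mask = edge_set([(0, 1), (0, 2), (0, 3)],
                        ["ADHD>TD", "ADHD<TD", "ADHD>TD"])
        for r, fc in zip(recs, fcs):
            r.inattention = float(rng.normal())
        corr = attention_correlation(fcs, recs, mask)
        nt = corr.node_table
        s_up = nt.query("roi == 0 and direction == 'ADHD>TD'").strength_mean.iloc[0]
        s_dn = nt.query("roi == 0 and direction == 'ADHD<TD'").strength_mean.iloc[0]
        total = np.mean([abs(fc.values[0, 1]) + abs(fc.values[0, 2])
                         + abs(fc.values[0, 3]) for fc in fcs])
        assert s_up + s_dn == pytest.approx(total, abs=1e-12)

    def test_edge_r_matches_brute_force(self, rng):
        recs, fcs = case_stack(rng)
        mask = edge_set([(1, 4), (2, 6)])
        for r in recs:
            r.inattention = float(rng.normal(18, 4))
        corr = attention_correlation(fcs, recs, mask)
        scores = np.array([r.inattention for r in recs])
        for _, row in corr.edge_table.iterrows():
            vals = np.array([fc.values[int(row.i), int(row.j)] for fc in fcs])
            mx, my = vals.mean(), scores.mean()
            r_bf = (((vals - mx) * (scores - my)).sum()
                    / np.sqrt(((vals - mx) ** 2).sum()
                              * ((scores - my) ** 2).sum()))
            assert row.r == pytest.approx(r_bf, abs=1e-10)
            assert row["sign"] == np.sign(row.r)

    def test_constant_scores_rejected(self, rng):
        recs, fcs = case_stack(rng)
        corr_mask = edge_set([(0, 1)])
        with pytest.raises(ValueError, match="zero variance"):
            attention_correlation(fcs, recs, corr_mask)

    def test_too_few_cases_rejected(self, rng):
        recs, fcs = case_stack(rng, n_subj=4)
        for r in recs[:2]:
            r.inattention = None
        with pytest.raises(ValueError, match="at least 3"):
            attention_correlation(fcs, recs, edge_set([(0, 1)]))

    def test_fdr_never_shrinks_p(self, rng):
        recs, fcs = case_stack(rng)
        mask = edge_set([(0, 1), (2, 3), (4, 5), (1, 6)])
        for r in recs:
            r.inattention = float(rng.normal(18, 4))
        raw = attention_correlation(fcs, recs, mask, fdr=False)
        adj = attention_correlation(fcs, recs, mask, fdr=True)
        assert np.all(adj.edge_table.p.values >= raw.edge_table.p.values - 1e-12)

    def test_spearman_mode_runs(self, rng):
        recs, fcs = case_stack(rng)
        mask = edge_set([(0, 1)])
        for r in recs:
            r.inattention = float(rng.normal(18, 4))
        corr = attention_correlation(fcs, recs, mask, method="spearman")
        assert np.isfinite(corr.edge_table.p.iloc[0])


def contrib_table(percents):
    c = np.asarray(percents, dtype=float)
    c = 100.0 * c / c.sum()
    order = np.argsort(-c, kind="stable")
    ranks = np.empty(len(c), dtype=int)
    ranks[order] = np.arange(1, len(c) + 1)
    return ContributionTable(contributions=c, ranks=ranks,
                             retained_frequency=np.ones(len(c)))


def corr_table(n_rois, sig_rois, r=0.5):
    rows = []
    for roi in range(n_rois):
        rows.append({"roi": roi, "label": str(roi), "direction": "ADHD>TD",
                     "r": r if roi in sig_rois else 0.01,
                     "p": 0.001 if roi in sig_rois else 0.9,
                     "strength_mean": 1.0})
    return AttentionCorrelation(node_table=pd.DataFrame(rows),
                                edge_table=pd.DataFrame(
                                    columns=["i", "j", "direction", "r", "p", "sign"]))


class TestIntersection:
    def test_disjoint_sets_give_empty_result(self):
        ct = contrib_table([96, 1, 1, 1, 1, 0])      # only node 0 above 5%
        corr = corr_table(6, sig_rois={3})           # node 3 correlated
        out = intersect_discriminative(ct, corr, contrib_threshold=5.0)
        assert out.empty

    def test_planted_intersection_recovered_exactly(self):
        # after normalization nodes 2 and 9 hold 45% each, others 1.25%
        ct = contrib_table([1, 1, 36, 1, 1, 1, 1, 1, 1, 36])
        corr = corr_table(10, sig_rois={2, 9, 4})
        out = intersect_discriminative(ct, corr, contrib_threshold=2.0,
                                       p_threshold=0.05)
        assert sorted(out.roi.tolist()) == [2, 9]
        assert set(out.correlation_sign) == {"positive"}

    def test_no_filtering_keeps_all_correlated_contributors(self):
        ct = contrib_table([5, 5, 5, 5])
        corr = corr_table(4, sig_rois={0, 1, 2, 3})
        out = intersect_discriminative(ct, corr, contrib_threshold=0.0,
                                       p_threshold=1.0)
        assert sorted(out.roi.tolist()) == [0, 1, 2, 3]
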