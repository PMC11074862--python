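"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

from diffconn.connectivity import fisher_z, pearson_fc
from diffconn.synth import SynthConfig, hub_planted_edges, simulate_cohort


def cohort_fcs(records, series):
    return [fisher_z(pearson_fc(ts), subject_id=r.subject_id)
            for ts, r in zip(series, records)]


@pytest.fixture(scope="session")
def planted_cohort():
    """Small case-control cohort with hub-planted group effects."""
    edges, hubs = hub_planted_edges(n_rois=60, n_hubs=4, edges_per_hub=6,
                                    delta_z=0.35, seed=3)
    cfg = SynthConfig(n_subjects=80, n_rois=60, n_timepoints=120,
                      planted_edges=edges, seed=5)
    records, series, truth = simulate_cohort(cfg, return_truth=True)
    return {
        "cfg": cfg, "records": records, "series": series, "truth": truth,
        "fcs": cohort_fcs(records, series), "hubs": hubs,
        "planted": {(i, j) for i, j, _ in edges},
    }


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no group effects at all."""
    cfg = SynthConfig(n_subjects=60, n_rois=40, n_timepoints=100, seed=17,
                      site_offsets=(0.0,) * 4)
    records, series = simulate_cohort(cfg)
    return {"cfg": cfg, "records": records, "series": series,
            "fcs": cohort_fcs(records, series)}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
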