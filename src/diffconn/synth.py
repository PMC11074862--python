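"""Synthetic rs-fMRI cohort generator.

Emulates the statistical structure a case-control connectome analysis
assumes: ~460 subjects over 4 acquisition sites, 116 ROIs with ~150
retained volumes each, group-differential edges of configurable
Fisher-Z effect size, additive site offsets, covariate confounding, and
an inattention score linearly coupled to each case's planted connection
strength.

Each subject's ROI time series are drawn from a zero-mean multivariate
Gaussian whose correlation matrix is the inverse Fisher-Z of that
subject's target Z-matrix, projected to the nearest valid correlation
matrix.  The sample Pearson correlation of the series therefore equals
the target in expectation, so every downstream stage (FC construction,
edge selection, classification, attribution) sees data with known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.correlation_tools import corr_clipped

__all__ = ["SynthConfig", "SubjectRecord", "CohortTruth", "simulate_cohort",
           "write_cohort", "hub_planted_edges", "calibrate_attention_noise"]

MOTION_COLUMNS = ("rot_x", "rot_y", "rot_z", "trans_x", "trans_y", "trans_z")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic cohort.

    planted_edges are (i, j, delta_z) triples with i < j: the Fisher-Z
    group effect added to cases on that edge.  site_offsets is one
    additive Fisher-Z shift per site, applied to every edge.
    covariate_effects maps a covariate name (age, sex, handedness,
    mean_fd, rot_x..trans_z) to an edge-wise Fisher-Z slope per unit of
    the (centred) covariate.  attention_coupling is the slope linking a
    case's planted connection strength (sum of |z| over planted edges)
    to the inattention score; noise_sd is the score's residual SD.
    subject_sd is the SD of a per-case latent severity added to every
    planted edge's delta (shared within subject), which is what makes
    connection strength — and through it the score — vary across cases.
    """

    n_subjects: int = 460
    n_rois: int = 116
    n_timepoints: int = 150
    n_sites: int = 4
    prop_cases: float = 0.5
    planted_edges: tuple[tuple[int, int, float], ...] = ()
    site_offsets: tuple[float, ...] | None = None
    site_proportions: tuple[float, ...] | None = None
    covariate_effects: dict[str, float] = field(default_factory=dict)
    attention_coupling: float = 0.5
    noise_sd: float = 3.0
    subject_sd: float = 0.15
    base_z_mean: float = 0.2
    base_z_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prop_cases < 1:
            raise ValueError("prop_cases must lie strictly in (0, 1)")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for (i, j, _dz) in self.planted_edges:
            if not (0 <= i < j < self.n_rois):
                raise ValueError(
                    f"planted edge ({i}, {j}) must satisfy 0 <= i < j < n_rois={self.n_rois}"
                )
        if self.site_offsets is not None and len(self.site_offsets) != self.n_sites:
            raise ValueError("site_offsets must have one entry per site")
        if self.site_proportions is not None:
            props = np.asarray(self.site_proportions, dtype=float)
            if len(props) != self.n_sites or not np.isclose(props.sum(), 1.0):
                raise ValueError("site_proportions must have n_sites entries summing to 1")

    def resolved_site_offsets(self) -> np.ndarray:
        if self.site_offsets is not None:
            return np.asarray(self.site_offsets, dtype=float)
        if self.n_sites == 1:
            return np.zeros(1)
        # modest default site effect, centred at zero
        return np.linspace(-0.05, 0.05, self.n_sites)

    def site_names(self) -> list[str]:
        return [f"SITE{k + 1:02d}" for k in range(self.n_sites)]


@dataclass
class SubjectRecord:
    """One phenotype row."""

    subject_id: str
    group: str  # "ADHD" or "TD"
    site: str
    age: float
    sex: int
    handedness: int
    mean_fd: float
    motion: tuple[float, ...]  # six realignment-parameter summaries
    inattention: float | None  # missing (None) for TD subjects

    def covariate_value(self, name: str) -> float:
        if name in MOTION_COLUMNS:
            return self.motion[MOTION_COLUMNS.index(name)]
        return float(getattr(self, name))


@dataclass
class CohortTruth:
    """Ground truth retained for tests and calibration checks."""

    base_z: np.ndarray                 # shared background Z matrix (n_rois, n_rois)
    planted_edges: tuple[tuple[int, int, float], ...]
    severity: np.ndarray               # per-subject latent severity (0 for TD)
    planted_strength: np.ndarray       # per-subject sum of |realized z| over planted edges
    target_z: np.ndarray | None        # realized (n_subjects, n_rois, n_rois) if kept

    @property
    def planted_nodes(self) -> np.ndarray:
        nodes = sorted({i for i, _, _ in self.planted_edges} | {j for _, j, _ in self.planted_edges})
        return np.asarray(nodes, dtype=int)


def hub_planted_edges(n_rois: int = 116, n_hubs: int = 6, edges_per_hub: int = 10,
                      delta_z: float = 0.3, seed: int = 0):
    """Planted edges concentrated on hub ROIs.

    Group effects in case-control connectomes cluster on a handful of
    regions rather than scattering uniformly, so the default planted
    layout picks ``n_hubs`` hub ROIs and gives each ``edges_per_hub``
    partners.  Returns ``(edges, hub_indices)``.
    """
    rng = np.random.default_rng(seed)
    hubs = rng.choice(n_rois, size=n_hubs, replace=False)
    edges, used = [], set()
    for h in hubs:
        partners = rng.choice([k for k in range(n_rois) if k != h],
                              size=edges_per_hub, replace=False)
        for p in partners:
            i, j = (int(min(h, p)), int(max(h, p)))
            if (i, j) not in used:
                used.add((i, j))
                edges.append((i, j, delta_z))
    return tuple(edges), np.sort(hubs)


def calibrate_attention_noise(cfg: SynthConfig, hub: int,
                              target_r: float = 0.6) -> float:
    """Inattention noise SD giving a chosen true correlation.

    The score couples to a case's total realized planted strength P; a
    hub's measured directional strength is S = S_real + measurement
    noise with per-edge Fisher-Z variance 1/(T-3).  The generator's own
    realized strengths (deterministic given cfg.seed) supply Var(S_real),
    Var(P) and their covariance, and solving

        corr(S_real + m, coupling*P + eps) = target_r

    for eps's SD gives the required noise.  Raises if the target exceeds
    what measurement noise allows.  Re-simulating the same config with
    the returned ``noise_sd`` leaves everything but the scores unchanged.
    """
    records, _, truth = simulate_cohort(cfg, return_truth=True, keep_target_z=True)
    case = np.array([rec.group == "ADHD" for rec in records])
    if case.sum() < 3:
        raise ValueError("too few case subjects to calibrate against")
    deg = sum(1 for i, j, _ in cfg.planted_edges if hub in (i, j))
    if deg == 0:
        raise ValueError(f"node {hub} has no planted edges")
    s_real = np.zeros(int(case.sum()))
    for (i, j, _dz) in cfg.planted_edges:
        if hub in (i, j):
            s_real += np.abs(truth.target_z[case][:, i, j])
    p_real = truth.planted_strength[case]
    c = cfg.attention_coupling
    var_m = deg / (cfg.n_timepoints - 3)
    var_s = float(np.var(s_real))
    var_p = float(np.var(p_real))
    cov_sp = float(np.cov(s_real, p_real)[0, 1])
    rhs = (c * cov_sp) ** 2 / (target_r ** 2 * (var_s + var_m))
    if rhs <= c ** 2 * var_p:
        raise ValueError(f"target correlation {target_r} unattainable: "
                         "measurement noise alone caps it lower")
    return float(np.sqrt(rhs - c ** 2 * var_p))


def _nearest_correlation(mat: np.ndarray) -> np.ndarray:
    """Project a symmetric matrix to a valid correlation matrix.

    Eigenvalue clipping with unit-diagonal rescaling: cheap, and close
    enough to the Higham projection that planted edge values are
    perturbed by far less than sampling noise at the cohort sizes used.
    """
    return corr_clipped(mat, threshold=1e-4)


def simulate_cohort(
    cfg: SynthConfig, return_truth: bool = False, keep_target_z: bool = False
):
    """Draw a synthetic cohort.

    Returns ``(records, series)`` — or ``(records, series, truth)`` when
    ``return_truth`` — where ``series`` is a list of (n_rois,
    n_timepoints) arrays.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n, r = cfg.n_subjects, cfg.n_rois
    if n < 1:
        raise ValueError("n_subjects must be positive")
    site_names = cfg.site_names()
    site_offsets = cfg.resolved_site_offsets()
    props = (
        np.full(cfg.n_sites, 1.0 / cfg.n_sites)
        if cfg.site_proportions is None
        else np.asarray(cfg.site_proportions, dtype=float)
    )

    # Shared background connectivity: a random Wishart-factor correlation
    # mixture a*C0 + mean_r*J + cushion*I whose off-diagonal entries have
    # approximately the configured mean/SD once mapped to Fisher-Z, while
    # staying positive definite by construction (eigenvalues >= cushion).
    # An i.i.d. background of this strength would be far from PD and the
    # projection would distort every edge; the factor construction keeps
    # the projection a no-op in the common case.
    mean_r = np.tanh(cfg.base_z_mean)
    sd_r = cfg.base_z_sd * (1 - mean_r ** 2)   # delta method, z -> r
    cushion = 0.1
    a = 1.0 - mean_r - cushion
    if a <= 0:
        raise ValueError("base_z_mean too large for a valid background correlation")
    nu = max(8, int(round((a / max(sd_r, 1e-9)) ** 2)))
    loadings = rng.standard_normal((r, nu))
    w = loadings @ loadings.T / nu
    d = np.sqrt(np.diag(w))
    c0 = w / np.outer(d, d)
    base_r = a * c0 + mean_r * np.ones((r, r)) + cushion * np.eye(r)
    off = ~np.eye(r, dtype=bool)
    base_z = np.zeros((r, r))
    base_z[off] = np.arctanh(np.clip(base_r[off], -0.999, 0.999))

    groups = np.where(rng.random(n) < cfg.prop_cases, "ADHD", "TD")
    sites = rng.choice(cfg.n_sites, size=n, p=props)
    age = rng.uniform(8.0, 15.0, size=n)
    sex = rng.integers(0, 2, size=n)
    handed = (rng.random(n) < 0.9).astype(int)
    mean_fd = np.abs(rng.normal(0.15, 0.05, size=n))
    motion = rng.normal(0.0, 0.05, size=(n, 6))
    severity = np.where(groups == "ADHD", rng.normal(0.0, cfg.subject_sd, size=n), 0.0)

    cov_values = {
        "age": age, "sex": sex.astype(float), "handedness": handed.astype(float),
        "mean_fd": mean_fd,
        **{name: motion[:, k] for k, name in enumerate(MOTION_COLUMNS)},
    }
    for name in cfg.covariate_effects:
        if name not in cov_values:
            raise ValueError(f"unknown covariate in covariate_effects: {name!r}")

    records: list[SubjectRecord] = []
    series: list[np.ndarray] = []
    planted_strength = np.zeros(n)
    target_store = np.zeros((n, r, r)) if keep_target_z else None

    off_diag = ~np.eye(r, dtype=bool)
    for s in range(n):
        z = base_z.copy()
        z[off_diag] += site_offsets[sites[s]]
        for name, slope in cfg.covariate_effects.items():
            centred = cov_values[name][s] - cov_values[name].mean()
            z[off_diag] += slope * centred
        if groups[s] == "ADHD":
            for (i, j, dz) in cfg.planted_edges:
                z[i, j] += dz + severity[s]
                z[j, i] = z[i, j]

        corr = np.tanh(z)
        np.fill_diagonal(corr, 1.0)
        corr = _nearest_correlation(corr)
        # ground truth is the realized correlation structure actually
        # sampled from (the projection can attenuate strong planted
        # stars, and downstream estimators see the realized network)
        z_real = np.zeros_like(corr)
        z_real[off_diag] = np.arctanh(np.clip(corr[off_diag], -0.999999, 0.999999))
        planted_strength[s] = sum(abs(z_real[i, j]) for i, j, _ in cfg.planted_edges)
        if target_store is not None:
            target_store[s] = z_real
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(r))
        ts = chol @ rng.standard_normal((r, cfg.n_timepoints))
        series.append(ts)

        if groups[s] == "ADHD":
            score = cfg.attention_coupling * planted_strength[s] + rng.normal(0.0, cfg.noise_sd)
            score = float(18.0 + score)  # clinically plausible offset for a rating-scale score
        else:
            score = None
        records.append(SubjectRecord(
            subject_id=f"sub-{s + 1:04d}",
            group=str(groups[s]),
            site=site_names[sites[s]],
            age=float(age[s]),
            sex=int(sex[s]),
            handedness=int(handed[s]),
            mean_fd=float(mean_fd[s]),
            motion=tuple(float(v) for v in motion[s]),
            inattention=score,
        ))

    if return_truth:
        truth = CohortTruth(
            base_z=base_z, planted_edges=cfg.planted_edges, severity=severity,
            planted_strength=planted_strength, target_z=target_store,
        )
        return records, series, truth
    return records, series


def write_cohort(records, series, directory) -> list:
    """Write a cohort to ``directory``: phenotype.tsv + one series file per subject.

    Formats match :mod:`diffconn.io`; returns the list of paths written.
    """
    from . import io as dcio  # local import to avoid cycle at module load

    if len(records) == 0:
        raise ValueError("cannot write an empty cohort")
    if len(records) != len(series):
        raise ValueError("records and series must have equal length")
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = [dcio.write_phenotype(records, directory / "phenotype.tsv")]
    for rec, ts in zip(records, series):
        p = directory / f"{rec.subject_id}_timeseries.txt"
        dcio.write_series(ts, p)
        paths.append(p)
    return paths
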