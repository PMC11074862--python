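"""Per-subject functional-connectivity networks from ROI time series.

FC is the sample Pearson correlation between each pair of ROI time
series, variance-stabilized by the Fisher Z transform z = atanh(r).
Self-connections are uninformative, so the diagonal of every FCMatrix
is fixed at 0 (rather than atanh(1) = inf).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["FCMatrix", "BinaryNetwork", "pearson_fc", "fisher_z", "binarize", "node_degree"]


@dataclass
class FCMatrix:
    """Symmetric Fisher-Z connectivity matrix for one subject."""

    values: np.ndarray
    roi_labels: list[str] | None = None
    subject_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FCMatrix values must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("FCMatrix values must be symmetric")
        if not np.all(np.isfinite(v)):
            raise ValueError("FCMatrix values must be finite")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class BinaryNetwork:
    """Binarized network with the rule that produced it."""

    adjacency: np.ndarray
    threshold_spec: str

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not np.all(np.isin(a, (0, 1))):
            raise ValueError("adjacency entries must be 0/1")
        if np.any(np.diag(a) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = a.astype(np.int8)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


def pearson_fc(series: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of ROI time series (rows = ROIs)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError("series must be 2-D (n_rois, n_timepoints)")
    if x.shape[1] < 3:
        raise ValueError(f"need at least 3 time points, got {x.shape[1]}")
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"constant time series for ROI index(es) {dead.tolist()}")
    corr = np.corrcoef(x)
    # guard against fp spill past [-1, 1]
    return np.clip(corr, -1.0, 1.0)


def fisher_z(corr: np.ndarray, roi_labels=None, subject_id: str = "") -> FCMatrix:
    """Fisher Z transform of a correlation matrix; diagonal set to 0."""
    r = np.asarray(corr, dtype=float)
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0):
        bad = np.argwhere((np.abs(r) >= 1.0) & off)[0]
        raise ValueError(
            f"|r| = 1 between ROIs {bad[0]} and {bad[1]}: degenerate pair, "
            "Fisher Z undefined"
        )
    z = np.zeros_like(r)
    z[off] = np.arctanh(r[off])
    return FCMatrix(values=z, roi_labels=roi_labels, subject_id=subject_id)


def binarize(fc: FCMatrix, rule: str = "absolute", *, cutoff: float | None = None,
             density: float | None = None, mask: np.ndarray | None = None) -> BinaryNetwork:
    """Binarize an FC matrix into a BinaryNetwork.

    rule:
      - ``"absolute"``: keep edges with |z| >= cutoff.
      - ``"density"``: keep the top round(d * n(n-1)/2) edges by |z|;
        ties broken by (i, j) lexicographic order.
      - ``"mask"``: keep exactly the edges of a boolean/0-1 matrix
        (e.g. a differential-edge mask from the selection stage).
    """
    z = fc.values
    n = z.shape[0]
    adj = np.zeros((n, n), dtype=np.int8)
    iu = np.triu_indices(n, k=1)

    if rule == "absolute":
        if cutoff is None:
            raise ValueError("absolute rule requires a cutoff")
        keep = np.abs(z[iu]) >= cutoff
        spec = f"absolute |z| >= {cutoff}"
    elif rule == "density":
        if density is None or not 0 < density <= 1:
            raise ValueError("density must lie in (0, 1]")
        m = len(iu[0])
        k = int(round(density * m))
        w = np.abs(z[iu])
        # sort by (-weight, i, j): deterministic tie-break
        order = np.lexsort((iu[1], iu[0], -w))
        keep = np.zeros(m, dtype=bool)
        keep[order[:k]] = True
        spec = f"proportional density {density}"
    elif rule == "mask":
        if mask is None:
            raise ValueError("mask rule requires a mask matrix")
        mask = np.asarray(mask)
        if mask.shape != z.shape:
            raise ValueError("mask shape must match FC matrix")
        keep = mask[iu].astype(bool)
        spec = "differential-edge mask"
    else:
        raise ValueError(f"unknown binarization rule {rule!r}")

    adj[iu[0][keep], iu[1][keep]] = 1
    adj = adj + adj.T
    if adj.sum() == 0:
        warnings.warn("binarization produced an empty network", stacklevel=2)
    return BinaryNetwork(adjacency=adj, threshold_spec=spec)


def node_degree(net: BinaryNetwork) -> np.ndarray:
    """Per-ROI degree (row sums of the adjacency)."""
    return net.adjacency.sum(axis=1).astype(int)
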