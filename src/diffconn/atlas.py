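"""AAL116 atlas metadata: region labels and stand-in coordinates.

The Automated Anatomical Labeling atlas (116 regions: 90 cerebral, 26
cerebellar/vermal) defines the nodes of every network in this package.
Only the region *names* and their conventional ordering are needed for
analysis; spatial coordinates are used solely for BrainNet-Viewer-style
``.node`` exports.
"""

from __future__ import annotations

import numpy as np

# Cerebral regions come in left/right pairs in standard AAL order.
_CEREBRAL_PAIRS = [
    "Precentral", "Frontal_Sup", "Frontal_Sup_Orb", "Frontal_Mid",
    "Frontal_Mid_Orb", "Frontal_Inf_Oper", "Frontal_Inf_Tri",
    "Frontal_Inf_Orb", "Rolandic_Oper", "Supp_Motor_Area", "Olfactory",
    "Frontal_Sup_Medial", "Frontal_Med_Orb", "Rectus", "Insula",
    "Cingulum_Ant", "Cingulum_Mid", "Cingulum_Post", "Hippocampus",
    "ParaHippocampal", "Amygdala", "Calcarine", "Cuneus", "Lingual",
    "Occipital_Sup", "Occipital_Mid", "Occipital_Inf", "Fusiform",
    "Postcentral", "Parietal_Sup", "Parietal_Inf", "SupraMarginal",
    "Angular", "Precuneus", "Paracentral_Lobule", "Caudate", "Putamen",
    "Pallidum", "Thalamus", "Heschl", "Temporal_Sup",
    "Temporal_Pole_Sup", "Temporal_Mid", "Temporal_Pole_Mid",
    "Temporal_Inf",
]

_CEREBELLAR_PAIRS = [
    "Cerebelum_Crus1", "Cerebelum_Crus2", "Cerebelum_3", "Cerebelum_4_5",
    "Cerebelum_6", "Cerebelum_7b", "Cerebelum_8", "Cerebelum_9",
    "Cerebelum_10",
]

_VERMIS = [
    "Vermis_1_2", "Vermis_3", "Vermis_4_5", "Vermis_6", "Vermis_7",
    "Vermis_8", "Vermis_9", "Vermis_10",
]


def aal116_labels() -> list[str]:
    """Return the 116 AAL region labels in standard atlas order."""
    labels: list[str] = []
    for name in _CEREBRAL_PAIRS + _CEREBELLAR_PAIRS:
        labels.append(f"{name}_L")
        labels.append(f"{name}_R")
    labels.extend(_VERMIS)
    assert len(labels) == 116
    return labels


def synthetic_centroids(n_rois: int = 116) -> np.ndarray:
    """Deterministic synthetic stand-in region coordinates (n_rois, 3).

    These are NOT the true AAL MNI centroids (which require the atlas
    volume, not shipped here); they are synthetic placeholder positions
    laid out on a sphere so that exported ``.node`` files are
    geometrically valid for viewers.  Replace with real centroids via
    the ``coords`` argument of :func:`diffconn.io.write_node_file` for
    anatomical figures.
    """
    idx = np.arange(n_rois, dtype=float)
    # Fibonacci sphere: evenly spread, deterministic, no RNG involved.
    golden = (1 + 5 ** 0.5) / 2
    theta = 2 * np.pi * idx / golden
    z = 1 - 2 * (idx + 0.5) / n_rois
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts * 70.0  # scale to roughly brain-sized mm
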