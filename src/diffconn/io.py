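"""Plain-text readers and writers for every artifact the pipeline touches.

Phenotype tables are tab-separated with "NA" for missing values; time
series and FC matrices are whitespace-delimited numeric text;
BrainNet-Viewer-style ``.node`` / ``.edge`` files are emitted for
visualization in external tools.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from .atlas import aal116_labels, synthetic_centroids
from .connectivity import FCMatrix
from .synth import MOTION_COLUMNS, SubjectRecord

__all__ = [
    "write_phenotype", "read_phenotype", "write_series", "read_series",
    "write_fc", "read_fc", "write_edge_stats", "write_mask",
    "write_node_file", "write_edge_file",
]

PHENO_COLUMNS = ("subject_id", "group", "site", "age", "sex", "handedness",
                 "mean_fd") + MOTION_COLUMNS + ("inattention",)


def write_phenotype(records: list[SubjectRecord], path) -> pathlib.Path:
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id, "group": r.group, "site": r.site,
            "age": r.age, "sex": r.sex, "handedness": r.handedness,
            "mean_fd": r.mean_fd,
            **dict(zip(MOTION_COLUMNS, r.motion)),
            "inattention": r.inattention,
        }
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(PHENO_COLUMNS))
    path = pathlib.Path(path)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")
    return path


def read_phenotype(path) -> list[SubjectRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        inatt = row["inattention"]
        records.append(SubjectRecord(
            subject_id=str(row["subject_id"]), group=str(row["group"]),
            site=str(row["site"]), age=float(row["age"]), sex=int(row["sex"]),
            handedness=int(row["handedness"]), mean_fd=float(row["mean_fd"]),
            motion=tuple(float(row[c]) for c in MOTION_COLUMNS),
            inattention=None if pd.isna(inatt) else float(inatt),
        ))
    return records


def write_series(series: np.ndarray, path) -> pathlib.Path:
    path = pathlib.Path(path)
    np.savetxt(path, np.asarray(series), fmt="%.10g")
    return path


def read_series(path) -> np.ndarray:
    arr = np.loadtxt(path)
    if arr.ndim != 2:
        raise ValueError(f"time-series file {path} is not a 2-D matrix")
    return arr


def write_fc(fc: FCMatrix, path) -> pathlib.Path:
    """FC matrix as whitespace-delimited text with a sidecar label file."""
    path = pathlib.Path(path)
    np.savetxt(path, fc.values, fmt="%.10g")
    if fc.roi_labels is not None:
        path.with_suffix(path.suffix + ".labels").write_text(
            "\n".join(fc.roi_labels) + "\n")
    return path


def read_fc(path, subject_id: str = "") -> FCMatrix:
    path = pathlib.Path(path)
    vals = np.loadtxt(path)
    sidecar = path.with_suffix(path.suffix + ".labels")
    labels = sidecar.read_text().split() if sidecar.exists() else None
    return FCMatrix(values=vals, roi_labels=labels, subject_id=subject_id)


def write_edge_stats(edge_stats, path) -> pathlib.Path:
    df = pd.DataFrame([{
        "roi_i": e.edge[0], "roi_j": e.edge[1], "t": e.t_stat, "p": e.p_value,
        "p_tail": e.p_tail, "direction": e.direction, "mean_diff": e.mean_diff,
    } for e in edge_stats])
    path = pathlib.Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    return path


def write_mask(mask_matrix: np.ndarray, path) -> pathlib.Path:
    path = pathlib.Path(path)
    np.savetxt(path, np.asarray(mask_matrix, dtype=int), fmt="%d")
    return path


def write_node_file(path, sizes, colors=None, coords=None, labels=None) -> pathlib.Path:
    """BrainNet-Viewer ``.node`` file: x y z color size label per row.

    Default coordinates are the synthetic stand-in positions from
    :func:`diffconn.atlas.synthetic_centroids` (NOT true MNI centroids);
    pass real centroids for anatomical rendering.
    """
    sizes = np.asarray(sizes, dtype=float)
    n = len(sizes)
    coords = synthetic_centroids(n) if coords is None else np.asarray(coords)
    colors = np.ones(n) if colors is None else np.asarray(colors, dtype=float)
    labels = labels or (aal116_labels() if n == 116 else [f"ROI{i}" for i in range(n)])
    path = pathlib.Path(path)
    with path.open("w") as fh:
        for k in range(n):
            x, y, z = coords[k]
            fh.write(f"{x:.2f}\t{y:.2f}\t{z:.2f}\t{colors[k]:g}\t{sizes[k]:g}\t{labels[k]}\n")
    return path


def write_edge_file(path, matrix: np.ndarray) -> pathlib.Path:
    """BrainNet-Viewer ``.edge`` file (square matrix, signed weights
    allowed so positive and negative edges stay distinguishable)."""
    path = pathlib.Path(path)
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.6g")
    return path
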