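"""Embedding differential connectomes as graph-classification samples.

Every subject shares one topology — the binary differential-edge mask —
while node features carry the subject's own connectivity: node i's
feature vector is the subject's Fisher-Z row i restricted to i's own
selected edges (zeros elsewhere), i.e. the rows of the masked
differential connectivity, so feature length always equals the ROI
count and every non-zero entry is a group-differential connection.
Two alternative feature modes are available: "incident" keeps all
columns of ROIs incident to any selected edge, and "full" keeps the
unmasked row.  A batch is the standard disjoint union with node
indices offset per graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import FCMatrix
from .select import DifferentialEdgeSet

__all__ = ["GraphSample", "BatchedGraphs", "build_graph", "batch_graphs", "unbatch_graphs"]


@dataclass
class GraphSample:
    """One subject's embedded graph."""

    edge_list: np.ndarray        # (2, n_directed_edges), both directions present
    node_labels: np.ndarray      # ROI identity per node, 0..n_rois-1
    node_features: np.ndarray    # (n_nodes, feature_len)
    graph_label: str             # "ADHD" or "TD"
    graph_index: int             # subject ordinal

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=np.int8)
        a[self.edge_list[0], self.edge_list[1]] = 1
        return a


@dataclass
class BatchedGraphs:
    """Disjoint union of equally sized graphs."""

    node_features: np.ndarray    # (n_graphs * n_nodes, feature_len)
    edge_list: np.ndarray        # (2, total_directed_edges), offset per graph
    labels: np.ndarray           # per-graph label strings
    graph_indices: np.ndarray    # per-graph original ordinals
    n_nodes_per_graph: int

    @property
    def n_graphs(self) -> int:
        return len(self.labels)


def build_graph(fc: FCMatrix, mask: DifferentialEdgeSet, graph_index: int = 0,
                graph_label: str = "", feature_mode: str = "edges",
                full_rows: bool = False) -> GraphSample:
    """Embed one subject using the shared differential-edge mask.

    feature_mode:
      - ``"edges"`` (default): node i's features are the Fisher-Z values
        of i's own selected edges, zeros elsewhere — the rows of the
        masked differential connectivity.
      - ``"incident"``: node i's full row restricted to columns of ROIs
        incident to any selected edge.
      - ``"full"``: the unmasked Fisher-Z row (also via ``full_rows``).
    """
    n = fc.n_rois
    if len(mask) == 0:
        raise ValueError(
            "differential-edge mask is empty: no edges survived selection; "
            "try a larger p threshold"
        )
    if full_rows:
        feature_mode = "full"
    pairs = np.asarray(mask.edge_pairs)
    if pairs.max() >= n:
        raise ValueError("mask ROI indices exceed FC matrix size")
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    order = np.lexsort((dst, src))
    edge_list = np.stack([src[order], dst[order]])

    if feature_mode == "edges":
        feats = fc.values * mask.mask(n)
    elif feature_mode == "incident":
        feats = fc.values.copy()
        keep = np.zeros(n, dtype=bool)
        keep[mask.incident_nodes] = True
        feats[:, ~keep] = 0.0
    elif feature_mode == "full":
        feats = fc.values.copy()
    else:
        raise ValueError(f"unknown feature_mode {feature_mode!r}")
    return GraphSample(
        edge_list=edge_list,
        node_labels=np.arange(n),
        node_features=feats,
        graph_label=graph_label,
        graph_index=graph_index,
    )


def batch_graphs(samples: list[GraphSample]) -> BatchedGraphs:
    """Disjoint-union batch; node k of graph g gets global index g*N + k."""
    if not samples:
        raise ValueError("cannot batch an empty sample list")
    n = samples[0].n_nodes
    flen = samples[0].node_features.shape[1]
    for s in samples:
        if s.n_nodes != n or s.node_features.shape[1] != flen:
            raise ValueError("heterogeneous node counts or feature lengths")
    feats = np.concatenate([s.node_features for s in samples], axis=0)
    edges = np.concatenate(
        [s.edge_list + g * n for g, s in enumerate(samples)], axis=1
    )
    return BatchedGraphs(
        node_features=feats,
        edge_list=edges,
        labels=np.asarray([s.graph_label for s in samples]),
        graph_indices=np.asarray([s.graph_index for s in samples]),
        n_nodes_per_graph=n,
    )


def unbatch_graphs(batch: BatchedGraphs) -> list[GraphSample]:
    """Inverse of :func:`batch_graphs` (exact round trip)."""
    n = batch.n_nodes_per_graph
    out = []
    for g in range(batch.n_graphs):
        sel = (batch.edge_list[0] >= g * n) & (batch.edge_list[0] < (g + 1) * n)
        el = batch.edge_list[:, sel] - g * n
        if el.size and (el.min() < 0 or el.max() >= n):
            raise AssertionError("batch mixes edges across graph boundaries")
        out.append(GraphSample(
            edge_list=el,
            node_labels=np.arange(n),
            node_features=batch.node_features[g * n:(g + 1) * n].copy(),
            graph_label=str(batch.labels[g]),
            graph_index=int(batch.graph_indices[g]),
        ))
    return out
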