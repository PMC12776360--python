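"""Similarity-graph construction over one modality's embeddings.

Entities within a modality are connected when the Euclidean distance between
their embeddings does not exceed a threshold tau: E = {(i,k) : i != k,
S[i,k] <= tau}.  The threshold can be given as an absolute distance or as a
percentile of the off-diagonal distance distribution (the default in the
run configuration, since absolute distances depend on the provenance and
scale of the embeddings).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Set, Tuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import EmbeddingMatrix

__all__ = ["SimilarityGraph", "pairwise_distances", "build_graph", "graph_stats",
           "write_edge_list"]


@dataclass
class SimilarityGraph:
    node_ids: List[str]
    edges: Set[Tuple[int, int]]          # unordered pairs stored as i < k
    distance_matrix: np.ndarray
    threshold: float

    def __post_init__(self):
        n = len(self.node_ids)
        if self.distance_matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match node count")
        for i, k in self.edges:
            if not (0 <= i < n and 0 <= k < n):
                raise ValueError(f"edge ({i},{k}) out of range for {n} nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def adjacency(self, include_self: bool = False) -> np.ndarray:
        """Boolean adjacency; optionally with self-loops on the diagonal."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for i, k in self.edges:
            a[i, k] = a[k, i] = True
        if include_self:
            np.fill_diagonal(a, True)
        return a

    def neighbors(self, i: int) -> List[int]:
        return sorted(
            {k for (a, k) in self.edges if a == i} | {a for (a, k) in self.edges if k == i}
        )


def pairwise_distances(emb: EmbeddingMatrix) -> np.ndarray:
    """Symmetric Euclidean distance matrix with zero diagonal."""
    if emb.n_entities == 1:
        return np.zeros((1, 1))
    return squareform(pdist(emb.values, metric="euclidean"))


def _resolve_threshold(dist: np.ndarray, threshold_spec) -> float:
    if "absolute" in threshold_spec:
        tau = float(threshold_spec["absolute"])
        if tau < 0:
            raise ValueError(f"absolute threshold must be nonnegative, got {tau}")
        return tau
    if "percentile" in threshold_spec:
        pct = float(threshold_spec["percentile"])
        if not 0 < pct <= 100:
            raise ValueError(f"percentile must be in (0, 100], got {pct}")
        n = dist.shape[0]
        if n < 2:
            return 0.0
        off_diag = dist[np.triu_indices(n, k=1)]
        return float(np.percentile(off_diag, pct))
    raise ValueError("threshold_spec must contain 'absolute' or 'percentile'")


def build_graph(
    emb: EmbeddingMatrix,
    threshold_spec,
    normalize: bool = False,
) -> SimilarityGraph:
    """Build the thresholded similarity graph for one modality.

    Parameters
    ----------
    threshold_spec : dict
        Either ``{"absolute": tau}`` or ``{"percentile": p}`` with p in
        (0, 100]; the percentile is taken over off-diagonal distances.
    normalize : bool
        If True, rows are L2-normalized before distances are computed.
    """
    if normalize:
        norms = np.linalg.norm(emb.values, axis=1, keepdims=True)
        emb = EmbeddingMatrix(
            emb.ids, emb.values / np.maximum(norms, 1e-12), emb.modality
        )
    dist = pairwise_distances(emb)
    tau = _resolve_threshold(dist, threshold_spec)
    n = dist.shape[0]
    iu, ku = np.triu_indices(n, k=1)
    keep = dist[iu, ku] <= tau
    edges = {(int(i), int(k)) for i, k in zip(iu[keep], ku[keep])}
    return SimilarityGraph(list(emb.ids), edges, dist, tau)


def graph_stats(g: SimilarityGraph) -> dict:
    degrees = np.zeros(g.n_nodes, dtype=int)
    for i, k in g.edges:
        degrees[i] += 1
        degrees[k] += 1
    return {
        "n_nodes": g.n_nodes,
        "n_edges": len(g.edges),
        "mean_degree": float(degrees.mean()) if g.n_nodes else 0.0,
        "n_isolated": int((degrees == 0).sum()),
    }


def write_edge_list(g: SimilarityGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("i\tk\tdistance\n")
        for i, k in sorted(g.edges):
            fh.write(f"{i}\t{k}\t{g.distance_matrix[i, k]:.6g}\n")
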