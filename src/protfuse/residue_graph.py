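"""Residue-level graphs: one-hot node features, KNN edges on CA distances.

Nodes are residues, features are a 21-way one-hot over the 20 standard amino
acids plus an unknown bucket.  Edges connect each residue to its k nearest
neighbours by alpha-carbon Euclidean distance (default k=5) and are then
symmetrized to an undirected set — the construction depends only on pairwise
distances, so it is invariant under any rigid motion of the structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .fixtures import AMINO_ACIDS
from .structures import ProteinStructure, alpha_carbon_coords

__all__ = [
    "ResidueGraph",
    "one_hot_encode",
    "pairwise_ca_distance",
    "knn_edges",
    "build_residue_graph",
    "write_graph_tsv",
]

N_CLASSES = 21  # 20 standard amino acids + unknown


@dataclass(frozen=True)
class ResidueGraph:
    """Undirected, unweighted residue graph with one-hot node features."""

    node_features: np.ndarray          # (n_nodes, 21) binary
    edges: frozenset                   # frozenset of frozenset({i, j}) pairs
    n_nodes: int

    def edge_array(self) -> np.ndarray:
        """Edges as a sorted (n_edges, 2) int array with i < j."""
        pairs = sorted(tuple(sorted(e)) for e in self.edges)
        return np.array(pairs, dtype=int).reshape(-1, 2)

    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency without self-loops."""
        A = np.zeros((self.n_nodes, self.n_nodes))
        for e in self.edges:
            i, j = tuple(e)
            A[i, j] = A[j, i] = 1.0
        return A

    def degrees(self) -> np.ndarray:
        return self.adjacency().sum(axis=1).astype(int)


def one_hot_encode(sequence: str) -> np.ndarray:
    """(N, 21) binary matrix; letters outside the 20 standard AAs hit column 20."""
    if not sequence:
        raise ValueError("sequence must be nonempty")
    X = np.zeros((len(sequence), N_CLASSES))
    for i, ch in enumerate(sequence):
        j = AMINO_ACIDS.find(ch)
        X[i, j if j >= 0 else 20] = 1.0
    return X


def pairwise_ca_distance(coords: np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix over CA coordinates (Angstrom)."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2 or coords.shape[1] != 3:
        raise ValueError("need at least 2 finite 3D coordinates")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    return squareform(pdist(coords))


def knn_edges(coords: np.ndarray, k: int) -> frozenset:
    """Symmetrized k-nearest-neighbour edge set over coordinates.

    Each node selects its k nearest neighbours (self excluded; distance ties
    broken by lower index); the directed selections are unioned into an
    undirected set, so an edge exists if either endpoint selected the other.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    D = pairwise_ca_distance(coords)
    np.fill_diagonal(D, np.inf)
    # stable argsort: equal distances resolve to the smaller index
    order = np.argsort(D, axis=1, kind="stable")
    edges = set()
    for i in range(n):
        for j in order[i, :k]:
            edges.add(frozenset((i, int(j))))
    return frozenset(edges)


def build_residue_graph(s: ProteinStructure, k: int = 5) -> ResidueGraph:
    """Residue graph of a structure: one-hot features + CA-distance KNN edges.

    k is capped at n_residues - 1 for very small structures.
    """
    coords = alpha_carbon_coords(s)
    n = coords.shape[0]
    if n < 2:
        raise ValueError(f"{s.id}: need >= 2 CA residues to build a graph")
    if len(s.sequence) != n:
        raise ValueError("sequence length does not match CA count")
    k_eff = min(k, n - 1)
    return ResidueGraph(
        node_features=one_hot_encode(s.sequence),
        edges=knn_edges(coords, k_eff),
        n_nodes=n,
    )


def write_graph_tsv(g: ResidueGraph, edge_path, feature_path) -> None:
    """Dump edges as 2-column TSV and node features as CSV, for inspection."""
    np.savetxt(edge_path, g.edge_array(), fmt="%d", delimiter="\t")
    np.savetxt(feature_path, g.node_features, fmt="%d", delimiter=",")
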