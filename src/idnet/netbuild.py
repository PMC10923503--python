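"""From identifiability scores to weighted and binary functional networks.

Link weight is ``1 - score``: the lower the classification score of a pair,
the more their dynamics are shared, hence the stronger the functional
connection.  Binarisation is *proportional*: each network keeps a fixed
number of the strongest links, so networks compared across groups or
conditions all have identical link density (constant network cost).  Any
strictly decreasing transform of the scores yields the same binary networks;
``1 - score`` is fixed for reporting purposes only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .errors import DataError, ParameterError
from .identifiability import IdentifiabilityMatrix


@dataclass
class WeightedNetwork:
    """Symmetric weighted adjacency over named nodes (zero diagonal)."""

    nodes: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.nodes)
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (n, n):
            raise DataError("weight matrix shape does not match node count")
        if not np.all(np.isfinite(w)):
            raise DataError("weights must be finite")
        if not np.allclose(w, w.T):
            raise DataError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise DataError("weight diagonal must be zero")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def edge_ranking(self) -> list[tuple[int, int]]:
        """All node pairs sorted by decreasing weight; ties in lexicographic
        (i, j) order so thresholding is deterministic and nested."""
        pairs = list(itertools.combinations(range(self.n_nodes), 2))
        return sorted(pairs, key=lambda ij: (-self.weights[ij], ij[0], ij[1]))


@dataclass
class BinaryNetwork:
    """0/1 adjacency with named nodes.

    ``density`` is the realised link fraction; ``target_density`` (when set)
    is the grid value the network was thresholded at — the two differ by at
    most one-link rounding, and curves are indexed by the grid value.
    """

    nodes: list[str]
    adjacency: np.ndarray
    target_density: float | None = None

    def __post_init__(self) -> None:
        n = len(self.nodes)
        a = np.asarray(self.adjacency)
        if a.shape != (n, n):
            raise DataError("adjacency shape does not match node count")
        if not np.array_equal(a, a.T):
            raise DataError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise DataError("adjacency diagonal must be zero")
        if not np.isin(a, (0, 1)).all():
            raise DataError("adjacency entries must be 0 or 1")
        self.adjacency = a.astype(int)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.adjacency.sum() / (n * (n - 1)) if n > 1 else 0.0

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def edges(self) -> list[tuple[str, str]]:
        idx = np.argwhere(np.triu(self.adjacency, 1))
        return [(self.nodes[i], self.nodes[j]) for i, j in idx]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        return g

    def save_edge_list(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        lines = ["node_a\tnode_b"] + [f"{a}\t{b}" for a, b in self.edges()]
        path.write_text("\n".join(lines) + "\n")
        return path

    def save_graphml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        nx.write_graphml(self.to_networkx(), path)
        return path


def weights_from_scores(matrix: IdentifiabilityMatrix) -> WeightedNetwork:
    """Weighted functional network: weight = 1 - identifiability score."""
    scores = matrix.scores
    n = len(matrix.channels)
    off = ~np.eye(n, dtype=bool)
    if np.any(~np.isfinite(scores[off])):
        raise DataError("identifiability matrix has missing off-diagonal entries")
    w = 1.0 - scores
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(nodes=list(matrix.channels), weights=w)


def binarize_proportional(w: WeightedNetwork, density: float) -> BinaryNetwork:
    """Keep exactly ``round(density * N(N-1)/2)`` strongest links.

    Ties at the cutoff are resolved by lexicographic node order, so the edge
    set at a lower density is always nested within that at a higher one.
    """
    if not 0 < density <= 1:
        raise ParameterError(f"density {density} outside (0, 1]")
    n = w.n_nodes
    n_possible = n * (n - 1) // 2
    k = int(round(density * n_possible))
    if k == 0:
        raise ParameterError(
            f"density {density} keeps zero links on {n} nodes; increase it"
        )
    adj = np.zeros((n, n), dtype=int)
    for i, j in w.edge_ranking()[:k]:
        adj[i, j] = adj[j, i] = 1
    return BinaryNetwork(nodes=list(w.nodes), adjacency=adj, target_density=float(density))


#: default density grid: low-to-mid densities where thresholded networks are
#: informative (very dense networks converge to the complete graph)
DEFAULT_DENSITIES = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))


def density_sweep(
    w: WeightedNetwork, grid: Sequence[float] = DEFAULT_DENSITIES
) -> list[BinaryNetwork]:
    """One binary network per density; edge sets are nested along the grid."""
    grid = list(grid)
    if grid != sorted(grid):
        raise ParameterError("density grid must be sorted ascending")
    return [binarize_proportional(w, d) for d in grid]
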