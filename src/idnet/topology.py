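"""Topological metrics of binary functional networks.

Eight metrics characterise each thresholded network: transitivity, global
efficiency, degree assortativity, information content, maximum degree,
rich-club coefficient, Louvain modularity and nestedness.  Metrics that are
undefined for a given graph (assortativity on a degree-regular graph, rich
club with fewer than two qualifying nodes, ...) evaluate to ``nan`` — the
explicit undefined marker used throughout — never to a silent zero.

Standard metrics are delegated to networkx; information content, rich club
and nestedness are computed here (see the individual docstrings for the
exact conventions).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import AlignmentError
from .netbuild import BinaryNetwork

#: undefined-value marker
UNDEFINED = float("nan")


def transitivity(net: BinaryNetwork) -> float:
    """3 x triangles / connected triples; nan for fewer than 3 nodes."""
    if net.n_nodes < 3:
        return UNDEFINED
    return float(nx.transitivity(net.to_networkx()))


def global_efficiency(net: BinaryNetwork) -> float:
    """Mean of 1/d_ij over node pairs, 1/inf = 0 for disconnected pairs."""
    if net.n_nodes < 2:
        return UNDEFINED
    return float(nx.global_efficiency(net.to_networkx()))


def assortativity(net: BinaryNetwork) -> float:
    """Pearson correlation of the degrees at either end of each link.

    nan when there is no link or all link-endpoint degrees are equal
    (zero variance).
    """
    if net.n_edges == 0:
        return UNDEFINED
    deg = net.degrees()
    ii, jj = np.nonzero(np.triu(net.adjacency, 1))
    # each undirected link contributes both orderings, as in the standard
    # degree-degree correlation over directed stubs
    x = np.concatenate([deg[ii], deg[jj]]).astype(float)
    y = np.concatenate([deg[jj], deg[ii]]).astype(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return UNDEFINED
    return float(np.corrcoef(x, y)[0, 1])


def max_degree(net: BinaryNetwork) -> float:
    """Degree of the most connected node."""
    if net.n_nodes == 0:
        return 0.0
    return float(net.degrees().max())


def rich_club(net: BinaryNetwork, k: int) -> float:
    """Rich-club coefficient phi(k): link density among nodes of degree > k.

    nan when fewer than two nodes exceed degree k.
    """
    deg = net.degrees()
    rich = np.nonzero(deg > k)[0]
    m = len(rich)
    if m < 2:
        return UNDEFINED
    sub = net.adjacency[np.ix_(rich, rich)]
    return float(sub.sum() / (m * (m - 1)))


def rich_club_curve(net: BinaryNetwork) -> dict[int, float]:
    """phi(k) for every k from 0 to the maximum degree."""
    kmax = int(max_degree(net))
    return {k: rich_club(net, k) for k in range(kmax + 1)}


def rich_club_at_median_degree(net: BinaryNetwork) -> float:
    """Scalar rich-club summary used in density-sweep curves.

    phi evaluated at k = floor(median degree); a single-number convention
    for plotting phi against density (the curve over k remains available
    via :func:`rich_club_curve`).
    """
    if net.n_nodes == 0:
        return UNDEFINED
    k = int(math.floor(float(np.median(net.degrees()))))
    return rich_club(net, k)


def _partition_modularity(net: BinaryNetwork, communities: list[set[int]]) -> float:
    """Direct Newman Q = sum_c (e_c - a_c^2) over within-community edge and
    degree fractions."""
    adj = net.adjacency
    two_m = adj.sum()
    deg = net.degrees()
    q = 0.0
    for comm in communities:
        idx = sorted(comm)
        q += adj[np.ix_(idx, idx)].sum() / two_m - (deg[idx].sum() / two_m) ** 2
    return float(q)


def modularity_louvain(
    net: BinaryNetwork, seed: int = 0, n_restarts: int = 5
) -> tuple[float, list[set[str]] | None]:
    """Best Louvain modularity over seeded restarts, with the partition.

    Uses the igraph multilevel (Louvain) implementation, seeded per restart;
    Q of the returned partition is recomputed directly from the adjacency.
    Returns (nan, None) for a graph without links.
    """
    import random

    import igraph as ig

    if net.n_edges == 0:
        return UNDEFINED, None
    label_of = dict(enumerate(net.nodes))
    edges = [
        (int(i), int(j)) for i, j in np.argwhere(np.triu(net.adjacency, 1))
    ]
    g = ig.Graph(n=net.n_nodes, edges=edges)
    best_q, best_part = -np.inf, None
    try:
        for r in range(n_restarts):
            ig.set_random_number_generator(random.Random(seed + r))
            clustering = g.community_multilevel()
            comms = [set(map(int, c)) for c in clustering]
            q = _partition_modularity(net, comms)
            if q > best_q:
                best_q, best_part = q, comms
    finally:
        ig.set_random_number_generator(random)
    return float(best_q), [{label_of[i] for i in c} for c in best_part]


def modularity(net: BinaryNetwork, seed: int = 0) -> float:
    return modularity_louvain(net, seed)[0]


def nestedness(net: BinaryNetwork) -> float:
    """NODF-style nestedness of the symmetric adjacency, scaled 0-100.

    For every unordered node pair the two neighbourhoods are compared with
    the mutual link (if any) excluded — on a symmetric adjacency with an
    empty diagonal this is the only comparison under which one adjacent
    node's neighbourhood can fully contain another's.  The pair ordered so
    the larger residual neighbourhood comes first contributes
    ``100 * |overlap| / |smaller|``; pairs whose smaller residual
    neighbourhood is empty carry no information and are skipped.  The value
    is the mean contribution: 100 for a perfectly nested neighbourhood
    chain, 0 when no compared neighbourhoods overlap.  nan for a graph
    without links.
    """
    if net.n_edges == 0:
        return UNDEFINED
    adj = net.adjacency.astype(bool)
    n = net.n_nodes
    contributions = []
    for i, j in itertools.combinations(range(n), 2):
        a = adj[i].copy()
        b = adj[j].copy()
        a[j] = False
        b[i] = False
        ka, kb = int(a.sum()), int(b.sum())
        if min(ka, kb) == 0:
            continue
        if ka < kb:
            a, b = b, a
            ka, kb = kb, ka
        contributions.append(100.0 * np.sum(a & b) / kb)
    if not contributions:
        return UNDEFINED
    return float(np.mean(contributions))


def information_content(net: BinaryNetwork) -> float:
    """Information (bits) needed to encode the adjacency given row regularities.

    The adjacency matrix is encoded row by row: one root row is stored
    verbatim (``n - 1`` bits) and every other row as a difference from some
    already-encoded row, paying ``log2(m+1) + log2(C(m, d))`` bits — the
    number of differing entries, then which entries differ — where the two
    rows are compared over the other ``m = n - 2`` nodes.  The cheapest such
    encoding order is the minimum spanning tree of the pairwise
    difference-cost graph, whose total weight is unique even under cost
    ties, making the value deterministic and invariant under node
    relabelling.  Regular topologies (complete, empty, modular) have many
    identical rows and compress to the minimum; random-like structures pay
    for every difference.
    """
    n = net.n_nodes
    if n < 2:
        return UNDEFINED
    if n == 2:
        return 1.0  # root row only
    adj = net.adjacency.astype(bool)
    # Hamming distance over the other nodes' columns: full-row distance
    # minus the two mutual positions (diagonal is always zero)
    full = (adj[:, None, :] != adj[None, :, :]).sum(axis=2)
    d = full - 2 * net.adjacency
    m = n - 2
    log_comb = np.array([math.log2(math.comb(m, k)) for k in range(m + 1)])
    cost = math.log2(m + 1) + log_comb[d]
    np.fill_diagonal(cost, 0.0)
    from scipy.sparse.csgraph import minimum_spanning_tree

    mst = minimum_spanning_tree(np.triu(cost, 1))
    return float((n - 1) + mst.sum())


@dataclass
class MetricCurve:
    """A topological metric as a function of link density."""

    metric_name: str
    densities: list[float]
    values: list[float]
    group: str = ""
    condition: str = "all"
    band: str = "broadband"

    def __post_init__(self) -> None:
        if len(self.densities) != len(self.values):
            raise AlignmentError("densities and values differ in length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "condition": self.condition,
                "band": self.band,
                "metric": self.metric_name,
                "density": self.densities,
                "value": self.values,
            }
        )


#: metric registry: name -> callable(net, seed)
ALL_METRICS: dict[str, Callable[[BinaryNetwork, int], float]] = {
    "transitivity": lambda net, seed: transitivity(net),
    "global_efficiency": lambda net, seed: global_efficiency(net),
    "assortativity": lambda net, seed: assortativity(net),
    "information_content": lambda net, seed: information_content(net),
    "max_degree": lambda net, seed: max_degree(net),
    "rich_club": lambda net, seed: rich_club_at_median_degree(net),
    "modularity": lambda net, seed: modularity(net, seed),
    "nestedness": lambda net, seed: nestedness(net),
}


def metric_curves(
    nets: Sequence[BinaryNetwork],
    metrics: Sequence[str] | None = None,
    seed: int = 0,
    group: str = "",
    condition: str = "all",
    band: str = "broadband",
) -> list[MetricCurve]:
    """One curve per metric over a density sweep; undefined points stay nan."""
    if not nets:
        raise AlignmentError("empty density sweep")
    if metrics is None:
        metrics = list(ALL_METRICS)
    densities = [
        net.target_density if net.target_density is not None else net.density
        for net in nets
    ]
    curves = []
    for name in metrics:
        fn = ALL_METRICS[name]
        values = [fn(net, seed) for net in nets]
        curves.append(
            MetricCurve(name, list(densities), values, group, condition, band)
        )
    return curves


def curves_to_frame(curves: Sequence[MetricCurve]) -> pd.DataFrame:
    """Long-format table (group, condition, band, density, metric, value)."""
    return pd.concat([c.to_frame() for c in curves], ignore_index=True)
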