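"""Structural measures of episode networks.

Global clustering is the average of the local clustering coefficients over
all nodes (nodes of degree < 2 contribute 0), i.e. the mean probability
that two neighbours of a node are themselves connected.  Average path
length is the mean shortest-path distance over unordered distinct node
pairs.  Degree statistics come as an exact histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .netconstruct import EpisodeNetwork

__all__ = ["MeasureReport", "global_clustering", "average_path_length",
           "degree_histogram", "measure"]


@dataclass
class MeasureReport:
    """Summary measures of one episode network."""

    n_nodes: int
    n_edges: int
    global_clustering: float
    avg_path_length: float
    degree_histogram: np.ndarray  # counts indexed by degree
    max_degree: int
    mean_degree: float

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["degree_histogram"] = list(map(int, self.degree_histogram))
        return d


def _as_graph(net) -> nx.Graph:
    if isinstance(net, EpisodeNetwork):
        return net.graph()
    if isinstance(net, nx.Graph):
        return net
    raise TypeError("expected EpisodeNetwork or networkx.Graph")


def global_clustering(net) -> float:
    """Average local clustering coefficient over all nodes."""
    g = _as_graph(net)
    if g.number_of_nodes() < 1:
        raise ValueError("empty graph")
    return nx.average_clustering(g, count_zeros=True)


def average_path_length(net) -> float:
    """Mean shortest-path distance over unordered distinct node pairs."""
    g = _as_graph(net)
    if g.number_of_nodes() < 2:
        raise ValueError("average path length needs at least 2 nodes")
    if not nx.is_connected(g):
        raise ValueError("graph is disconnected; path length undefined")
    return nx.average_shortest_path_length(g)


def degree_histogram(net) -> tuple[np.ndarray, int, float]:
    """Exact degree counts, the maximal degree, and the mean degree 2|E|/n."""
    g = _as_graph(net)
    counts = np.asarray(nx.degree_histogram(g), dtype=int)
    if counts.size == 0:
        counts = np.zeros(1, dtype=int)
    max_degree = counts.size - 1
    mean_degree = 2.0 * g.number_of_edges() / g.number_of_nodes()
    return counts, max_degree, mean_degree


def measure(net) -> MeasureReport:
    """All reported measures of one network in a single record."""
    g = _as_graph(net)
    counts, max_deg, mean_deg = degree_histogram(g)
    return MeasureReport(
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        global_clustering=global_clustering(g),
        avg_path_length=average_path_length(g) if g.number_of_nodes() > 1 else np.nan,
        degree_histogram=counts,
        max_degree=max_deg,
        mean_degree=mean_deg,
    )
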