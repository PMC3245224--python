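"""Episode-network construction by greedy descending-weight edge addition.

The network is the *maximal connected component*: starting from an empty
graph on all episodes, edges are added one at a time in descending order of
similarity, and the construction stops the moment the graph first becomes
connected.  The result is exactly the shortest prefix of the sorted edge
list that connects all nodes.  Unlike a maximum spanning tree, an edge that
closes a cycle is still added if its weight comes up before connectivity is
reached, so the network need not be a tree.

The greedy stopping weight equals the minimum edge weight of the maximum
spanning tree (the bottleneck weight); :func:`maximum_spanning_tree` is
provided for that contrast and as a testing oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from networkx.utils import UnionFind

from .exceptions import CannotConnectError
from .similarity import SimilarityMatrix

__all__ = ["EpisodeNetwork", "maximal_connected_component", "maximum_spanning_tree"]


@dataclass
class EpisodeNetwork:
    """An undirected, unweighted, connected graph on episode indices.

    ``trace`` records (i, j, weight) in edge-addition order;
    ``stopping_weight`` is the weight of the final, connectivity-completing
    edge.
    """

    n_nodes: int
    edges: list = field(default_factory=list)
    trace: list = field(default_factory=list)
    stopping_weight: float = np.nan

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def graph(self) -> nx.Graph:
        """The network as a :class:`networkx.Graph` (nodes 0..n-1)."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.edges)
        return g


def _sorted_edge_list(S) -> tuple[np.ndarray, int]:
    """Upper-triangle edges sorted by descending weight, ties by ascending (i, j)."""
    vals = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
        raise ValueError("similarity matrix must be square")
    n = vals.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not np.all(np.isfinite(vals)):
        raise ValueError("similarity matrix must be finite")
    if not np.allclose(vals, vals.T):
        raise ValueError("similarity matrix must be symmetric")
    ii, jj = np.triu_indices(n, k=1)
    ww = vals[ii, jj]
    order = np.lexsort((jj, ii, -ww))
    return np.column_stack([ii[order], jj[order], ww[order]]), n


def maximal_connected_component(S) -> EpisodeNetwork:
    """Greedy construction: add edges in descending weight until connected.

    Parameters
    ----------
    S : SimilarityMatrix or (n, n) array
        Symmetric, finite similarity matrix; the diagonal is ignored.

    Returns
    -------
    EpisodeNetwork
        Connected network whose edge set is the shortest descending-weight
        prefix achieving connectivity.  Ties are broken by ascending
        lexicographic node pair; with real-valued similarities exact ties
        have measure zero.

    Raises
    ------
    CannotConnectError
        If the matrix has no positive entry at all (an all-zero matrix
        carries no similarity structure to build from).
    """
    edge_list, n = _sorted_edge_list(S)
    if not np.any(edge_list[:, 2] > 0):
        raise CannotConnectError("similarity matrix has no positive entries")
    uf = UnionFind(range(n))
    net = EpisodeNetwork(n_nodes=n)
    n_components = n
    for i, j, w in edge_list:
        i, j = int(i), int(j)
        if uf[i] != uf[j]:
            n_components -= 1
        uf.union(i, j)
        net.edges.append((i, j))
        net.trace.append((i, j, float(w)))
        if n_components == 1:
            net.stopping_weight = float(w)
            return net
    raise CannotConnectError("exhausted all edges without reaching connectivity")


def maximum_spanning_tree(S) -> EpisodeNetwork:
    """Kruskal maximum spanning tree under the same edge ordering.

    Exactly ``n - 1`` edges; the minimum edge weight of this tree is the
    bottleneck weight and equals the greedy construction's stopping weight
    when all weights are distinct.
    """
    edge_list, n = _sorted_edge_list(S)
    if not np.any(edge_list[:, 2] > 0):
        raise CannotConnectError("similarity matrix has no positive entries")
    uf = UnionFind(range(n))
    net = EpisodeNetwork(n_nodes=n)
    for i, j, w in edge_list:
        i, j = int(i), int(j)
        if uf[i] == uf[j]:
            continue
        uf.union(i, j)
        net.edges.append((i, j))
        net.trace.append((i, j, float(w)))
        if len(net.edges) == n - 1:
            net.stopping_weight = float(w)
            return net
    raise CannotConnectError("exhausted all edges without spanning all nodes")
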