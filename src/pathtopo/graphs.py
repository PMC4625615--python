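"""Graph machinery shared by the analysis methods.

Cliques, moralization, min-fill triangulation, junction trees, signed
adjacency/Laplacian matrices, reachability and hop distances. Simple
undirected views collapse parallel edges by sign majority (ties -> 0) and
ignore self-loops.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .pathway import Pathway

__all__ = [
    "SignedAdjacency",
    "JunctionTree",
    "signed_adjacency",
    "to_digraph",
    "undirected_skeleton",
    "maximal_cliques",
    "moralize",
    "triangulate",
    "build_junction_tree",
    "reachable_downstream",
    "shortest_path_lengths",
    "graph_laplacian",
]


# ---------------------------------------------------------------------------
# conversions
# ---------------------------------------------------------------------------


def to_digraph(p: Pathway, orient_mode: str = "both") -> nx.MultiDiGraph:
    """Signed directed multigraph view; undirected edges oriented per *orient_mode*."""
    from .pathway import orient_undirected

    if p.has_undirected_edges():
        p = orient_undirected(p, orient_mode)
    g = nx.MultiDiGraph()
    g.add_nodes_from(sorted(p.nodes))
    for e in p.edges:
        g.add_edge(e.source, e.target, sign=e.sign, subtype=e.subtype)
    return g


def undirected_skeleton(p: Pathway) -> nx.Graph:
    """Simple undirected view: directions dropped, parallel edges collapsed
    by sign majority (ties -> 0), self-loops ignored."""
    sign_sums: dict[frozenset, int] = {}
    for e in p.edges:
        if e.source == e.target:
            continue
        key = frozenset((e.source, e.target))
        sign_sums[key] = sign_sums.get(key, 0) + e.sign
    g = nx.Graph()
    g.add_nodes_from(sorted(p.nodes))
    for key, ssum in sign_sums.items():
        a, b = sorted(key)
        g.add_edge(a, b, sign=int(np.sign(ssum)))
    return g


# ---------------------------------------------------------------------------
# cliques (Bron-Kerbosch, degeneracy ordering + pivoting)
# ---------------------------------------------------------------------------


def _degeneracy_order(adj: dict[str, set[str]]) -> list[str]:
    # repeatedly remove a minimum-degree node; ties by node id for determinism
    remaining = {v: set(nb) for v, nb in adj.items()}
    order: list[str] = []
    while remaining:
        v = min(remaining, key=lambda x: (len(remaining[x]), x))
        order.append(v)
        for u in remaining[v]:
            remaining[u].discard(v)
        del remaining[v]
    return order


def _bron_kerbosch_pivot(adj, R: set, P: set, X: set, out: list) -> None:
    if not P and not X:
        out.append(frozenset(R))
        return
    pivot = max(P | X, key=lambda u: (len(adj[u] & P), u))
    for v in sorted(P - adj[pivot]):
        _bron_kerbosch_pivot(adj, R | {v}, P & adj[v], X & adj[v], out)
        P = P - {v}
        X = X | {v}


def maximal_cliques(g: nx.Graph | Pathway) -> list[frozenset[str]]:
    """All maximal cliques of a simple undirected graph via Bron-Kerbosch
    with a degeneracy-ordered outer loop and pivoting.

    Returned cliques are internally sorted sets; the list is sorted
    lexicographically by sorted member tuple. Isolated nodes form singleton
    cliques.
    """
    if isinstance(g, Pathway):
        g = undirected_skeleton(g)
    adj = {v: {u for u in g.neighbors(v) if u != v} for v in g.nodes}
    order = _degeneracy_order(adj)
    pos = {v: i for i, v in enumerate(order)}
    out: list[frozenset[str]] = []
    for v in order:
        later = {u for u in adj[v] if pos[u] > pos[v]}
        earlier = {u for u in adj[v] if pos[u] < pos[v]}
        _bron_kerbosch_pivot(adj, {v}, later, earlier, out)
    return sorted(set(out), key=lambda c: tuple(sorted(c)))


# ---------------------------------------------------------------------------
# moralization / triangulation / junction tree
# ---------------------------------------------------------------------------


def moralize(g: nx.DiGraph | nx.MultiDiGraph) -> nx.Graph:
    """Moral graph of a DAG: parents of each node married, directions dropped."""
    if not nx.is_directed_acyclic_graph(g):
        cycle = [e[0] for e in nx.find_cycle(g)]
        raise ValueError(f"moralize requires a DAG; found cycle through {cycle}")
    moral = nx.Graph()
    moral.add_nodes_from(g.nodes)
    moral.add_edges_from((u, v) for u, v in g.edges() if u != v)
    for v in g.nodes:
        parents = sorted({u for u in g.predecessors(v) if u != v})
        for i, a in enumerate(parents):
            for b in parents[i + 1 :]:
                moral.add_edge(a, b)
    return moral


def triangulate(g: nx.Graph) -> tuple[nx.Graph, list[str]]:
    """Chordal supergraph via the greedy min-fill heuristic.

    Ties are broken by node id so the elimination order, and hence the
    junction tree, is deterministic. Returns (chordal graph, elimination
    order); the order has zero fill-in on the returned graph.
    """
    adj = {v: {u for u in g.neighbors(v) if u != v} for v in g.nodes}
    fill_edges: list[tuple[str, str]] = []
    order: list[str] = []

    def fill_in(v: str) -> int:
        nbrs = sorted(adj[v])
        missing = 0
        for i, a in enumerate(nbrs):
            for b in nbrs[i + 1 :]:
                if b not in adj[a]:
                    missing += 1
        return missing

    while adj:
        v = min(adj, key=lambda x: (fill_in(x), x))
        nbrs = sorted(adj[v])
        for i, a in enumerate(nbrs):
            for b in nbrs[i + 1 :]:
                if b not in adj[a]:
                    adj[a].add(b)
                    adj[b].add(a)
                    fill_edges.append((a, b))
        order.append(v)
        for u in adj[v]:
            adj[u].discard(v)
        del adj[v]
    chordal = nx.Graph()
    chordal.add_nodes_from(g.nodes)
    chordal.add_edges_from((u, v) for u, v in g.edges() if u != v)
    chordal.add_edges_from(fill_edges)
    return chordal, order


@dataclass(frozen=True)
class JunctionTree:
    """Clique tree with separators satisfying the running-intersection property."""

    cliques: tuple[frozenset[str], ...]
    tree_edges: tuple[tuple[int, int], ...]
    separators: tuple[frozenset[str], ...]  # parallel to tree_edges

    def verify_running_intersection(self) -> bool:
        t = nx.Graph()
        t.add_nodes_from(range(len(self.cliques)))
        t.add_edges_from(self.tree_edges)
        nodes = set().union(*self.cliques) if self.cliques else set()
        for v in nodes:
            containing = [i for i, c in enumerate(self.cliques) if v in c]
            sub = t.subgraph(containing)
            if len(containing) > 1 and not nx.is_connected(sub):
                return False
        for (i, j), sep in zip(self.tree_edges, self.separators):
            if self.cliques[i] & self.cliques[j] != sep:
                return False
        return True


def build_junction_tree(g: nx.Graph) -> JunctionTree:
    """Junction tree of a chordal graph: maximum-weight spanning tree of the
    clique graph, weighted by separator size."""
    if not nx.is_chordal(g):
        raise ValueError("build_junction_tree requires a chordal graph")
    cliques = maximal_cliques(g)
    cg = nx.Graph()
    cg.add_nodes_from(range(len(cliques)))
    for i in range(len(cliques)):
        for j in range(i + 1, len(cliques)):
            w = len(cliques[i] & cliques[j])
            if w > 0:
                cg.add_edge(i, j, weight=w)
    mst = nx.maximum_spanning_tree(cg, weight="weight")
    # connect disconnected clique components with empty separators so the
    # result is a single tree over all cliques
    comp_reps = [min(c) for c in nx.connected_components(
        nx.Graph(list(mst.edges()) + [(i, i) for i in range(len(cliques))])
    )]
    edges = sorted(tuple(sorted(e)) for e in mst.edges())
    comp_reps = sorted(comp_reps)
    for a, b in zip(comp_reps, comp_reps[1:]):
        edges.append((a, b))
    edges = sorted(edges)
    seps = tuple(cliques[i] & cliques[j] for i, j in edges)
    jt = JunctionTree(tuple(cliques), tuple(edges), seps)
    assert jt.verify_running_intersection(), "junction tree violates running intersection"
    return jt


# ---------------------------------------------------------------------------
# reachability / distances
# ---------------------------------------------------------------------------


def reachable_downstream(g: nx.DiGraph | nx.MultiDiGraph | Pathway, node: str) -> set[str]:
    """Nodes reachable from *node* by >=1 directed step; includes *node*
    itself only if it lies on a directed cycle through itself."""
    if isinstance(g, Pathway):
        g = to_digraph(g)
    if node not in g:
        raise KeyError(f"unknown node {node!r}")
    out: set[str] = set()
    stack = [s for s in g.successors(node)]
    while stack:
        v = stack.pop()
        if v in out:
            continue
        out.add(v)
        stack.extend(u for u in g.successors(v) if u not in out)
    return out


def shortest_path_lengths(p: Pathway | nx.Graph) -> tuple[list[str], np.ndarray]:
    """Pairwise hop distances on the undirected skeleton (inf if disconnected)."""
    g = undirected_skeleton(p) if isinstance(p, Pathway) else p
    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    d = np.full((len(nodes), len(nodes)), np.inf)
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for tgt, length in lengths.items():
            d[idx[src], idx[tgt]] = length
    return nodes, d


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SignedAdjacency:
    """Column-to-row signed influence matrix for perturbation propagation.

    ``B[i, j]`` is the net sign of directed edges j -> i; ``outdegree[j]``
    counts j's outgoing nonzero-sign edges (neutral edges carry no
    perturbation and are excluded on both sides).
    """

    nodes: tuple[str, ...]
    B: np.ndarray
    outdegree: np.ndarray


def signed_adjacency(p: Pathway, orient_mode: str = "both") -> SignedAdjacency:
    g = to_digraph(p, orient_mode)
    nodes = tuple(sorted(g.nodes))
    idx = {n: i for i, n in enumerate(nodes)}
    B = np.zeros((len(nodes), len(nodes)))
    outdeg = np.zeros(len(nodes))
    for u, v, data in g.edges(data=True):
        s = data.get("sign", 0)
        if s == 0:
            continue
        B[idx[v], idx[u]] += s
        outdeg[idx[u]] += 1
    return SignedAdjacency(nodes, B, outdeg)


def graph_laplacian(p: Pathway, signed: bool = False) -> tuple[np.ndarray, list[str]]:
    """Graph Laplacian of the undirected skeleton.

    Unsigned: L = D - A with A the 0/1 symmetrized adjacency (positive
    semidefinite). Signed: A entries carry the interaction sign (conflicting
    parallel signs collapse to 0) and D is the diagonal of row sums of |A|,
    so an inhibition edge contributes +1 off-diagonal.
    """
    g = undirected_skeleton(p)
    nodes = sorted(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        val = float(data.get("sign", 0)) if signed else 1.0
        A[idx[u], idx[v]] = val
        A[idx[v], idx[u]] = val
    D = np.diag(np.abs(A).sum(axis=1))
    return D - A, nodes
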