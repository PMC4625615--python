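"""Signed pathway graphs and their manipulation.

A pathway topology is a multigraph over gene/protein identifiers in which
directed and undirected edges coexist, parallel edges between the same pair
of nodes are permitted, and every edge carries a regulatory sign
(+1 activation, -1 inhibition, 0 neutral/unknown) plus a free-text subtype
such as ``"phosphorylation"``.

All editing operations are non-mutating: they validate their inputs and
return new :class:`Pathway` values, which makes permutation and bootstrap
code safe to parallelise.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "Edge",
    "Pathway",
    "PathwayCollection",
    "NodeGrouping",
    "PathwayValidationError",
    "build_pathway",
    "edit_nodes",
    "edit_edges",
    "merge_pathways",
    "induced_subgraph",
    "reduce_graph",
    "estimate_cf",
    "convert_identifiers",
    "orient_undirected",
    "topology_stats",
    "filter_pathways",
]

VALID_SIGNS = (-1, 0, 1)


class PathwayValidationError(ValueError):
    """Raised when a pathway or an edit of one violates an invariant."""


@dataclass(frozen=True)
class Edge:
    """A single signed interaction.

    ``directed=False`` means the edge is unordered; ``source``/``target``
    then only record the order in which the endpoints were listed.
    """

    source: str
    target: str
    directed: bool = True
    sign: int = 0
    subtype: str = ""

    def __post_init__(self) -> None:
        if self.sign not in VALID_SIGNS:
            raise PathwayValidationError(
                f"edge {self.source}->{self.target}: sign {self.sign!r} not in {{-1,0,1}}"
            )

    def endpoints(self) -> frozenset[str]:
        return frozenset((self.source, self.target))


@dataclass(frozen=True)
class Pathway:
    """A named signed multigraph in a declared identifier namespace."""

    id: str
    nodes: frozenset[str]
    edges: tuple[Edge, ...]
    title: str = ""
    species: str = ""
    id_namespace: str = "symbol"

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_undirected_edges(self) -> bool:
        return any(not e.directed for e in self.edges)

    def degree(self, node: str) -> int:
        """Total degree of *node*, counting parallel edges and both edge ends."""
        if node not in self.nodes:
            raise PathwayValidationError(f"node {node!r} not in pathway {self.id!r}")
        deg = 0
        for e in self.edges:
            if e.source == node:
                deg += 1
            if e.target == node:
                deg += 1
        return deg


def build_pathway(
    id: str,
    nodes: Iterable[str],
    edges: Iterable[Edge | tuple],
    id_namespace: str = "symbol",
    title: str = "",
    species: str = "",
) -> Pathway:
    """Validate and assemble a :class:`Pathway`.

    ``edges`` may contain :class:`Edge` instances or tuples
    ``(source, target[, directed[, sign[, subtype]]])``.
    """
    node_list = list(nodes)
    seen: set[str] = set()
    for n in node_list:
        if n in seen:
            raise PathwayValidationError(f"duplicate node id {n!r}")
        seen.add(n)
    edge_tuple = tuple(e if isinstance(e, Edge) else Edge(*e) for e in edges)
    for e in edge_tuple:
        for endpoint in (e.source, e.target):
            if endpoint not in seen:
                raise PathwayValidationError(
                    f"edge {e.source!r}->{e.target!r}: endpoint {endpoint!r} "
                    f"is not a node of pathway {id!r}"
                )
    return Pathway(
        id=id,
        nodes=frozenset(seen),
        edges=edge_tuple,
        title=title,
        species=species,
        id_namespace=id_namespace,
    )


def _rebuild(p: Pathway, nodes: Iterable[str], edges: Iterable[Edge]) -> Pathway:
    return build_pathway(
        p.id, nodes, edges, id_namespace=p.id_namespace, title=p.title, species=p.species
    )


def edit_nodes(
    p: Pathway,
    add: Iterable[str] = (),
    remove: Iterable[str] = (),
) -> Pathway:
    """Add and/or remove nodes; removing a node removes all incident edges."""
    add = list(add)
    remove = set(remove)
    for n in remove:
        if n not in p.nodes:
            raise PathwayValidationError(f"cannot remove unknown node {n!r}")
    for n in add:
        if n in p.nodes:
            raise PathwayValidationError(f"cannot add existing node {n!r}")
    nodes = (set(p.nodes) - remove) | set(add)
    edges = [e for e in p.edges if e.source not in remove and e.target not in remove]
    return _rebuild(p, nodes, edges)


def _edge_matches(e: Edge, selector: Mapping) -> bool:
    for key, val in selector.items():
        if getattr(e, key) != val:
            return False
    return True


def edit_edges(
    p: Pathway,
    add: Iterable[Edge | tuple] = (),
    remove: Iterable[Mapping] = (),
    retype: Iterable[tuple[Mapping, Mapping]] = (),
) -> Pathway:
    """Add edges, remove edges by selector, or retype matched edges.

    A selector is a mapping of Edge field names to required values, e.g.
    ``{"source": "A", "target": "B", "sign": 1}``; it must match at least
    one edge. ``retype`` pairs a selector with the fields to change
    (``sign``, ``directed`` and/or ``subtype`` only).
    """
    edges = list(p.edges)
    for sel in remove:
        matched = [e for e in edges if _edge_matches(e, sel)]
        if not matched:
            raise PathwayValidationError(f"edge selector {dict(sel)!r} matched no edge")
        for e in matched:
            edges.remove(e)
    for sel, changes in retype:
        bad = set(changes) - {"sign", "directed", "subtype"}
        if bad:
            raise PathwayValidationError(f"retype may not change fields {sorted(bad)}")
        matched = [i for i, e in enumerate(edges) if _edge_matches(e, sel)]
        if not matched:
            raise PathwayValidationError(f"edge selector {dict(sel)!r} matched no edge")
        for i in matched:
            edges[i] = replace(edges[i], **changes)
    for e in add:
        edges.append(e if isinstance(e, Edge) else Edge(*e))
    return _rebuild(p, p.nodes, edges)


def merge_pathways(p1: Pathway, p2: Pathway, id: str | None = None) -> Pathway:
    """Union of node sets, concatenation of edge lists (parallel edges kept)."""
    if p1.id_namespace != p2.id_namespace:
        raise PathwayValidationError(
            f"cannot merge pathways with different identifier namespaces "
            f"({p1.id_namespace!r} vs {p2.id_namespace!r}); convert identifiers first"
        )
    return build_pathway(
        id if id is not None else f"{p1.id}+{p2.id}",
        p1.nodes | p2.nodes,
        p1.edges + p2.edges,
        id_namespace=p1.id_namespace,
        title=p1.title,
        species=p1.species,
    )


def induced_subgraph(p: Pathway, keep: Iterable[str]) -> Pathway:
    """Subgraph on ``keep``, retaining exactly edges with both endpoints kept."""
    keep = set(keep)
    unknown = keep - p.nodes
    if unknown:
        raise PathwayValidationError(f"unknown node(s) in keep set: {sorted(unknown)}")
    edges = [e for e in p.edges if e.source in keep and e.target in keep]
    return _rebuild(p, keep, edges)


# ---------------------------------------------------------------------------
# node merging (gene families / protein complexes)
# ---------------------------------------------------------------------------

NodeGrouping = Mapping[str, frozenset[str] | set[str]]


def _signed_neighborhoods(p: Pathway, node: str, exclude: set[str]):
    """(incoming, outgoing, undirected) signed neighborhoods of *node*,
    ignoring partners in *exclude*."""
    inc, out, und = set(), set(), set()
    for e in p.edges:
        if e.directed:
            if e.target == node and e.source not in exclude:
                inc.add((e.source, e.sign))
            if e.source == node and e.target not in exclude:
                out.add((e.target, e.sign))
        else:
            if e.source == node and e.target not in exclude:
                und.add((e.target, e.sign))
            if e.target == node and e.source not in exclude:
                und.add((e.source, e.sign))
    return inc, out, und


def _internal_edges(p: Pathway, group: set[str]) -> list[Edge]:
    return [e for e in p.edges if e.source in group and e.target in group]


def _is_gene_family(p: Pathway, group: set[str]) -> bool:
    """Identical signed in/out neighborhoods outside the group, no internal edges."""
    if _internal_edges(p, group):
        return False
    hoods = [_signed_neighborhoods(p, n, group) for n in group]
    return all(h == hoods[0] for h in hoods[1:])


def _is_complex(p: Pathway, group: set[str]) -> bool:
    """All-to-all undirected binding among members, identical external neighborhoods."""
    members = sorted(group)
    for a, b in itertools.combinations(members, 2):
        if not any(
            not e.directed and e.endpoints() == frozenset((a, b)) for e in p.edges
        ):
            return False
    # internal edges must all be undirected (binding); a directed internal
    # edge means real regulatory structure that merging would destroy
    if any(e.directed for e in _internal_edges(p, group)):
        return False
    hoods = [_signed_neighborhoods(p, n, group) for n in group]
    return all(h == hoods[0] for h in hoods[1:])


def _is_mergeable(p: Pathway, group: set[str]) -> bool:
    return len(group) >= 2 and (_is_gene_family(p, group) or _is_complex(p, group))


def validate_grouping(p: Pathway, grouping: NodeGrouping) -> None:
    seen: set[str] = set()
    for name, members in grouping.items():
        members = set(members)
        if len(members) < 2:
            raise PathwayValidationError(f"group {name!r} has fewer than 2 members")
        missing = members - p.nodes
        if missing:
            raise PathwayValidationError(
                f"group {name!r} contains unknown node(s) {sorted(missing)}"
            )
        overlap = members & seen
        if overlap:
            raise PathwayValidationError(
                f"group {name!r} overlaps another group on {sorted(overlap)}"
            )
        seen |= members
        if not _is_mergeable(p, members):
            raise PathwayValidationError(
                f"group {name!r} is not mergeable: members must form a gene family "
                f"(identical signed in/out neighborhoods, no internal edges) or a "
                f"protein complex (all-to-all undirected binding, identical external "
                f"neighborhoods)"
            )


def reduce_graph(
    p: Pathway, grouping: NodeGrouping
) -> tuple[Pathway, dict[str, frozenset[str]]]:
    """Collapse each node group into a single node named after its group.

    External edges are re-attached to the merged node; edges internal to a
    group are dropped (their structure is redundant by the family/complex
    rule); re-attached parallel edges identical in (endpoints, direction,
    sign, subtype) collapse to one, while conflicting signs are kept as
    parallel edges. Returns the reduced pathway and the merged-node ->
    original-members mapping.
    """
    validate_grouping(p, grouping)
    node_map = {n: n for n in p.nodes}
    for name, members in grouping.items():
        if name in p.nodes and name not in set(members):
            raise PathwayValidationError(
                f"group name {name!r} collides with an existing node"
            )
        for m in members:
            node_map[m] = name
    grouped = {m for ms in grouping.values() for m in ms}
    new_edges: list[Edge] = []
    seen_merged: set[tuple] = set()
    for e in p.edges:
        if e.source in grouped and e.target in grouped and node_map[e.source] == node_map[e.target]:
            continue  # internal to one group
        ne = replace(e, source=node_map[e.source], target=node_map[e.target])
        if ne.source in grouping or ne.target in grouping:
            key = (ne.source, ne.target, ne.directed, ne.sign, ne.subtype)
            ukey = (frozenset((ne.source, ne.target)), ne.directed, ne.sign, ne.subtype)
            k = key if ne.directed else ukey
            if k in seen_merged:
                continue
            seen_merged.add(k)
        new_edges.append(ne)
    nodes = set(node_map.values())
    members_of = {name: frozenset(ms) for name, ms in grouping.items()}
    return _rebuild(p, nodes, new_edges), members_of


def estimate_cf(p: Pathway) -> dict[str, frozenset[str]]:
    """Estimate the maximal disjoint sets of nodes mergeable as gene families
    or protein complexes (candidates for :func:`reduce_graph`).

    Groups are grown greedily from a signature partition (nodes sharing
    signed neighborhoods), are maximal under set inclusion, and disjoint;
    ties are broken by the lexicographically smallest member.
    """
    nodes = sorted(p.nodes)
    # signature ignoring a candidate partner set is group-dependent, so start
    # from pairs and grow; pathways are small enough for the quadratic scan.
    assigned: set[str] = set()
    groups: list[set[str]] = []
    for a in nodes:
        if a in assigned:
            continue
        group = {a}
        for b in nodes:
            if b == a or b in assigned or b in group:
                continue
            if _is_mergeable(p, group | {b}):
                group.add(b)
        if len(group) >= 2 and _is_mergeable(p, group):
            groups.append(group)
            assigned |= group
    out: dict[str, frozenset[str]] = {}
    for g in sorted(groups, key=lambda s: min(s)):
        kind = "family" if _is_gene_family(p, g) else "complex"
        out[f"{kind}:{'+'.join(sorted(g))}"] = frozenset(g)
    return out


def convert_identifiers(
    p: Pathway, mapping: Mapping[str, Sequence[str]]
) -> Pathway:
    """Rename nodes by a user-supplied old-id -> new-ids mapping.

    A node with one image is renamed; k>1 images expand the node into k
    copies each inheriting all incident edges; unmapped nodes keep their old
    id (counted in a warning). Two old nodes mapping onto one new id are
    merged, keeping their combined (deduplicated) edges, with a warning.
    """
    images: dict[str, list[str]] = {}
    unmapped = 0
    for n in p.nodes:
        imgs = list(mapping.get(n, []))
        if not imgs:
            images[n] = [n]
            unmapped += 1
        else:
            images[n] = list(dict.fromkeys(imgs))
    if unmapped:
        warnings.warn(
            f"convert_identifiers: {unmapped} node(s) had no mapping and keep "
            f"their original identifier",
            stacklevel=2,
        )
    new_nodes: list[str] = []
    seen: set[str] = set()
    collisions: set[str] = set()
    for n in sorted(p.nodes):
        for img in images[n]:
            if img in seen:
                collisions.add(img)
            else:
                seen.add(img)
                new_nodes.append(img)
    if collisions:
        warnings.warn(
            f"convert_identifiers: distinct nodes collided onto {sorted(collisions)}; "
            f"they were merged",
            stacklevel=2,
        )
    new_edges: list[Edge] = []
    edge_seen: set[tuple] = set()
    for e in p.edges:
        for s_img in images[e.source]:
            for t_img in images[e.target]:
                ne = replace(e, source=s_img, target=t_img)
                key = (ne.source, ne.target, ne.directed, ne.sign, ne.subtype)
                # collisions merge nodes; drop only exact duplicate edges that
                # arise from the merge, keep genuine parallel edges
                if collisions and key in edge_seen:
                    continue
                edge_seen.add(key)
                new_edges.append(ne)
    return _rebuild(p, new_nodes, new_edges)


def orient_undirected(p: Pathway, mode: str = "both") -> Pathway:
    """Replace undirected edges with directed ones.

    mode="both": each undirected edge becomes two directed edges of the same
    sign (one per direction). mode="as-listed": one directed edge in the
    order the endpoints were listed.
    """
    if mode not in ("both", "as-listed"):
        raise ValueError(f"mode must be 'both' or 'as-listed', got {mode!r}")
    edges: list[Edge] = []
    for e in p.edges:
        if e.directed:
            edges.append(e)
        else:
            edges.append(replace(e, directed=True))
            if mode == "both":
                edges.append(replace(e, source=e.target, target=e.source, directed=True))
    return _rebuild(p, p.nodes, edges)


def topology_stats(p: Pathway) -> dict:
    """Basic topology descriptors; parallel edges each count."""
    indeg = {n: 0 for n in p.nodes}
    outdeg = {n: 0 for n in p.nodes}
    total = {n: 0 for n in p.nodes}
    parent = {n: n for n in p.nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in p.edges:
        if e.directed:
            outdeg[e.source] += 1
            indeg[e.target] += 1
        total[e.source] += 1
        if e.target != e.source:
            total[e.target] += 1
        else:
            total[e.source] += 1  # self-loop contributes 2 to degree
        parent[find(e.source)] = find(e.target)
    n_components = len({find(n) for n in p.nodes})
    return {
        "n_nodes": p.n_nodes,
        "n_edges": p.n_edges,
        "n_components": n_components,
        "in_degree": indeg,
        "out_degree": outdeg,
        "degree": total,
        "max_degree": max(total.values()) if total else 0,
    }


# ---------------------------------------------------------------------------
# collections
# ---------------------------------------------------------------------------


@dataclass
class PathwayCollection:
    """Ordered mapping of unique pathway names to pathways."""

    pathways: dict[str, Pathway] = field(default_factory=dict)

    @classmethod
    def from_pathways(cls, pathways: Iterable[Pathway]) -> "PathwayCollection":
        out: dict[str, Pathway] = {}
        for p in pathways:
            if not p.id:
                raise PathwayValidationError("pathway name must be non-empty")
            if p.id in out:
                raise PathwayValidationError(f"duplicate pathway name {p.id!r}")
            out[p.id] = p
        return cls(out)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.values())

    def __getitem__(self, name: str) -> Pathway:
        return self.pathways[name]

    def names(self) -> list[str]:
        return list(self.pathways)

    def all_nodes(self) -> set[str]:
        out: set[str] = set()
        for p in self:
            out |= p.nodes
        return out


def filter_pathways(
    c: PathwayCollection, predicate: Callable[[dict], bool]
) -> PathwayCollection:
    """Order-preserving subset of pathways whose topology_stats satisfy *predicate*."""
    return PathwayCollection(
        {name: p for name, p in c.pathways.items() if predicate(topology_stats(p))}
    )
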