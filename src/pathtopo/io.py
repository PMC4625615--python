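"""Reading and writing: KGML pathways, edge-list TSVs, expression tables,
group labels, result tables and Graphviz DOT export.

All tabular formats are TSV with a header row and '.' decimals; reads are
gzip-transparent (pandas handles the compression by file suffix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from lxml import etree

from .pathway import Edge, Pathway, build_pathway
from .preprocess import ExpressionMatrix, GroupLabels

__all__ = [
    "KgmlDialect",
    "DEFAULT_KGML_DIALECT",
    "parse_kgml",
    "read_edge_list",
    "write_edge_list",
    "read_expression",
    "read_groups",
    "write_results",
    "read_results",
    "export_dot",
]


# ---------------------------------------------------------------------------
# KGML
# ---------------------------------------------------------------------------


@dataclass
class KgmlDialect:
    """How KGML relation subtypes map to (sign, directed) and whether
    multi-gene entries expand into one node per gene."""

    subtype_map: dict[str, tuple[int, bool]] = field(default_factory=dict)
    expand_entries: bool = True

    def __post_init__(self) -> None:
        for name, (sign, _) in self.subtype_map.items():
            if sign not in (-1, 0, 1):
                raise ValueError(f"dialect subtype {name!r}: sign {sign} not in {{-1,0,1}}")


DEFAULT_KGML_DIALECT = KgmlDialect(
    subtype_map={
        "activation": (1, True),
        "expression": (1, True),
        "inhibition": (-1, True),
        "repression": (-1, True),
        "binding/association": (0, False),
        "dissociation": (0, False),
        "phosphorylation": (0, True),
        "dephosphorylation": (0, True),
        "ubiquitination": (0, True),
        "indirect effect": (0, True),
    }
)

_SKIP_SUBTYPES = {"compound", "hidden compound"}


def parse_kgml(xml: str | bytes | Path, dialect: KgmlDialect | None = None) -> Pathway:
    """Parse a KEGG KGML document into a signed pathway.

    Gene-type entries become nodes (an entry listing k gene ids expands to
    k nodes, each inheriting all of the entry's relations); ``group``
    entries become all-to-all undirected sign-0 binding edges among their
    component genes; compound and map entries are skipped (counted in a
    warning). Relation subtypes map through the dialect; an unknown subtype
    is kept as a neutral directed edge with a warning; an "indirect effect"
    co-occurring with activation/inhibition inherits that sign.
    """
    dialect = dialect or DEFAULT_KGML_DIALECT
    if isinstance(xml, Path) or (isinstance(xml, str) and "\n" not in xml and xml.endswith(".xml")):
        data = Path(xml).read_bytes()
    else:
        data = xml.encode() if isinstance(xml, str) else xml
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed KGML: {exc}") from exc

    entry_genes: dict[str, list[str]] = {}
    entry_groups: dict[str, list[str]] = {}
    skipped = 0
    for entry in root.findall("entry"):
        eid = entry.get("id")
        etype = entry.get("type")
        names = (entry.get("name") or "").split()
        if etype == "gene":
            genes = names if dialect.expand_entries else [" ".join(names)]
            entry_genes[eid] = genes
        elif etype == "group":
            comp = [c.get("id") for c in entry.findall("component")]
            entry_groups[eid] = comp
        else:
            skipped += 1
    if skipped:
        warnings.warn(f"parse_kgml: skipped {skipped} non-gene entr(ies) "
                      f"(compounds, maps, ...)", stacklevel=2)

    def genes_of(eid: str) -> list[str]:
        if eid in entry_genes:
            return entry_genes[eid]
        if eid in entry_groups:
            out: list[str] = []
            for cid in entry_groups[eid]:
                out.extend(genes_of(cid))
            return out
        return []

    nodes: list[str] = []
    for genes in entry_genes.values():
        for g in genes:
            if g not in nodes:
                nodes.append(g)

    edges: list[Edge] = []
    unknown = 0
    for rel in root.findall("relation"):
        e1, e2 = rel.get("entry1"), rel.get("entry2")
        subtypes = [s.get("name") for s in rel.findall("subtype")]
        if any(s in _SKIP_SUBTYPES for s in subtypes):
            continue
        src, tgt = genes_of(e1), genes_of(e2)
        if not src or not tgt:
            continue
        if not subtypes:
            subtypes = [""]
        # "indirect effect" inherits a co-occurring activation/inhibition sign
        signed_partner = next(
            (s for s in subtypes if s in ("activation", "inhibition", "expression", "repression")),
            None,
        )
        for sub in subtypes:
            if sub == "indirect effect" and signed_partner:
                continue
            if sub in dialect.subtype_map:
                sign, directed = dialect.subtype_map[sub]
            else:
                sign, directed = 0, True
                if sub:
                    unknown += 1
            label = sub or "unknown"
            for a in src:
                for b in tgt:
                    edges.append(Edge(a, b, directed=directed, sign=sign, subtype=label))
    if unknown:
        warnings.warn(f"parse_kgml: {unknown} relation(s) with unknown subtype kept "
                      f"as neutral directed edges", stacklevel=2)

    # group entries: all-to-all undirected binding among members
    for comp in entry_groups.values():
        members: list[str] = []
        for cid in comp:
            members.extend(genes_of(cid))
        members = sorted(set(members))
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                edges.append(Edge(a, b, directed=False, sign=0, subtype="binding"))

    name = root.get("name") or "kgml-pathway"
    title = root.get("title") or ""
    species = root.get("org") or ""
    # canonical order for byte-determinism
    nodes = sorted(nodes)
    edges.sort(key=lambda e: (e.source, e.target, not e.directed, e.sign, e.subtype))
    return build_pathway(name, nodes, edges, id_namespace="kegg",
                         title=title, species=species)


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ["source", "target", "directed", "sign"]


def read_edge_list(path: str | Path, id: str | None = None,
                   id_namespace: str = "symbol") -> Pathway:
    """Read a pathway from a TSV with columns source, target, directed(0/1),
    sign(-1/0/1) and optional subtype."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    for col in _EDGE_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"edge list {path}: missing column {col!r}")
    edges = []
    for i, row in enumerate(df.itertuples(index=False)):
        if int(row.sign) not in (-1, 0, 1):
            raise ValueError(f"edge list {path}: sign {row.sign!r} not in {{-1,0,1}} "
                             f"at data row {i + 1}")
        edges.append(Edge(str(row.source), str(row.target),
                          directed=bool(int(row.directed)), sign=int(row.sign),
                          subtype=str(getattr(row, "subtype", "") or "")))
    nodes = sorted(set(df["source"].astype(str)) | set(df["target"].astype(str)))
    name = id if id is not None else Path(path).stem
    return build_pathway(name, nodes, edges, id_namespace=id_namespace)


def write_edge_list(p: Pathway, path: str | Path) -> None:
    rows = [
        {"source": e.source, "target": e.target, "directed": int(e.directed),
         "sign": e.sign, "subtype": e.subtype}
        for e in p.edges
    ]
    df = pd.DataFrame(rows, columns=_EDGE_COLUMNS + ["subtype"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression / groups
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, kind: str) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids) as counts or
    normalized values; count validation errors name the offending cell."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df.astype(float), kind=kind)


def read_groups(path: str | Path, reference: str = "") -> GroupLabels:
    """Read sample group labels from a two-column TSV (sample, group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"groups file {path}: expected columns (sample, group)")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    return GroupLabels(s, reference=reference)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


def write_results(result_set, path: str | Path) -> None:
    """Write a MethodResultSet as a TSV (one row per pathway, deterministic
    column order); round-trips through :func:`read_results`."""
    df = result_set.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# DOT export
# ---------------------------------------------------------------------------

_ARROWS = {1: "normal", -1: "tee", 0: "none"}


def export_dot(
    p: Pathway,
    gene_stats: pd.DataFrame | None = None,
    threshold: float = 1.0,
    sig_threshold: float = 0.05,
    merged_members: dict[str, frozenset[str]] | None = None,
    aggregate: str = "mean",
) -> str:
    """Render the pathway as Graphviz DOT with per-gene statistics.

    ``gene_stats`` is indexed by node id with optional columns ``logFC``,
    ``p`` and ``de`` (boolean); missing nodes render neutral. Node fill
    encodes the logFC sign of differentially expressed genes, node border
    encodes significance, edge arrowheads encode the interaction sign
    (normal +1, tee -1, dashed when neutral). An activation/inhibition edge
    whose two endpoints are both beyond ``threshold`` in |logFC| but whose
    expression change disagrees with the edge sign is highlighted in red.
    Merged nodes (from reduce_graph) show their member list and the
    aggregated (default mean) logFC of their members.
    """
    stats = gene_stats if gene_stats is not None else pd.DataFrame()
    merged_members = merged_members or {}

    def stat(node: str, col: str, default):
        if node in stats.index and col in stats.columns:
            v = stats.loc[node, col]
            if pd.notna(v):
                return v
        return default

    def node_logfc(node: str):
        if node in merged_members:
            vals = [stat(m, "logFC", None) for m in sorted(merged_members[node])]
            vals = [v for v in vals if v is not None]
            if not vals:
                return None
            return sum(vals) / len(vals) if aggregate == "mean" else max(vals, key=abs)
        return stat(node, "logFC", None)

    lines = [f'digraph "{p.id}" {{', "  node [style=filled];"]
    for n in sorted(p.nodes):
        lfc = node_logfc(n)
        de = bool(stat(n, "de", False))
        pval = stat(n, "p", None)
        if lfc is None or not de:
            fill = "white"
        elif lfc > 0:
            fill = "indianred1"
        else:
            fill = "lightskyblue"
        border = "black" if (pval is not None and pval < sig_threshold) else "gray60"
        if n in merged_members:
            members = "+".join(sorted(merged_members[n]))
            agg = f"{lfc:.2f}" if lfc is not None else "NA"
            label = f"{n}\\n[{members}]\\n{aggregate}={agg}"
        else:
            label = n
        lines.append(
            f'  "{n}" [label="{label}", fillcolor={fill}, color={border}];'
        )
    for e in p.edges:
        attrs = [f"arrowhead={_ARROWS[e.sign]}"]
        if e.sign == 0:
            attrs.append("style=dashed")
        if not e.directed:
            attrs.append("dir=none")
        s_lfc, t_lfc = node_logfc(e.source), node_logfc(e.target)
        if (
            e.sign != 0
            and s_lfc is not None and t_lfc is not None
            and abs(s_lfc) > threshold and abs(t_lfc) > threshold
            and (1 if t_lfc > 0 else -1) != e.sign * (1 if s_lfc > 0 else -1)
        ):
            attrs.append("color=red")  # expression change discordant with edge sign
        lines.append(f'  "{e.source}" -> "{e.target}" [{", ".join(attrs)}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
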