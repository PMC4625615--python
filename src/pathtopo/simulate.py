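"""Synthetic pathway collections and two-condition expression data.

The generators emulate what the analysis methods assume about real data: a
collection of signed, mixed-direction pathway graphs; negative-binomial
RNA-Seq counts or Gaussian normalized expression, optionally with a
graph-structured covariance; and one planted differentially expressed
pathway whose affected genes shift by a configurable log2 effect.

The ``paper_like`` preset mirrors the scale of a small two-condition
RNA-Seq knockdown study: 50 pathways of 10-40 genes, 4 + 4 samples, one
planted pathway with effect 2 on 30 % of its genes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pathway import Edge, Pathway, PathwayCollection, build_pathway
from .preprocess import ExpressionMatrix, GroupLabels

__all__ = [
    "SimulationTruth",
    "make_random_pathway",
    "make_collection",
    "simulate_expression",
    "paper_like",
    "write_simulation",
]


@dataclass
class SimulationTruth:
    """Ground truth of a planted-signal simulation."""

    planted: str | None
    affected: tuple[str, ...]
    effect: float  # log2 scale
    kind: str  # nb-counts | gaussian | graph-gaussian
    seed: int | None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def make_random_pathway(
    n_nodes: int,
    edge_prob: float = 0.15,
    inhibition_frac: float = 0.3,
    dag: bool = True,
    seed: int | None = None,
    id: str = "pathway",
    node_prefix: str = "g",
) -> Pathway:
    """Random signed pathway; with ``dag=True`` edges only run from lower to
    higher random topological rank, so acyclicity is guaranteed."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    names = [f"{node_prefix}{i:04d}" for i in range(n_nodes)]
    rank = rng.permutation(n_nodes)
    edges: list[Edge] = []
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i == j:
                continue
            if dag and rank[i] >= rank[j]:
                continue
            if not dag and i > j and any(
                e.source == names[j] and e.target == names[i] for e in edges
            ):
                continue
            if rng.random() < edge_prob:
                sign = -1 if rng.random() < inhibition_frac else 1
                edges.append(Edge(names[i], names[j], directed=True, sign=sign))
    return build_pathway(id, names, edges, id_namespace="symbol")


def make_collection(
    n_pathways: int,
    size_range: tuple[int, int] = (10, 40),
    edge_prob: float | None = None,
    inhibition_frac: float = 0.3,
    seed: int | None = None,
) -> PathwayCollection:
    """Collection of random DAG pathways over disjoint gene sets.

    With ``edge_prob=None`` each pathway gets an edge probability giving an
    expected out-degree around 1.5, independent of its size.
    """
    rng = np.random.default_rng(seed)
    pathways = []
    offset = 0
    for i in range(n_pathways):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        ep = edge_prob if edge_prob is not None else min(1.0, 3.0 / max(size - 1, 1))
        p = make_random_pathway(
            size, ep, inhibition_frac, dag=True,
            seed=int(rng.integers(2**31)), id=f"pw{i:03d}",
        )
        # relabel onto a disjoint slice of the gene universe
        mapping = {f"g{j:04d}": f"g{offset + j:05d}" for j in range(size)}
        edges = [Edge(mapping[e.source], mapping[e.target], e.directed, e.sign, e.subtype)
                 for e in p.edges]
        pathways.append(build_pathway(p.id, list(mapping.values()), edges))
        offset += size
    return PathwayCollection.from_pathways(pathways)


def simulate_expression(
    collection: PathwayCollection,
    truth: SimulationTruth,
    n1: int = 4,
    n2: int = 4,
    n_background: int = 200,
    baseline_log_mean: float = np.log(500.0),
    baseline_log_sd: float = 1.0,
    phi: float = 0.1,
    graph_coupling: float = 0.3,
    eig_floor: float = 0.1,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, GroupLabels]:
    """Two-group expression for all pathway genes plus background genes.

    nb-counts: per-gene baseline mean ~ lognormal(log 500, 1), negative
    binomial with dispersion ``phi`` (variance mu + phi*mu^2); affected
    genes' group-2 means are multiplied by 2**effect. gaussian: unit
    variance, affected group-2 means shifted by effect. graph-gaussian: per
    pathway, the precision matrix is I + coupling * symmetrized adjacency
    with eigenvalues floored at ``eig_floor``; genes outside any pathway
    are independent.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if truth.planted is not None and truth.planted not in collection.pathways:
        raise ValueError(f"planted pathway {truth.planted!r} not in collection")
    rng = np.random.default_rng(seed if seed is not None else truth.seed)
    genes = sorted(collection.all_nodes())
    genes += [f"bg{i:05d}" for i in range(n_background)]
    gidx = {g: i for i, g in enumerate(genes)}
    n = n1 + n2
    samples = [f"ctrl{i + 1}" for i in range(n1)] + [f"case{i + 1}" for i in range(n2)]
    labels = GroupLabels(
        pd.Series(["control"] * n1 + ["case"] * n2, index=samples), reference="control"
    )
    affected = set(truth.affected)
    shift = np.zeros(len(genes))
    for g in affected:
        shift[gidx[g]] = truth.effect

    if truth.kind == "nb-counts":
        base = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=len(genes)))
        mu = np.tile(base[:, None], (1, n))
        mu[:, n1:] *= 2.0 ** shift[:, None]
        r = 1.0 / phi
        p_nb = r / (r + mu)
        vals = rng.negative_binomial(r, p_nb).astype(float)
        em = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples), "counts")
    elif truth.kind in ("gaussian", "graph-gaussian"):
        vals = rng.standard_normal((len(genes), n))
        if truth.kind == "graph-gaussian":
            from .graphs import undirected_skeleton

            covered: set[str] = set()
            for pw in collection:
                pnodes = [g for g in sorted(pw.nodes) if g not in covered]
                if len(pnodes) < 2:
                    continue
                covered |= set(pnodes)
                skel = undirected_skeleton(pw)
                k = len(pnodes)
                A = np.zeros((k, k))
                pidx = {g: i for i, g in enumerate(pnodes)}
                for a, b in skel.edges():
                    if a in pidx and b in pidx:
                        A[pidx[a], pidx[b]] = A[pidx[b], pidx[a]] = 1.0
                P = np.eye(k) + graph_coupling * A
                evals, evecs = np.linalg.eigh(P)
                evals = np.maximum(evals, eig_floor)
                cov = (evecs / evals) @ evecs.T  # inverse of floored precision
                chol = np.linalg.cholesky(cov)
                rows = np.array([gidx[g] for g in pnodes])
                vals[rows, :] = chol @ rng.standard_normal((k, n))
        vals[:, n1:] += shift[:, None]
        em = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples), "normalized")
    else:
        raise ValueError(f"unknown generator kind {truth.kind!r}")
    return em, labels


def paper_like(
    seed: int | None = None,
    n_pathways: int = 50,
    size_range: tuple[int, int] = (10, 40),
    effect: float = 2.0,
    affected_frac: float = 0.3,
    kind: str = "nb-counts",
    n1: int = 4,
    n2: int = 4,
    n_background: int = 200,
):
    """The default planted-signal study: one affected pathway among
    ``n_pathways``, ``affected_frac`` of its genes shifted by ``effect``
    log2 units, 4 + 4 samples.

    Returns (collection, expression, groups, truth).
    """
    rng = np.random.default_rng(seed)
    coll = make_collection(n_pathways, size_range, seed=int(rng.integers(2**31)))
    names = coll.names()
    planted = names[int(rng.integers(len(names)))]
    pnodes = sorted(coll[planted].nodes)
    n_aff = max(1, int(round(affected_frac * len(pnodes))))
    affected = tuple(sorted(rng.choice(pnodes, size=n_aff, replace=False)))
    truth = SimulationTruth(planted, affected, effect, kind, seed)
    em, labels = simulate_expression(
        coll, truth, n1=n1, n2=n2, n_background=n_background,
        seed=int(rng.integers(2**31)),
    )
    return coll, em, labels, truth


def write_simulation(
    outdir: str | Path,
    collection: PathwayCollection,
    expr: ExpressionMatrix,
    groups: GroupLabels,
    truth: SimulationTruth,
) -> None:
    """Write expression TSV, groups TSV, an edge-list pathway directory and
    the truth JSON under *outdir*."""
    from .io import write_edge_list

    outdir = Path(outdir)
    (outdir / "pathways").mkdir(parents=True, exist_ok=True)
    expr.values.rename_axis("gene").to_csv(outdir / "expression.tsv", sep="\t",
                                           float_format="%.10g")
    pd.DataFrame({"sample": groups.labels.index, "group": groups.labels.values}).to_csv(
        outdir / "groups.tsv", sep="\t", index=False
    )
    for name, p in collection.pathways.items():
        write_edge_list(p, outdir / "pathways" / f"{name}.tsv")
    (outdir / "truth.json").write_text(truth.to_json() + "\n")
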