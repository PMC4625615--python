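"""Univariable topology-based pathway analysis: SPIA, PRS, PWEA, TAPPA.

These methods score a pathway by combining per-gene statistics (log
fold-changes, moderated t) over the pathway topology:

* SPIA propagates the log fold-changes of differentially expressed genes
  through the signed directed graph, accumulating a gene-level net
  perturbation, and combines a perturbation bootstrap p-value with a
  hypergeometric over-representation p-value.
* PRS weights each differentially expressed gene's |logFC| by one plus the
  number of differentially expressed genes downstream of it, against a
  gene-relabelling permutation null.
* PWEA computes per-gene topology influence factors (TIFs) from expression
  correlation and hop distance, and runs a TIF-weighted enrichment
  running-sum against a sample-label permutation null.
* TAPPA summarizes each sample by a pathway connectivity index (PCI) over
  the undirected skeleton and compares the two groups by a Mann-Whitney
  rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .graphs import (
    reachable_downstream,
    shortest_path_lengths,
    signed_adjacency,
    to_digraph,
    undirected_skeleton,
)
from .pathway import Pathway
from .preprocess import ExpressionMatrix, GroupLabels, moderated_t_stats

__all__ = ["SpiaResult", "PrsResult", "PweaResult", "TappaResult",
           "spia", "prs", "pwea", "tappa", "spia_pg", "pwea_tif"]

MAX_CONDITION = 1e12


def _rng_for(seed: int | None, *salt) -> np.random.Generator:
    """Deterministic child generator derived by stable hashing of the salt."""
    import hashlib

    h = hashlib.blake2b(repr((seed, *salt)).encode(), digest_size=4).digest()
    return np.random.default_rng(int.from_bytes(h, "big"))


# ---------------------------------------------------------------------------
# SPIA
# ---------------------------------------------------------------------------


@dataclass
class SpiaResult:
    pathway: str
    status: str = "ok"
    n_genes: int = 0
    n_de: int = 0
    t_a: float = np.nan
    p_nde: float = np.nan
    p_pert: float = np.nan
    p: float = np.nan
    acc: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def spia_pg(p_nde: float, p_pert: float) -> float:
    """Fisher-product combination: p_G = c - c*ln(c), c = p_NDE * p_PERT."""
    c = p_nde * p_pert
    if c <= 0:
        return 0.0
    if c >= 1:
        return 1.0
    return float(c - c * np.log(c))


def spia(
    pathway: Pathway,
    de_table: pd.DataFrame,
    deg: pd.Series,
    all_genes: list[str],
    nboot: int = 2000,
    seed: int | None = None,
    orient_mode: str = "both",
) -> SpiaResult:
    """Signaling pathway impact analysis for one pathway.

    ``deg`` is the logFC vector of differentially expressed genes
    (genome-wide); ``all_genes`` the measured universe. The propagation
    matrix has B[i, j] = sign(j->i) / N_ds(j) with N_ds(j) the number of
    outgoing nonzero-sign edges of j; the net accumulation is
    Acc = PF - dE with (I - B) PF = dE.
    """
    measured = sorted(pathway.nodes & set(all_genes))
    if not measured:
        return SpiaResult(pathway.id, status="no-measured-genes")
    sa = signed_adjacency(pathway, orient_mode)
    idx = [sa.nodes.index(g) for g in sorted(pathway.nodes)]  # all nodes, sorted
    nodes = list(sa.nodes)
    with np.errstate(divide="ignore", invalid="ignore"):
        B = np.where(sa.outdegree[None, :] > 0, sa.B / sa.outdegree[None, :], 0.0)
    n = len(nodes)
    IB = np.eye(n) - B
    if np.linalg.cond(IB) > MAX_CONDITION:
        return SpiaResult(pathway.id, status="singular", n_genes=len(measured))
    inv = np.linalg.inv(IB)
    M = inv - np.eye(n)  # Acc = M @ dE
    de_on_path = deg[deg.index.isin(pathway.nodes)]
    n_de = len(de_on_path)
    dE = np.zeros(n)
    for g, lfc in de_on_path.items():
        dE[nodes.index(g)] = lfc
    acc = M @ dE
    t_a = float(acc.sum())
    # perturbation null: place n_de logFC values drawn with replacement from
    # the global DEG pool onto random pathway positions
    pool = deg.to_numpy(dtype=float)
    if n_de == 0 or len(pool) == 0:
        p_pert = 1.0
    else:
        rng = _rng_for(seed, "spia", pathway.id)
        w = M.sum(axis=0)  # t_A^b = sum_k w[pos_k] * val_k
        positions = rng.integers(0, n, size=(nboot, n_de))
        values = pool[rng.integers(0, len(pool), size=(nboot, n_de))]
        t_boot = (w[positions] * values).sum(axis=1)
        med = float(np.median(t_boot))
        k = int(np.sum(np.abs(t_boot - med) >= abs(t_a - med)))
        p_pert = (1 + k) / (nboot + 1)
    n_universe = len(set(all_genes))
    n_deg_global = int(deg.index.isin(all_genes).sum())
    p_nde = float(stats.hypergeom.sf(n_de - 1, n_universe, n_deg_global, len(measured)))
    p_nde = min(1.0, max(p_nde, np.finfo(float).tiny))
    return SpiaResult(
        pathway.id,
        n_genes=len(measured),
        n_de=n_de,
        t_a=t_a,
        p_nde=p_nde,
        p_pert=p_pert,
        p=spia_pg(p_nde, p_pert),
        acc=pd.Series(acc, index=nodes, name="Acc"),
    )


# ---------------------------------------------------------------------------
# PRS
# ---------------------------------------------------------------------------


@dataclass
class PrsResult:
    pathway: str
    status: str = "ok"
    raw: float = np.nan
    null_mean: float = np.nan
    null_sd: float = np.nan
    z: float = np.nan
    p: float = np.nan
    weights: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    contributions: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def prs(
    pathway: Pathway,
    de_table: pd.DataFrame,
    deg: pd.Series,
    all_genes: list[str],
    nperm: int = 1000,
    seed: int | None = None,
    orient_mode: str = "both",
) -> PrsResult:
    """Pathway regulation score: downstream-weighted |logFC| of DE genes.

    v_i = |logFC_i| for DE pathway genes else 0; w_i = 1 + |downstream DE
    genes|; raw = sum(v*w) / max(1, #DE on pathway). The null resamples
    genome-wide (DE status, |logFC|) gene records without replacement onto
    the pathway's measured slots.
    """
    measured = sorted(pathway.nodes & set(all_genes))
    if not measured:
        return PrsResult(pathway.id, status="no-measured-genes")
    g = to_digraph(pathway, orient_mode)
    down = {gene: reachable_downstream(g, gene) for gene in measured}
    deg_set = set(deg.index)
    n_path = len(measured)
    D = np.zeros((n_path, n_path), dtype=bool)  # D[i, j]: j downstream of i
    for i, gi in enumerate(measured):
        for j, gj in enumerate(measured):
            if gj in down[gi]:
                D[i, j] = True
    de_mask = np.array([gene in deg_set for gene in measured])
    v = np.array([abs(deg.get(gene, 0.0)) if de_mask[i] else 0.0
                  for i, gene in enumerate(measured)])
    # downstream DE genes counted over all pathway nodes, not just measured
    w = np.array([1 + len(down[gene] & deg_set) for gene in measured], dtype=float)
    n_de = int(de_mask.sum())
    raw = float((v * w).sum() / max(1, n_de))
    flagged = "ok"
    universe = sorted(set(all_genes))
    glob_de = np.array([gene in deg_set for gene in universe])
    glob_v = np.array([abs(deg.get(gene, 0.0)) if glob_de[i] else 0.0
                       for i, gene in enumerate(universe)])
    if not glob_de.any():
        return PrsResult(pathway.id, status="no-deg", raw=raw, z=0.0, p=1.0)
    rng = _rng_for(seed, "prs", pathway.id)
    perm_raw = np.empty(nperm)
    for b in range(nperm):
        pick = rng.choice(len(universe), size=n_path, replace=False)
        pd_mask = glob_de[pick]
        pv = glob_v[pick]
        pw = 1.0 + D.astype(float) @ pd_mask.astype(float)
        perm_raw[b] = (pv * pw).sum() / max(1, int(pd_mask.sum()))
    mu, sd = float(perm_raw.mean()), float(perm_raw.std(ddof=0))
    if sd > 0:
        z = (raw - mu) / sd
    else:
        z, flagged = 0.0, "degenerate-null"
    p = (1 + int(np.sum(perm_raw >= raw))) / (nperm + 1)
    return PrsResult(
        pathway.id,
        status=flagged,
        raw=raw,
        null_mean=mu,
        null_sd=sd,
        z=float(z),
        p=float(p),
        weights=pd.Series(w, index=measured, name="w"),
        contributions=pd.Series(v * w, index=measured, name="vw"),
    )


# ---------------------------------------------------------------------------
# PWEA
# ---------------------------------------------------------------------------


@dataclass
class PweaResult:
    pathway: str
    status: str = "ok"
    es: float = np.nan
    p: float = np.nan
    tif: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def pwea_tif(pathway: Pathway, expr: ExpressionMatrix) -> pd.Series:
    """Topology influence factors: TIF_i = mean_j exp(rho_ij / d_ij) over
    pathway partners j at finite hop distance; isolated genes get 1."""
    measured = sorted(pathway.nodes & set(expr.genes))
    sub = expr.values.loc[measured].to_numpy(dtype=float)
    nodes, dist = shortest_path_lengths(pathway)
    didx = {n: i for i, n in enumerate(nodes)}
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(sub) if len(measured) > 1 else np.ones((1, 1))
    rho = np.nan_to_num(np.atleast_2d(rho), nan=0.0)
    tif = np.ones(len(measured))
    for i, gi in enumerate(measured):
        vals = []
        for j, gj in enumerate(measured):
            if i == j:
                continue
            d = dist[didx[gi], didx[gj]]
            if np.isfinite(d) and d > 0:
                vals.append(np.exp(rho[i, j] / d))
        if vals:
            tif[i] = np.mean(vals)
    return pd.Series(tif, index=measured, name="TIF")


def _running_es(order: np.ndarray, t_abs: np.ndarray, in_path: np.ndarray,
                tif_full: np.ndarray) -> float:
    """Signed maximal deviation of the TIF-weighted enrichment running sum."""
    n = len(order)
    n_path = int(in_path.sum())
    if n_path == 0 or n_path == n:
        return 0.0
    inc = np.where(in_path, t_abs * tif_full, 0.0)[order]
    denom = inc.sum()
    if denom <= 0:
        return 0.0
    miss = 1.0 / (n - n_path)
    steps = np.where(inc > 0, inc / denom, 0.0) - np.where(in_path[order], 0.0, miss)
    # pathway genes with zero weight still step by 0 (not the miss penalty)
    run = np.cumsum(steps)
    return float(run[np.argmax(np.abs(run))])


def pwea(
    pathway: Pathway,
    expr: ExpressionMatrix,
    groups: GroupLabels,
    nperm: int = 1000,
    seed: int | None = None,
    perm_t: np.ndarray | None = None,
) -> PweaResult:
    """Pathway-weighted enrichment analysis for one pathway.

    The observed moderated-t profile is ranked genome-wide in decreasing
    order; pathway genes add |t| * TIF (normalized), others subtract
    1/(N - n_path); ES is the signed maximal deviation. The null permutes
    sample labels and recomputes the full differential expression, with the
    TIFs held fixed. ``perm_t`` allows a precomputed genes x nperm matrix
    of permuted t-statistics to be shared across pathways.
    """
    measured = sorted(pathway.nodes & set(expr.genes))
    if len(measured) < 2:
        return PweaResult(pathway.id, status="too-few-genes")
    tif = pwea_tif(pathway, expr)
    values = expr.values.to_numpy(dtype=float)
    m1, m2 = groups.masks(expr.samples)
    _, t_obs, _ = moderated_t_stats(values, m1, m2)
    genes = expr.genes
    in_path = np.array([g in set(measured) for g in genes])
    tif_full = np.ones(len(genes))
    gidx = {g: i for i, g in enumerate(genes)}
    for g, v in tif.items():
        tif_full[gidx[g]] = v
    order = np.argsort(-t_obs, kind="stable")
    es = _running_es(order, np.abs(t_obs), in_path, tif_full)
    if perm_t is None:
        perm_t = pwea_permuted_t(values, m1, m2, nperm, seed)
    es_perm = np.empty(perm_t.shape[1])
    for b in range(perm_t.shape[1]):
        tb = perm_t[:, b]
        ob = np.argsort(-tb, kind="stable")
        es_perm[b] = _running_es(ob, np.abs(tb), in_path, tif_full)
    nperm_eff = perm_t.shape[1]
    p = (1 + int(np.sum(np.abs(es_perm) >= abs(es)))) / (nperm_eff + 1)
    return PweaResult(pathway.id, es=es, p=float(p), tif=tif)


def pwea_permuted_t(
    values: np.ndarray, mask1: np.ndarray, mask2: np.ndarray,
    nperm: int, seed: int | None
) -> np.ndarray:
    """genes x nperm matrix of moderated-t under sample-label permutations.

    Each permutation's shuffle is derived from an independent child seed
    indexed by the permutation number, so the loop can be distributed
    without changing results.
    """
    n = values.shape[1]
    n1 = int(mask1.sum())
    out = np.empty((values.shape[0], nperm))
    for b in range(nperm):
        rng = _rng_for(seed, "pwea-perm", b)
        perm = rng.permutation(n)
        pm1 = np.zeros(n, dtype=bool)
        pm1[perm[:n1]] = True
        _, t, _ = moderated_t_stats(values, pm1, ~pm1)
        out[:, b] = t
    return out


# ---------------------------------------------------------------------------
# TAPPA
# ---------------------------------------------------------------------------


@dataclass
class TappaResult:
    pathway: str
    status: str = "ok"
    u: float = np.nan
    p: float = np.nan
    pci: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))


def tappa_pci(pathway: Pathway, expr: ExpressionMatrix) -> pd.Series:
    """Per-sample pathway connectivity index.

    Pathway genes are z-scored across samples (population sd); with A the
    undirected skeleton adjacency plus self-loops and
    T = {(i,j): i<=j, A_ij=1},
    PCI_s = (1/|T|) sum_T sign(x_i + x_j) sqrt(|x_i| |x_j|),
    so a self-loop contributes the signed magnitude sign(x_i)|x_i| = x_i.
    """
    import warnings

    measured = sorted(pathway.nodes & set(expr.genes))
    if len(measured) < 1:
        raise ValueError("no measured pathway genes")
    x = expr.values.loc[measured].to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    const = (sd == 0).ravel()
    if const.any():
        warnings.warn(
            f"tappa: {int(const.sum())} constant gene(s) in {pathway.id!r} z-scored to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mu) / sd, 0.0)
    skel = undirected_skeleton(pathway)
    gidx = {g: i for i, g in enumerate(measured)}
    terms: list[tuple[int, int]] = [(i, i) for i in range(len(measured))]
    for a, b in skel.edges():
        if a in gidx and b in gidx and a != b:
            i, j = sorted((gidx[a], gidx[b]))
            terms.append((i, j))
    ii = np.array([t[0] for t in terms])
    jj = np.array([t[1] for t in terms])
    prod = np.sign(z[ii] + z[jj]) * np.sqrt(np.abs(z[ii]) * np.abs(z[jj]))
    pci = prod.sum(axis=0) / len(terms)
    return pd.Series(pci, index=expr.samples, name="PCI")


def tappa(
    pathway: Pathway, expr: ExpressionMatrix, groups: GroupLabels
) -> TappaResult:
    """Topological analysis of pathway phenotype association for one pathway."""
    measured = pathway.nodes & set(expr.genes)
    if len(measured) < 2:
        return TappaResult(pathway.id, status="too-few-genes")
    pci = tappa_pci(pathway, expr)
    m1, m2 = groups.masks(expr.samples)
    a, b = pci.to_numpy()[m1], pci.to_numpy()[m2]
    if np.ptp(np.concatenate([a, b])) == 0:  # all PCI identical: no separation
        return TappaResult(pathway.id, u=float(len(a) * len(b) / 2), p=1.0, pci=pci)
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return TappaResult(pathway.id, u=float(res.statistic), p=float(res.pvalue), pci=pci)
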