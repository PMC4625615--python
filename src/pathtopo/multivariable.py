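"""Multivariable topology-based pathway analysis: DEGraph, TopologyGSA, clipper.

These methods test the joint multivariate distribution of the pathway's
genes between two groups:

* DEGraph projects each sample onto the k smoothest eigenvectors of the
  pathway (optionally signed) graph Laplacian and applies a two-sample
  Hotelling T^2 test in the reduced space, component by component.
* TopologyGSA fits decomposable Gaussian graphical models on the junction
  tree of the moralized, triangulated pathway DAG and compares groups by
  likelihood-ratio statistics for the mean and for the covariance, with
  sample-label permutation nulls; per-clique tests are reported as well.
* clipper performs the same two pathway-level tests with Ledoit-Wolf-shrunk
  covariances (valid when samples are fewer than genes), then walks the
  junction tree to report the root-to-leaf clique path most associated with
  the phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.covariance import ledoit_wolf_shrinkage

from .graphs import (
    JunctionTree,
    build_junction_tree,
    graph_laplacian,
    moralize,
    to_digraph,
    triangulate,
    undirected_skeleton,
)
from .pathway import Pathway, induced_subgraph
from .preprocess import ExpressionMatrix, GroupLabels
from .univariable import _rng_for

__all__ = ["CliqueTestResult", "MultivarResult", "degraph", "topology_gsa", "clipper",
           "hotelling_t2", "decomposable_concentration", "pathway_junction_tree"]


@dataclass
class CliqueTestResult:
    clique: frozenset[str]
    p_mean: float = np.nan
    p_var: float = np.nan
    stat_mean: float = np.nan
    stat_var: float = np.nan

    @property
    def score(self) -> float:
        """-log10 of the smallest available clique p-value."""
        ps = [p for p in (self.p_mean, self.p_var) if np.isfinite(p)]
        return float(-np.log10(min(ps))) if ps else 0.0


@dataclass
class MultivarResult:
    pathway: str
    status: str = "ok"
    p: float = np.nan  # selected-test p-value
    p_mean: float = np.nan
    p_var: float = np.nan
    p_var_asymptotic: float = np.nan
    k: int | None = None  # DEGraph subspace dimension
    n_components: int = 0
    cliques: list[CliqueTestResult] = field(default_factory=list)
    best_path: list[int] = field(default_factory=list)
    best_path_score: float = np.nan
    junction_tree: JunctionTree | None = None
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def _group_arrays(expr: ExpressionMatrix, groups: GroupLabels, genes: list[str]):
    x = expr.values.loc[genes].to_numpy(dtype=float)
    m1, m2 = groups.masks(expr.samples)
    return x[:, m1], x[:, m2]


def hotelling_t2(x1: np.ndarray, x2: np.ndarray, ridge: bool = True):
    """Two-sample Hotelling T^2 with the exact F transform.

    x1, x2 are features x samples. Returns (T2, F, df1, df2, p, ridged).
    A numerically singular pooled covariance is regularized by adding
    1e-8 * trace/k to the diagonal (flagged).
    """
    k, n1 = x1.shape
    n2 = x2.shape[1]
    n = n1 + n2
    d = x1.mean(axis=1) - x2.mean(axis=1)
    s_pool = (
        (x1 - x1.mean(axis=1, keepdims=True)) @ (x1 - x1.mean(axis=1, keepdims=True)).T
        + (x2 - x2.mean(axis=1, keepdims=True)) @ (x2 - x2.mean(axis=1, keepdims=True)).T
    ) / (n - 2)
    ridged = False
    if ridge and (s_pool.size == 0 or np.linalg.cond(s_pool) > 1e10):
        s_pool = s_pool + np.eye(k) * (1e-8 * max(np.trace(s_pool), 1.0) / max(k, 1))
        ridged = True
    t2 = float(n1 * n2 / n * d @ np.linalg.solve(s_pool, d))
    df1, df2 = k, n - k - 1
    if df2 <= 0:
        return t2, np.nan, df1, df2, np.nan, ridged
    f = t2 * df2 / (df1 * (n - 2))
    p = float(stats.f.sf(f, df1, df2))
    return t2, f, df1, df2, p, ridged


def pathway_junction_tree(pathway: Pathway, genes: list[str] | None = None):
    """DAG -> moral graph -> min-fill triangulation -> junction tree.

    Undirected edges are oriented both ways first; a greedy minimal
    feedback-edge set (edges scanned in sorted order, kept only when they do
    not close a directed cycle) enforces acyclicity. Returns
    (junction tree, dropped edge list).
    """
    if genes is not None:
        pathway = induced_subgraph(pathway, set(genes) & pathway.nodes)
    g = to_digraph(pathway, "both")
    dag = nx.DiGraph()
    dag.add_nodes_from(sorted(g.nodes))
    dropped: list[tuple[str, str]] = []
    for u, v in sorted(set((u, v) for u, v, _ in g.edges(keys=True) if u != v)):
        if dag.has_node(v) and nx.has_path(dag, v, u):
            dropped.append((u, v))
        else:
            dag.add_edge(u, v)
    moral = moralize(dag)
    chordal, _ = triangulate(moral)
    return build_junction_tree(chordal), dropped


def decomposable_concentration(
    S: np.ndarray, genes: list[str], jt: JunctionTree
) -> np.ndarray:
    """MLE concentration of a decomposable Gaussian model.

    K = sum over cliques of the padded inverse clique covariance minus the
    sum over separators of the padded inverse separator covariance.
    Raises LinAlgError when a clique covariance is singular (too few
    samples for the largest clique).
    """
    gidx = {g: i for i, g in enumerate(genes)}
    K = np.zeros_like(S)

    def add(block: frozenset[str], sign: float) -> None:
        if not block:
            return
        ix = np.array(sorted(gidx[g] for g in block))
        sub = S[np.ix_(ix, ix)]
        if np.linalg.cond(sub) > 1e10:
            raise np.linalg.LinAlgError(
                f"singular covariance on clique/separator of size {len(ix)}"
            )
        K[np.ix_(ix, ix)] += sign * np.linalg.inv(sub)

    for c in jt.cliques:
        add(c, +1.0)
    for s in jt.separators:
        add(s, -1.0)
    return K


def _mle_cov(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=1, keepdims=True)
    return xc @ xc.T / x.shape[1]


def _lw_cov(x: np.ndarray, shrinkage: float | None = None) -> np.ndarray:
    """Ledoit-Wolf-shrunk MLE covariance, target (trace(S)/p) * I."""
    S = _mle_cov(x)
    p = S.shape[0]
    if shrinkage is None:
        lam = float(ledoit_wolf_shrinkage((x - x.mean(axis=1, keepdims=True)).T,
                                          assume_centered=True))
    else:
        lam = float(shrinkage)
    mu = np.trace(S) / p
    return (1.0 - lam) * S + lam * mu * np.eye(p)


# -- batched permutation engine --------------------------------------------
#
# All permutation statistics are computed with stacked linear algebra: axis 0
# indexes the group assignment (entry 0 = observed labels, the rest the
# permutations), so each clique costs a handful of batched inv/slogdet calls
# instead of one Python loop iteration per permutation.


def _batch_center(X: np.ndarray, M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Masked, group-centered copies: X (p,n), M (B,n) -> C (B,p,n), mu (B,p)."""
    ng = M[0].sum()
    mu = (X @ M.T).T / ng
    C = (X[None, :, :] - mu[:, :, None]) * M[:, None, :]
    return C, mu


def _batch_lw_shrinkage(C: np.ndarray, ng: int) -> np.ndarray:
    """Analytic Ledoit-Wolf intensity per batch entry, target (trace/p) I.

    C is the (B, p, n) group-centered, masked data. Matches
    ``sklearn.covariance.ledoit_wolf_shrinkage(assume_centered=True)``.
    """
    p = C.shape[1]
    S = np.einsum("bpn,bqn->bpq", C, C) / ng
    tr = np.einsum("bpp->b", S)
    mu = tr / p
    frob2 = np.einsum("bpq,bpq->b", S, S)
    sq = np.einsum("bpn,bpn->bn", C, C)  # ||x_s||^2 per sample (0 off-group)
    beta_ = (sq**2).sum(axis=1)
    beta = (beta_ / ng - frob2) / (p * ng)
    delta = (frob2 - 2.0 * mu * tr + p * mu**2) / p
    beta = np.minimum(beta, delta)
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(delta > 0, beta / delta, 0.0)
    return np.clip(lam, 0.0, 1.0)


def _batch_group_cov(X, M, shrinkage):
    """(S, mu) per batch entry; S optionally Ledoit-Wolf shrunk."""
    ng = int(M[0].sum())
    C, mu = _batch_center(X, M)
    S = np.einsum("bpn,bqn->bpq", C, C) / ng
    if shrinkage == "none":
        return S, mu
    lam = (
        _batch_lw_shrinkage(C, ng)
        if shrinkage is None
        else np.full(S.shape[0], float(shrinkage))
    )
    p = S.shape[1]
    tr_mu = np.einsum("bpp->b", S) / p
    S = (1.0 - lam)[:, None, None] * S
    diag = np.arange(p)
    S[:, diag, diag] += (lam * tr_mu)[:, None]
    return S, mu


def _batch_inv_logdet(A: np.ndarray):
    """Stacked inverse + log-determinant with validity flags.

    Entries whose matrix is not (numerically) positive definite are flagged
    invalid; their inverse slot holds the identity so downstream assembly
    stays finite.
    """
    sign, logdet = np.linalg.slogdet(A)
    valid = (sign > 0) & np.isfinite(logdet)
    eye = np.eye(A.shape[-1])
    A_safe = np.where(valid[:, None, None], A, eye)
    try:
        inv = np.linalg.inv(A_safe)
    except np.linalg.LinAlgError:
        inv = np.empty_like(A)
        for b in range(A.shape[0]):
            try:
                inv[b] = np.linalg.inv(A_safe[b])
            except np.linalg.LinAlgError:
                inv[b] = eye
                valid[b] = False
    bad = ~np.isfinite(inv).all(axis=(1, 2))
    if bad.any():
        valid &= ~bad
        inv[bad] = eye
    return inv, logdet, valid


def _tree_engine(X, masks, clique_ix, sep_ix, shrinkage):
    """Pathway-level and per-clique statistics for every group assignment.

    X is genes x samples (rows ordered like the sorted measured genes),
    masks (B, n) boolean group-1 indicators with row 0 the observed labels,
    clique_ix/sep_ix the junction tree's cliques and separators as sorted
    row-index arrays. Returns arrays: mean/var statistics (B,), per-clique
    mean/var statistics (B, C).
    """
    p, n = X.shape
    n1 = int(masks[0].sum())
    n2 = n - n1
    S1, mu1 = _batch_group_cov(X, masks, shrinkage)
    S2, mu2 = _batch_group_cov(X, ~masks, shrinkage)
    S_pool = (n1 * S1 + n2 * S2) / n
    d = mu1 - mu2
    B = masks.shape[0]
    C = len(clique_ix)

    def assemble(S):
        """K (B,p,p) from clique/separator inverses of S; validity (B,)."""
        K = np.zeros_like(S)
        valid = np.ones(B, dtype=bool)
        for ix in clique_ix:
            inv, _, ok = _batch_inv_logdet(S[:, ix[:, None], ix])
            K[:, ix[:, None], ix] += inv
            valid &= ok
        for ix in sep_ix:
            if len(ix) == 0:
                continue
            inv, _, ok = _batch_inv_logdet(S[:, ix[:, None], ix])
            K[:, ix[:, None], ix] -= inv
            valid &= ok
        return K, valid

    K_pool, pool_ok = assemble(S_pool)
    mean_stat = np.einsum("bp,bpq,bq->b", d, K_pool, d) * n1 * n2 / n
    mean_stat[~pool_ok] = np.nan

    K1, ok1 = assemble(S1)
    K2, ok2 = assemble(S2)
    var_ok = pool_ok & ok1 & ok2

    def deviance(K, S, m):
        sign, logdet = np.linalg.slogdet(K)
        tr = np.einsum("bpq,bqp->b", K, S)
        with np.errstate(invalid="ignore"):
            dev = m * (-logdet + tr)
        dev[sign <= 0] = np.nan
        return dev

    with np.errstate(invalid="ignore"):
        var_stat = (
            deviance(K_pool, S1, n1) + deviance(K_pool, S2, n2)
            - deviance(K1, S1, n1) - deviance(K2, S2, n2)
        )
    var_stat[~var_ok] = np.nan

    cl_mean = np.full((B, C), np.nan)
    cl_var = np.full((B, C), np.nan)
    for ci, ix in enumerate(clique_ix):
        Sp = S_pool[:, ix[:, None], ix]
        inv_p, ld_p, ok_p = _batch_inv_logdet(Sp)
        dc = d[:, ix]
        ms = np.einsum("bp,bpq,bq->b", dc, inv_p, dc) * n1 * n2 / n
        ms[~ok_p] = np.nan
        cl_mean[:, ci] = ms
        _, ld_1, ok_a = _batch_inv_logdet(S1[:, ix[:, None], ix])
        _, ld_2, ok_b = _batch_inv_logdet(S2[:, ix[:, None], ix])
        with np.errstate(invalid="ignore"):
            vs = n * ld_p - n1 * ld_1 - n2 * ld_2
        vs[~(ok_p & ok_a & ok_b)] = np.nan
        cl_var[:, ci] = vs
    return {"mean": mean_stat, "var": var_stat, "cl_mean": cl_mean, "cl_var": cl_var}


def _permutation_masks(n: int, n1: int, nperm: int, seed, salt) -> np.ndarray:
    masks = np.zeros((nperm, n), dtype=bool)
    for b in range(nperm):
        rng = _rng_for(seed, salt, b)
        masks[b, rng.permutation(n)[:n1]] = True
    return masks


def _perm_p(obs: float, perm: np.ndarray) -> float:
    perm = perm[np.isfinite(perm)]
    if not np.isfinite(obs) or len(perm) == 0:
        return np.nan
    return float((1 + np.sum(perm >= obs)) / (len(perm) + 1))


# ---------------------------------------------------------------------------
# DEGraph
# ---------------------------------------------------------------------------


def degraph(
    pathway: Pathway,
    expr: ExpressionMatrix,
    groups: GroupLabels,
    k: int | None = None,
    signed: bool = False,
) -> MultivarResult:
    """Graph-Laplacian-smoothed Hotelling test, per connected component.

    The pathway p-value is the Bonferroni-corrected minimum component
    p-value. ``k`` defaults to min(ceil(p_genes/4), n-3, 5) and is clipped
    per component to the component size.
    """
    measured = sorted(pathway.nodes & set(expr.genes))
    if len(measured) < 2:
        return MultivarResult(pathway.id, status="too-few-genes")
    sub = induced_subgraph(pathway, measured)
    x1, x2 = _group_arrays(expr, groups, measured)
    n = x1.shape[1] + x2.shape[1]
    notes: list[str] = []
    if k is None:
        k = max(1, min(int(np.ceil(len(measured) / 4)), n - 3, 5))
    if k > n - 3:
        notes.append(f"k clipped from {k} to {n - 3}")
        k = max(1, n - 3)
    L, lnodes = graph_laplacian(sub, signed=signed)
    skel = undirected_skeleton(sub)
    comps = [sorted(c) for c in nx.connected_components(skel) if len(c) >= 2]
    if not comps:
        return MultivarResult(pathway.id, status="no-connected-component", k=k)
    lidx = {g: i for i, g in enumerate(lnodes)}
    gidx = {g: i for i, g in enumerate(measured)}
    p_comps = []
    ridged_any = False
    for comp in sorted(comps, key=min):
        ix_l = np.array([lidx[g] for g in comp])
        ix_x = np.array([gidx[g] for g in comp])
        k_c = min(k, len(comp))
        Lc = L[np.ix_(ix_l, ix_l)]
        evals, evecs = np.linalg.eigh(Lc)
        U = evecs[:, np.argsort(evals)[:k_c]]
        y1, y2 = U.T @ x1[ix_x], U.T @ x2[ix_x]
        _, _, _, _, p, ridged = hotelling_t2(y1, y2)
        ridged_any = ridged_any or ridged
        p_comps.append(p)
    if ridged_any:
        notes.append("singular projected covariance regularized by ridge")
    p_comps = [p for p in p_comps if np.isfinite(p)]
    if not p_comps:
        return MultivarResult(pathway.id, status="insufficient-samples", k=k,
                              n_components=len(comps), notes=notes)
    p_path = min(1.0, min(p_comps) * len(p_comps))
    return MultivarResult(
        pathway.id, p=p_path, p_mean=p_path, k=k,
        n_components=len(comps), notes=notes,
    )


# ---------------------------------------------------------------------------
# TopologyGSA / clipper
# ---------------------------------------------------------------------------


def _tree_tests(
    pathway: Pathway,
    expr: ExpressionMatrix,
    groups: GroupLabels,
    test: str,
    nperm: int,
    seed,
    shrinkage,  # "none" = raw MLE covariances; None = analytic LW; float = forced
    salt: str,
) -> MultivarResult:
    if test not in ("mean", "var"):
        raise ValueError(f"test must be 'mean' or 'var', got {test!r}")
    measured = sorted(pathway.nodes & set(expr.genes))
    if len(measured) < 2:
        return MultivarResult(pathway.id, status="too-few-genes")
    jt, dropped = pathway_junction_tree(pathway, measured)
    notes = [f"dropped feedback edge {u}->{v}" for u, v in dropped]
    x = expr.values.loc[measured].to_numpy(dtype=float)
    m1, m2 = groups.masks(expr.samples)
    n1, n2 = int(m1.sum()), int(m2.sum())
    n = n1 + n2
    max_clique = max(len(c) for c in jt.cliques)
    gpos = {g: i for i, g in enumerate(measured)}
    clique_ix = [np.array(sorted(gpos[g] for g in c)) for c in jt.cliques]
    sep_ix = [np.array(sorted(gpos[g] for g in s), dtype=int) for s in jt.separators]
    masks = np.vstack([m1, _permutation_masks(n, n1, nperm, seed,
                                              salt + ":" + pathway.id)])
    stats_all = _tree_engine(x, masks, clique_ix, sep_ix, shrinkage)
    mean_obs, mean_perm = stats_all["mean"][0], stats_all["mean"][1:]
    var_obs, var_perm = stats_all["var"][0], stats_all["var"][1:]
    clique_obs = list(zip(stats_all["cl_mean"][0], stats_all["cl_var"][0]))
    cl_mean_perm = stats_all["cl_mean"][1:]
    cl_var_perm = stats_all["cl_var"][1:]
    if not np.isfinite(mean_obs):
        return MultivarResult(pathway.id, status="insufficient-samples",
                              junction_tree=jt, notes=notes)
    if test == "var" and shrinkage == "none" and min(n1, n2) <= max_clique:
        var_obs = np.nan
        notes.append(
            f"covariance test skipped: largest clique ({max_clique}) "
            f"not smaller than the smaller group ({min(n1, n2)})"
        )
    p_mean = _perm_p(mean_obs, mean_perm)
    p_var = _perm_p(var_obs, var_perm) if np.isfinite(var_obs) else np.nan
    # asymptotic chi^2 for the covariance statistic when sample size permits
    p_var_asym = np.nan
    if np.isfinite(var_obs):
        df = sum(len(c) * (len(c) + 1) // 2 for c in jt.cliques) - sum(
            len(s) * (len(s) + 1) // 2 for s in jt.separators
        )
        p_var_asym = float(stats.chi2.sf(var_obs, df))
    cliques = []
    for ci, c in enumerate(jt.cliques):
        cm, cv = clique_obs[ci]
        cliques.append(
            CliqueTestResult(
                c,
                p_mean=_perm_p(cm, cl_mean_perm[:, ci]),
                p_var=_perm_p(cv, cl_var_perm[:, ci]) if np.isfinite(cv) else np.nan,
                stat_mean=float(cm),
                stat_var=float(cv),
            )
        )
    selected = p_mean if test == "mean" else p_var
    return MultivarResult(
        pathway.id,
        p=selected if selected is not None else np.nan,
        p_mean=p_mean,
        p_var=p_var,
        p_var_asymptotic=p_var_asym,
        cliques=cliques,
        junction_tree=jt,
        notes=notes,
    )


def topology_gsa(
    pathway: Pathway,
    expr: ExpressionMatrix,
    groups: GroupLabels,
    test: str = "mean",
    nperm: int = 1000,
    seed: int | None = None,
) -> MultivarResult:
    """Junction-tree Gaussian graphical model test (mean or covariance),
    with per-clique tests; p-values by sample-label permutation."""
    return _tree_tests(pathway, expr, groups, test, nperm, seed, "none", "tree")


def clipper(
    pathway: Pathway,
    expr: ExpressionMatrix,
    groups: GroupLabels,
    test: str = "mean",
    nperm: int = 1000,
    seed: int | None = None,
    shrinkage: float | None = None,
) -> MultivarResult:
    """Two-step junction-tree analysis with Ledoit-Wolf-shrunk covariances.

    Step (i): pathway-level mean/covariance permutation tests, valid for
    n < p thanks to shrinkage toward (trace/p) I with analytic intensity
    (``shrinkage`` overrides the intensity, 0 forcing the unshrunk limit).
    Step (ii): per-clique tests on the junction tree; the root is the
    clique with the smallest selected-test p-value and the reported best
    path is the root-to-leaf path maximizing the mean clique score
    (-log10 of the smallest clique p).
    """
    res = _tree_tests(
        pathway, expr, groups, test, nperm, seed, shrinkage, "tree",
    )
    if res.status != "ok" or not res.cliques:
        return res
    jt = res.junction_tree
    # root: smallest selected-test p; permutation-floor ties broken by the
    # larger observed statistic (the permutation p saturates at 1/(nperm+1))
    def root_key(c: CliqueTestResult):
        p = c.p_mean if test == "mean" else c.p_var
        s = c.stat_mean if test == "mean" else c.stat_var
        return (p if np.isfinite(p) else np.inf, -(s if np.isfinite(s) else -np.inf))

    root = int(min(range(len(res.cliques)), key=lambda i: root_key(res.cliques[i])))
    t = nx.Graph()
    t.add_nodes_from(range(len(jt.cliques)))
    t.add_edges_from(jt.tree_edges)
    leaves = [v for v in t.nodes if t.degree(v) <= 1 and v != root]
    best_path, best_score = [root], res.cliques[root].score
    for leaf in leaves:
        path = nx.shortest_path(t, root, leaf)
        score = float(np.mean([res.cliques[i].score for i in path]))
        if score > best_score + 1e-12 or (
            abs(score - best_score) <= 1e-12 and path < best_path
        ):
            best_path, best_score = path, score
    res.best_path = list(best_path)
    res.best_path_score = float(best_score)
    return res
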