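import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import optimize, stats

from pathtopo.graphs import build_junction_tree, triangulate
from pathtopo.multivariable import (
    clipper,
    decomposable_concentration,
    degraph,
    hotelling_t2,
    pathway_junction_tree,
    topology_gsa,
)
from pathtopo.pathway import build_pathway
from pathtopo.simulate import SimulationTruth, make_random_pathway, simulate_expression
from tests.conftest import make_expr, make_groups


def complete_pathway(genes):
    edges = [(a, b, True, 1) for a, b in itertools.combinations(genes, 2)]
    return build_pathway("full", genes, edges)


class TestHotellingEquivalence:
    def test_degraph_full_k_equals_classical_hotelling(self):
        """With k = number of genes the Laplacian projection spans the full
        space, so the p-value must equal the classical two-sample
        Hotelling T^2 / F p-value computed independently."""
        import pingouin

        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(4)]
        pw = complete_pathway(genes)
        groups, samples = make_groups(8, 8)
        x = rng.standard_normal((4, 16))
        x[:, 8:] += 0.8
        expr = make_expr(x, genes, samples)
        res = degraph(pw, expr, groups, k=4)
        ref = pingouin.multivariate_ttest(x[:, :8].T, x[:, 8:].T)
        assert abs(res.p - float(ref["pval"].iloc[0])) < 1e-8

    def test_hotelling_matches_formula(self):
        rng = np.random.default_rng(1)
        x1, x2 = rng.standard_normal((3, 10)), rng.standard_normal((3, 12))
        t2, f, df1, df2, p, _ = hotelling_t2(x1, x2)
        n1, n2, k = 10, 12, 3
        d = x1.mean(1) - x2.mean(1)
        s = (np.cov(x1) * (n1 - 1) + np.cov(x2) * (n2 - 1)) / (n1 + n2 - 2)
        t2_ref = n1 * n2 / (n1 + n2) * d @ np.linalg.solve(s, d)
        assert np.isclose(t2, t2_ref)
        assert np.isclose(p, stats.f.sf(t2_ref * df2 / (df1 * (n1 + n2 - 2)), df1, df2))


class TestDegraph:
    def test_invariant_to_gene_and_sample_order(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(6)]
        pw = make_random_pathway(6, 0.4, seed=3, node_prefix="g")
        pw = build_pathway("p", genes,
                          [(f"g{int(e.source[1:]):d}", f"g{int(e.target[1:]):d}",
                            e.directed, e.sign) for e in pw.edges])
        groups, samples = make_groups(5, 5)
        x = rng.standard_normal((6, 10))
        expr = make_expr(x, genes, samples)
        base = degraph(pw, expr, groups, k=2)
        order = rng.permutation(6)
        expr2 = make_expr(x[order], [genes[i] for i in order], samples)
        assert np.isclose(degraph(pw, expr2, groups, k=2).p, base.p)
        # reorder samples within groups
        cols = [2, 0, 1, 4, 3, 7, 5, 6, 9, 8]
        expr3 = make_expr(x[:, cols], genes, [samples[i] for i in cols])
        assert np.isclose(degraph(pw, expr3, groups, k=2).p, base.p)

    def test_smoothing_gains_power_on_smooth_shift(self):
        """A mean shift aligned with the smoothest Laplacian eigenvector is
        detected more often with k=1 than with the full-dimensional test."""
        genes = [f"g{i}" for i in range(6)]
        pw = complete_pathway(genes)  # smoothest eigenvector = constant
        groups, samples = make_groups(6, 6)
        wins = 0
        rng = np.random.default_rng(4)
        for rep in range(60):
            x = rng.standard_normal((6, 12))
            x[:, 6:] += 0.6  # constant shift = smoothest direction
            expr = make_expr(x, genes, samples)
            p1 = degraph(pw, expr, groups, k=1).p
            pfull = degraph(pw, expr, groups, k=6).p
            wins += p1 <= pfull
        assert wins >= 0.9 * 60

    def test_too_few_genes(self):
        pw = build_pathway("p", ["zz"], [])
        groups, samples = make_groups(3, 3)
        expr = make_expr(np.zeros((1, 6)), ["other"], samples)
        assert degraph(pw, expr, groups).status == "too-few-genes"


def random_chordal_fixture(n_nodes, seed):
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(f"g{i}" for i in range(n_nodes))
    for a, b in itertools.combinations(sorted(g.nodes), 2):
        if rng.random() < 0.45:
            g.add_edge(a, b)
    chordal, _ = triangulate(g)
    return chordal


def constrained_mle_oracle(S, genes, graph):
    """Numeric maximization of the Gaussian log-likelihood with off-graph
    concentration entries forced to zero (independent of the junction-tree
    assembly it checks)."""
    p = len(genes)
    gidx = {g: i for i, g in enumerate(genes)}
    free = [(i, i) for i in range(p)] + sorted(
        (min(gidx[a], gidx[b]), max(gidx[a], gidx[b])) for a, b in graph.edges()
    )

    def unpack(theta):
        K = np.zeros((p, p))
        for t, (i, j) in zip(theta, free):
            K[i, j] = t
            K[j, i] = t
        return K

    def negloglik(theta):
        K = unpack(theta)
        sign, logdet = np.linalg.slogdet(K)
        if sign <= 0:
            return 1e6
        return -logdet + np.trace(K @ S)

    def grad(theta):
        K = unpack(theta)
        sign, _ = np.linalg.slogdet(K)
        if sign <= 0:
            return np.zeros(len(theta))
        G = S - np.linalg.inv(K)  # d/dK of (-logdet K + tr K S)
        return np.array([G[i, j] * (1.0 if i == j else 2.0) for i, j in free])

    theta0 = np.array([1.0 if i == j else 0.0 for i, j in free])
    res = optimize.minimize(negloglik, theta0, jac=grad, method="BFGS",
                            options={"gtol": 1e-12, "maxiter": 2000})
    return unpack(res.x)


class TestDecomposableMle:
    def test_matches_numeric_optimizer(self):
        rng = np.random.default_rng(0)
        for seed in range(3):
            chordal = random_chordal_fixture(5, seed)
            genes = sorted(chordal.nodes)
            x = rng.standard_normal((len(genes), 60))
            S = np.cov(x, bias=True)
            jt = build_junction_tree(chordal)
            K_hat = decomposable_concentration(S, genes, jt)
            K_ref = constrained_mle_oracle(S, genes, chordal)
            assert np.abs(K_hat - K_ref).max() < 1e-4

    def test_complete_graph_inverse_covariance(self):
        rng = np.random.default_rng(1)
        genes = ["a", "b", "c", "d"]
        x = rng.standard_normal((4, 50))
        S = np.cov(x, bias=True)
        jt = build_junction_tree(nx.complete_graph(genes))
        K = decomposable_concentration(S, genes, jt)
        assert np.allclose(K, np.linalg.inv(S), atol=1e-10)

    def test_off_graph_entries_zero(self):
        rng = np.random.default_rng(2)
        chordal = random_chordal_fixture(6, 11)
        genes = sorted(chordal.nodes)
        x = rng.standard_normal((len(genes), 80))
        S = np.cov(x, bias=True)
        K = decomposable_concentration(S, genes, build_junction_tree(chordal))
        for i, a in enumerate(genes):
            for j, b in enumerate(genes):
                if i < j and not chordal.has_edge(a, b):
                    assert abs(K[i, j]) < 1e-10


class TestTopologyGsa:
    def _planted(self, seed, effect=0.0):
        pw = make_random_pathway(8, 0.25, seed=seed, node_prefix="g")
        coll_genes = sorted(pw.nodes)
        rng = np.random.default_rng(seed + 100)
        groups, samples = make_groups(5, 5)
        x = rng.standard_normal((8, 10))
        x[:3, 5:] += effect
        expr = make_expr(x, coll_genes, samples)
        return pw, expr, groups

    def test_junction_tree_running_intersection(self):
        for seed in range(10):
            pw = make_random_pathway(10, 0.25, seed=seed)
            jt, _ = pathway_junction_tree(pw)
            assert jt.verify_running_intersection()

    def test_detects_planted_shift(self):
        pw, expr, groups = self._planted(3, effect=3.0)
        res = topology_gsa(pw, expr, groups, test="mean", nperm=200, seed=0)
        assert res.p < 0.05

    def test_reproducible(self):
        pw, expr, groups = self._planted(4)
        a = topology_gsa(pw, expr, groups, nperm=100, seed=8)
        b = topology_gsa(pw, expr, groups, nperm=100, seed=8)
        assert a.p == b.p
        assert 1 / 101 <= a.p <= 1.0

    def test_var_test_needs_samples(self):
        pw = complete_pathway([f"g{i}" for i in range(6)])
        groups, samples = make_groups(4, 4)
        rng = np.random.default_rng(0)
        expr = make_expr(rng.standard_normal((6, 8)), sorted(pw.nodes), samples)
        res = topology_gsa(pw, expr, groups, test="var", nperm=50, seed=0)
        assert res.status == "insufficient-samples" or np.isnan(res.p_var)

    def test_clique_results_reported(self):
        pw, expr, groups = self._planted(5)
        res = topology_gsa(pw, expr, groups, nperm=100, seed=2)
        assert len(res.cliques) == len(res.junction_tree.cliques)
        for c in res.cliques:
            assert 0 < c.p_mean <= 1.0


class TestClipper:
    def test_zero_shrinkage_matches_topology_gsa(self):
        """Forcing lambda = 0 must reproduce the unshrunk junction-tree test
        exactly (shared permutation stream)."""
        pw = make_random_pathway(6, 0.3, seed=6, node_prefix="g")
        groups, samples = make_groups(10, 10)
        rng = np.random.default_rng(3)
        expr = make_expr(rng.standard_normal((6, 20)), sorted(pw.nodes), samples)
        a = topology_gsa(pw, expr, groups, test="mean", nperm=100, seed=4)
        b = clipper(pw, expr, groups, test="mean", nperm=100, seed=4, shrinkage=0.0)
        assert a.p_mean == b.p_mean

    def test_single_clique_path_is_root(self):
        pw = complete_pathway(["a", "b", "c"])
        groups, samples = make_groups(4, 4)
        rng = np.random.default_rng(5)
        expr = make_expr(rng.standard_normal((3, 8)), ["a", "b", "c"], samples)
        res = clipper(pw, expr, groups, nperm=50, seed=1)
        assert res.best_path == [0] and len(res.cliques) == 1

    def test_works_with_fewer_samples_than_genes(self):
        pw = complete_pathway([f"g{i}" for i in range(10)])
        groups, samples = make_groups(4, 4)
        rng = np.random.default_rng(6)
        expr = make_expr(rng.standard_normal((10, 8)), sorted(pw.nodes), samples)
        res = clipper(pw, expr, groups, nperm=50, seed=2)
        assert res.status == "ok" and np.isfinite(res.p)

    def test_planted_clique_on_best_path(self):
        nodes = [f"g{i:02d}" for i in range(13)]
        quads = [(0, 1, 2, 3), (3, 4, 5, 6), (6, 7, 8, 9), (9, 10, 11, 12)]
        edges = []
        for q in quads:
            for a, b in itertools.combinations(q, 2):
                edges.append((nodes[a], nodes[b], True, 1))
        pw = build_pathway("chain", nodes, edges)
        coll = [pw]
        from pathtopo.pathway import PathwayCollection

        collection = PathwayCollection.from_pathways(coll)
        target = set(nodes[i] for i in quads[1])
        hits = 0
        for rep in range(10):
            truth = SimulationTruth("chain", ("g04", "g05"), 2.0, "gaussian", None)
            expr, groups = simulate_expression(collection, truth, 4, 4,
                                               n_background=0, seed=700 + rep)
            res = clipper(pw, expr, groups, test="mean", nperm=100, seed=800 + rep)
            tgt = next(i for i, c in enumerate(res.cliques)
                       if set(c.clique) == target)
            hits += tgt in res.best_path
        assert hits >= 8


class TestLedoitWolfShrinkage:
    def test_batched_intensity_matches_sklearn(self):
        """The batched analytic shrinkage intensity agrees with
        sklearn's reference implementation on every batch entry."""
        from sklearn.covariance import ledoit_wolf_shrinkage

        from pathtopo.multivariable import _batch_center, _batch_lw_shrinkage, _lw_cov

        rng = np.random.default_rng(9)
        X = rng.standard_normal((7, 12))
        masks = np.zeros((5, 12), dtype=bool)
        for b in range(5):
            masks[b, rng.permutation(12)[:6]] = True
        C, _ = _batch_center(X, masks)
        lam = _batch_lw_shrinkage(C, 6)
        for b in range(5):
            xg = X[:, masks[b]]
            xc = (xg - xg.mean(axis=1, keepdims=True)).T
            ref = ledoit_wolf_shrinkage(xc, assume_centered=True)
            assert np.isclose(lam[b], ref, atol=1e-12)
            # and the reference covariance builder agrees with the target form
            S = _lw_cov(xg)
            mu = np.trace(np.cov(xg, bias=True)) / 7
            unshrunk = np.cov(xg, bias=True)
            assert np.allclose(S, (1 - ref) * unshrunk + ref * mu * np.eye(7))
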