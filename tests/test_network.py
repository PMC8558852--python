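"""Network construction and threshold selection against brute-force oracles."""

import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coexdiff.network import (
    build_network,
    clustering_coefficient,
    pearson_similarity,
    random_expectation_cr,
    scale_free_fit,
    select_threshold,
    threshold_scan,
)


def brute_force_clustering(adj: np.ndarray) -> float:
    """O(n^3) triangle enumeration per node."""
    n = adj.shape[0]
    coeffs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k == 0:
            continue
        if k < 2:
            coeffs.append(0.0)
            continue
        e = sum(
            1
            for x in range(k)
            for y in range(x + 1, k)
            if adj[nbrs[x], nbrs[y]]
        )
        coeffs.append(2 * e / (k * (k - 1)))
    return float(np.mean(coeffs)) if coeffs else 0.0


def random_adjacency(rng, n, p):
    a = rng.random((n, n)) < p
    a = np.triu(a, 1)
    return (a | a.T).astype(int)


@pytest.fixture()
def annotation_for(small_annotation):
    return small_annotation


class TestPearson:
    def test_duplicate_and_negated_gene(self, rng):
        x = rng.normal(size=10)
        mat = pd.DataFrame([x, x, -x], index=["a", "b", "c"])
        r = pearson_similarity(mat)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert r.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_two_pass_covariance(self, rng):
        mat = pd.DataFrame(rng.normal(size=(20, 15)))
        r = pearson_similarity(mat).to_numpy()
        x = mat.to_numpy()
        mu = x.mean(axis=1, keepdims=True)
        xc = x - mu
        cov = xc @ xc.T / (x.shape[1] - 1)
        sd = np.sqrt(np.diag(cov))
        expected = cov / np.outer(sd, sd)
        assert np.allclose(r, expected, atol=1e-12)

    def test_zero_variance_flagged_as_zero(self):
        mat = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], index=["flat", "g"])
        with pytest.warns(UserWarning):
            r = pearson_similarity(mat)
        assert r.loc["flat", "g"] == 0.0
        assert r.loc["flat", "flat"] == 1.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            pearson_similarity(pd.DataFrame([[1, 2]]))


class TestClustering:
    def test_triangle_and_path(self):
        tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        path = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        assert clustering_coefficient(tri) == 1.0
        assert clustering_coefficient(path) == 0.0

    def test_matches_brute_force_on_random_graphs(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 31))
            adj = random_adjacency(rng, n, rng.uniform(0.05, 0.6))
            assert clustering_coefficient(adj) == pytest.approx(
                brute_force_clustering(adj), abs=1e-12
            )

    def test_asymmetric_rejected(self):
        bad = np.array([[0, 1], [0, 0]])
        with pytest.raises(ValueError):
            clustering_coefficient(bad)


class TestRandomExpectation:
    def test_complete_and_empty(self):
        assert random_expectation_cr(5, 10) == 1.0
        assert random_expectation_cr(10, 0) == 0.0

    def test_matches_er_simulation(self, rng):
        n, p = 60, 0.2
        sims = []
        for s in range(500):
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            vals = [v for node, v in nx.clustering(g).items() if g.degree(node) > 0]
            sims.append(np.mean(vals) if vals else 0.0)
        m = g.number_of_edges()
        # density expectation with the nominal p
        assert abs(np.mean(sims) - p) < 0.02

    def test_too_many_edges(self):
        with pytest.raises(ValueError):
            random_expectation_cr(4, 7)


class TestScaleFree:
    def test_power_law_sample(self, rng):
        ks = np.arange(1, 1000)
        pmf = ks ** -2.5
        pmf = pmf / pmf.sum()
        degrees = rng.choice(ks, size=2000, p=pmf)
        slope, r2 = scale_free_fit(degrees)
        assert r2 >= 0.9
        assert -3.1 <= slope <= -1.9

    def test_er_fits_worse_than_power_law(self, rng):
        ks = np.arange(1, 1000)
        pmf = ks ** -2.5
        pmf = pmf / pmf.sum()
        worse = 0
        for s in range(20):
            g = nx.gnp_random_graph(500, 0.05, seed=int(rng.integers(2**31)))
            er_deg = [d for _, d in g.degree() if d > 0]
            _, r2_er = scale_free_fit(er_deg)
            _, r2_pl = scale_free_fit(rng.choice(ks, size=2000, p=pmf))
            worse += r2_er < r2_pl
        assert worse >= 18

    def test_degenerate_degrees(self):
        with pytest.warns(UserWarning):
            slope, r2 = scale_free_fit([3] * 50)
        assert r2 == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            scale_free_fit([0, 0, 0])


def block_similarity(genes, blocks, r_within=0.9, noise=0.0, rng=None):
    n = len(genes)
    r = np.zeros((n, n))
    for block in blocks:
        for i in block:
            for j in block:
                if i != j:
                    r[i, j] = r_within
    if noise and rng is not None:
        jitter = rng.uniform(-noise, noise, size=(n, n))
        jitter = (jitter + jitter.T) / 2
        r = np.clip(r + jitter, -0.99, 0.99)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=genes, columns=genes)


class TestThresholdScan:
    def test_no_edges_above_grid(self):
        sim = block_similarity([f"g{i}" for i in range(6)], [], 0.0)
        sim.values[~np.eye(6, dtype=bool)] = 0.3
        scan = threshold_scan(sim)
        assert (scan["n_edges"] == 0).all()

    def test_edge_count_monotone(self, rng):
        sim = block_similarity(
            [f"g{i}" for i in range(15)], [range(5)], 0.9, noise=0.3, rng=rng
        )
        scan = threshold_scan(sim)
        assert (np.diff(scan["n_edges"]) <= 0).all()

    def test_two_block_exact_edges(self):
        genes = [f"g{i}" for i in range(10)]
        sim = block_similarity(genes, [range(5), range(5, 10)], 0.9)
        scan = threshold_scan(sim, np.round(np.arange(0.5, 0.9, 0.01), 2))
        # for tau in (0.5, 0.9) the edges are exactly the within-block pairs
        assert (scan["n_edges"] == 20).all()

    def test_empty_grid_rejected(self):
        sim = block_similarity(["a", "b", "c"], [range(3)])
        with pytest.raises(ValueError):
            threshold_scan(sim, [])


class TestSelectThreshold:
    def make_scan(self, taus, deltas, sf=1.0, edges=10):
        return pd.DataFrame(
            {
                "tau": taus,
                "n_edges": edges,
                "co": deltas,
                "cr": 0.0,
                "delta": deltas,
                "sf_r2": sf,
                "n_nonisolated": 10,
            }
        )

    def test_unique_maximum(self):
        scan = self.make_scan([0.6, 0.7, 0.82, 0.9], [0.1, 0.2, 0.9, 0.3])
        assert select_threshold(scan).tau == 0.82

    def test_tie_goes_to_smaller_tau(self):
        scan = self.make_scan([0.80, 0.85], [0.5, 0.5])
        assert select_threshold(scan).tau == 0.80

    def test_gate_fallback_warns(self):
        scan = self.make_scan([0.6, 0.7], [0.2, 0.8], sf=0.0)
        with pytest.warns(UserWarning):
            choice = select_threshold(scan)
        assert not choice.scale_free_ok
        assert choice.tau == 0.7

    def test_all_edgeless_rejected(self):
        scan = self.make_scan([0.6], [0.0], edges=0)
        with pytest.raises(ValueError):
            select_threshold(scan)

    def test_plateau_prefers_onset_over_degenerate_tail(self):
        # sparse-tail row with delta ~1 must not beat the plateau onset
        scan = self.make_scan(
            [0.55, 0.60, 0.65, 0.95], [0.95, 0.96, 0.955, 0.99], sf=0.0, edges=50
        )
        with pytest.warns(UserWarning):
            assert select_threshold(scan).tau == 0.55


class TestBuildNetwork:
    def test_tau_above_max_r_empty(self, small_annotation):
        genes = list(small_annotation["gene_id"][:5])
        sim = block_similarity(genes, [range(5)], 0.4)
        net = build_network(sim, 0.9, small_annotation)
        assert net.number_of_edges() == 0

    def test_low_tau_complete_graph(self, small_annotation):
        genes = list(small_annotation["gene_id"][:5])
        sim = block_similarity(genes, [range(5)], 0.8)
        net = build_network(sim, 0.01, small_annotation)
        assert net.number_of_edges() == 10
        assert all("biotype" in net.nodes[n] for n in net.nodes)

    def test_planted_module_single_component(self, small_annotation):
        genes = list(small_annotation["gene_id"][:12])
        sim = block_similarity(genes, [range(8)], 0.9)
        net = build_network(sim, 0.5, small_annotation)
        comps = list(nx.connected_components(net))
        assert len(comps) == 1
        assert len(comps[0]) == 8

    def test_negative_correlation_sign_kept(self, small_annotation):
        genes = list(small_annotation["gene_id"][:2])
        sim = pd.DataFrame([[1.0, -0.9], [-0.9, 1.0]], index=genes, columns=genes)
        net = build_network(sim, 0.5, small_annotation)
        assert net.edges[genes[0], genes[1]]["sign"] == -1

    def test_invalid_tau(self, small_annotation):
        genes = list(small_annotation["gene_id"][:2])
        sim = block_similarity(genes, [range(2)])
        with pytest.raises(ValueError):
            build_network(sim, 1.5, small_annotation)
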