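import itertools

import numpy as np
import pytest

from paleodog import simdata
from paleodog.fstats import (
    AdmixtureGraph,
    FreqPanel,
    GraphEdge,
    blocks_from_genetic_map,
    d_stat,
    expected_f,
    f2,
    f3,
    f4,
    f4_ratio,
    fit_graph,
    weighted_block_jackknife,
)


def random_freq_panel(pops, n_sites=4000, n_blocks=20, seed=0, n_hap=20):
    rng = np.random.default_rng(seed)
    freq = {}
    count = {}
    for p in pops:
        anc = rng.uniform(0.05, 0.95, n_sites)
        cnt = rng.binomial(n_hap, anc)
        freq[p] = cnt / n_hap
        count[p] = np.full(n_sites, n_hap)
    block = np.arange(n_sites) // (n_sites // n_blocks)
    return FreqPanel(pops=list(pops), freq=freq, count=count, block_id=block)


def enumerate_routings(graph: AdmixtureGraph, pop: str):
    """Brute-force oracle: all root paths of a leaf with their probabilities.

    Returns a list of (probability, set of edge indices on the path).
    """
    children = {}
    for i, e in enumerate(graph.edges):
        children.setdefault(e.child, []).append((i, e))
    out = []

    def walk(node, prob, edges):
        parents = children.get(node, [])
        if not parents:
            out.append((prob, frozenset(edges)))
            return
        for i, e in parents:
            share = e.proportion if e.proportion is not None else 1.0
            walk(e.parent, prob * share, edges | {i})

    walk(graph.leaves[pop], 1.0, set())
    return out


def oracle_f4(graph, a, b, c, d):
    """Expected f4 by explicit enumeration over independent lineage routings."""
    lengths = graph.lengths()
    total = 0.0
    for (pa, ea), (pb, eb), (pc, ec), (pd, ed) in itertools.product(
        enumerate_routings(graph, a), enumerate_routings(graph, b),
        enumerate_routings(graph, c), enumerate_routings(graph, d),
    ):
        w = pa * pb * pc * pd
        s = 0.0
        for i in range(len(lengths)):
            sab = (i in ea) - (i in eb)
            scd = (i in ec) - (i in ed)
            s += sab * scd * lengths[i]
        total += w * s
    return total


class TestEstimators:
    def test_f4_identical_pair_zero(self):
        panel = random_freq_panel(["A", "B", "C"], seed=1)
        res = f4(panel, "A", "B", "C", "C")
        assert res.estimate == 0.0

    def test_f2_self_bias_corrected(self):
        panel = random_freq_panel(["A"], seed=2)
        res = f2(panel, "A", "A", bias_correction=True)
        assert res.estimate == 0.0

    def test_f2_bias_correction_removes_sampling_noise(self):
        # same underlying frequencies, two independent finite samples
        rng = np.random.default_rng(3)
        n = 30_000
        p = rng.uniform(0.1, 0.9, n)
        n_hap = 10
        freq = {
            "A": rng.binomial(n_hap, p) / n_hap,
            "B": rng.binomial(n_hap, p) / n_hap,
        }
        count = {k: np.full(n, n_hap) for k in freq}
        panel = FreqPanel(["A", "B"], freq, count, np.arange(n) // 500)
        corrected = f2(panel, "A", "B", bias_correction=True)
        raw = f2(panel, "A", "B", bias_correction=False)
        assert abs(corrected.estimate) < 3 * corrected.se
        assert raw.estimate > 5 * raw.se  # uncorrected keeps the sampling term

    def test_f4_additivity(self):
        panel = random_freq_panel(["A", "B", "C", "D", "E"], seed=4)
        lhs = f4(panel, "A", "B", "C", "D").estimate
        rhs = (
            f4(panel, "A", "B", "C", "E").estimate
            + f4(panel, "A", "B", "E", "D").estimate
        )
        assert abs(lhs - rhs) < 1e-12

    def test_d_and_f4_share_sign(self):
        for seed in range(5):
            panel = random_freq_panel(["A", "B", "C", "D"], seed=seed)
            fr = f4(panel, "A", "B", "C", "D").estimate
            dr = d_stat(panel, "A", "B", "C", "D").estimate
            assert np.sign(fr) == np.sign(dr)

    def test_outgroup_f3_matches_shared_drift(self):
        # (A,B) split 0.002, root at 0.012: shared A-B drift segment 0.01.
        # Polarization makes the outgroup the ancestral reference (freq 0),
        # so f3(outgroup; A, B) = E[a*b] = the shared segment exactly.
        theta = 1e-4
        cfg = simdata.DemographyConfig(
            populations=["O", "A", "B"],
            pop_sizes={p: theta for p in ["O", "A", "B", "AB", "R"]},
            splits=[(0.002, ["A", "B"], "AB"), (0.012, ["AB", "O"], "R")],
            samples={"O": 1, "A": 2, "B": 2},
        )
        panel = simdata.simulate_genotypes(cfg, 150_000, seed=5)
        fp = FreqPanel.from_genotype_panel(panel)
        n = panel.n_sites
        fp.pops.append("ANCREF")
        fp.freq["ANCREF"] = np.zeros(n)
        fp.count["ANCREF"] = np.full(n, 1000)
        res = f3(fp, "ANCREF", "A", "B", bias_correction=False)
        assert res.se < 8e-4
        assert abs(res.estimate - 0.01) < 3 * res.se

    def test_missing_population_raises(self):
        panel = random_freq_panel(["A", "B"], seed=6)
        with pytest.raises(KeyError):
            f2(panel, "A", "Z")


class TestJackknife:
    def test_se_matches_binomial_on_iid_sites(self):
        rng = np.random.default_rng(7)
        n = 50_000
        x = rng.binomial(1, 0.3, n).astype(float)
        block = np.arange(n) // 1000
        est, se, g = weighted_block_jackknife(x, np.ones(n), block)
        analytic = np.sqrt(0.3 * 0.7 / n)
        assert g == 50
        assert abs(est - 0.3) < 4 * analytic
        assert abs(se - analytic) / analytic < 0.2

    def test_too_few_blocks_flagged(self):
        panel = random_freq_panel(["A", "B"], n_sites=100, n_blocks=1, seed=8)
        res = f2(panel, "A", "B")
        assert "no-se" in res.flags
        assert np.isnan(res.se)

    def test_blocks_from_genetic_map(self):
        pos = np.array([0, 100, 200, 300, 400])
        blocks = blocks_from_genetic_map(pos, np.array([0, 400]), np.array([0.0, 20.0]),
                                         window_cm=5.0)
        assert list(blocks) == [0, 1, 2, 3, 4]


class TestF4Ratio:
    def test_unadmixed_target_ratio_one(self):
        theta = 0.002
        cfg = simdata.DemographyConfig(
            populations=["OUT", "A", "B", "X", "C"],
            pop_sizes={p: theta for p in
                       ["OUT", "A", "B", "X", "C", "N1", "N2", "N3", "ROOT"]},
            splits=[
                (0.010, ["B", "X"], "N1"),
                (0.016, ["A", "N1"], "N2"),
                (0.024, ["N2", "C"], "N3"),
                (0.060, ["N3", "OUT"], "ROOT"),
            ],
            samples={"OUT": 2, "A": 4, "B": 4, "X": 4, "C": 4},
        )
        panel = simdata.simulate_genotypes(cfg, 60_000, seed=9)
        fp = FreqPanel.from_genotype_panel(panel)
        res = f4_ratio(fp, ("A", "OUT", "X", "C"), ("A", "OUT", "B", "C"))
        assert abs(res.estimate - 1.0) < 3 * res.se

    def test_invariant_under_block_preserving_permutation(self):
        panel = random_freq_panel(["A", "B", "C", "D"], n_sites=2000, n_blocks=10, seed=10)
        res1 = f4_ratio(panel, ("A", "B", "C", "D"), ("A", "B", "D", "C"))
        rng = np.random.default_rng(11)
        # permute sites within blocks only
        order = np.arange(2000)
        for b in range(10):
            idx = np.flatnonzero(panel.block_id == b)
            order[idx] = rng.permutation(idx)
        panel2 = FreqPanel(
            pops=panel.pops,
            freq={k: v[order] for k, v in panel.freq.items()},
            count={k: v[order] for k, v in panel.count.items()},
            block_id=panel.block_id[order],
        )
        res2 = f4_ratio(panel2, ("A", "B", "C", "D"), ("A", "B", "D", "C"))
        assert abs(res1.estimate - res2.estimate) < 1e-12
        assert abs(res1.se - res2.se) < 1e-12


def simple_tree() -> AdmixtureGraph:
    edges = [
        GraphEdge("R", "AB", 0.02),
        GraphEdge("AB", "A", 0.01),
        GraphEdge("AB", "B", 0.015),
        GraphEdge("R", "C", 0.03),
    ]
    return AdmixtureGraph(edges, {"A": "A", "B": "B", "C": "C"})


def admixed_graph(alpha=0.5) -> AdmixtureGraph:
    edges = [
        GraphEdge("R", "P1", 0.02),
        GraphEdge("R", "P2", 0.03),
        GraphEdge("P1", "A", 0.01),
        GraphEdge("P2", "B", 0.012),
        GraphEdge("P1", "X", 0.004, proportion=alpha),
        GraphEdge("P2", "X", 0.004, proportion=1 - alpha),
        GraphEdge("X", "Xleaf", 0.002),
        GraphEdge("R", "O", 0.05),
    ]
    return AdmixtureGraph(edges, {"A": "A", "B": "B", "X": "Xleaf", "O": "O"})


class TestExpectedF:
    def test_tree_f2_is_path_sum(self):
        g = simple_tree()
        assert expected_f(g, "f2", ["A", "B"]) == pytest.approx(0.025, abs=1e-15)
        assert expected_f(g, "f2", ["A", "C"]) == pytest.approx(0.06, abs=1e-15)

    def test_disjoint_cherries_f4_zero(self):
        edges = [
            GraphEdge("R", "AB", 0.02),
            GraphEdge("AB", "A", 0.01),
            GraphEdge("AB", "B", 0.01),
            GraphEdge("R", "CD", 0.02),
            GraphEdge("CD", "C", 0.01),
            GraphEdge("CD", "D", 0.01),
        ]
        g = AdmixtureGraph(edges, {p: p for p in "ABCD"})
        assert expected_f(g, "f4", ["A", "B", "C", "D"]) == 0.0

    def test_admixed_f4_matches_routing_enumeration(self):
        for alpha in (0.5, 0.3, 0.8):
            g = admixed_graph(alpha)
            for quad in [("A", "B", "X", "O"), ("A", "X", "B", "O"), ("A", "O", "X", "B")]:
                assert expected_f(g, "f4", quad) == pytest.approx(
                    oracle_f4(g, *quad), abs=1e-12
                )

    def test_half_admixed_is_average_of_parent_graphs(self):
        g = admixed_graph(0.5)
        g1 = admixed_graph(1.0 - 1e-12)
        g0 = admixed_graph(1e-12)
        quad = ("A", "B", "X", "O")
        mix = 0.5 * expected_f(g1, "f4", quad) + 0.5 * expected_f(g0, "f4", quad)
        assert expected_f(g, "f4", quad) == pytest.approx(mix, abs=1e-9)

    def test_unmapped_population_errors(self):
        with pytest.raises(KeyError):
            expected_f(simple_tree(), "f2", ["A", "Z"])


def all_stats(graph, pops):
    out = []
    for a, b in itertools.combinations(pops, 2):
        out.append(("f2", (a, b)))
    for c, a, b in itertools.permutations(pops, 3):
        if a < b:
            out.append(("f3", (c, a, b)))
    for quad in itertools.permutations(pops, 4):
        if quad[0] < quad[1] and quad[2] < quad[3] and quad[0] < quad[2]:
            out.append(("f4", quad))
    return out


class TestFitGraph:
    def test_self_consistency_exact(self):
        truth = admixed_graph(0.3)
        pops = ["A", "B", "X", "O"]
        obs = [
            (s, p, expected_f(truth, s, p), 1e-4) for s, p in all_stats(truth, pops)
        ]
        start = admixed_graph(0.55)
        fit = fit_graph(start, obs)
        assert fit.outliers == []
        for s, p, val, _ in obs:
            assert expected_f(fit.graph, s, p) == pytest.approx(val, abs=1e-6)

    def test_missing_admixture_edge_flagged(self):
        truth = admixed_graph(0.4)
        pops = ["A", "B", "X", "O"]
        obs = [(s, p, expected_f(truth, s, p), 1e-4) for s, p in all_stats(truth, pops)]
        # fit a pure tree (X forced to descend from P1 only)
        edges = [
            GraphEdge("R", "P1", 0.02),
            GraphEdge("R", "P2", 0.03),
            GraphEdge("P1", "A", 0.01),
            GraphEdge("P2", "B", 0.012),
            GraphEdge("P1", "Xleaf", 0.006),
            GraphEdge("R", "O", 0.05),
        ]
        tree = AdmixtureGraph(edges, {"A": "A", "B": "B", "X": "Xleaf", "O": "O"})
        fit = fit_graph(tree, obs)
        assert len(fit.outliers) >= 1
        assert max(abs(z) for _, _, z in fit.outliers) >= 3.0

    def test_single_edge_graph_matches_observation(self):
        g = AdmixtureGraph([GraphEdge("R", "A", 0.5)], {"A": "A", "R": "R"})
        fit = fit_graph(g, [("f2", ("A", "R"), 0.125, 1e-3)])
        assert fit.graph.lengths()[0] == pytest.approx(0.125, abs=1e-8)

    def test_non_identifiable_flagged(self):
        # two edges in series: only their sum is constrained
        edges = [GraphEdge("R", "M", 0.1), GraphEdge("M", "A", 0.1)]
        g = AdmixtureGraph(edges, {"A": "A", "R": "R"})
        fit = fit_graph(g, [("f2", ("A", "R"), 0.2, 1e-3)])
        assert not fit.identifiable
        assert fit.null_space is not None and len(fit.null_space) >= 1
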