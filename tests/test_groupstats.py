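"""Group comparison machinery: densities, KS tests, fits, communities."""

import numpy as np
import pytest

from wrcf.homology import Generator
from wrcf.groupstats import (GroupSummary, pooled_density, ks_two_sample,
                             frequency_persistence_fit, slope_difference_test,
                             modularity_communities, cross_group_edge_report,
                             DegenerateFitError, FitResult)
from wrcf.scaffolds import persistence_scaffold, frequency_scaffold, Scaffold
from wrcf.graphio import WeightedNetwork

from test_scaffolds import make_generator


def brute_force_ks(a, b):
    """D by exhaustive ECDF evaluation at every sample point."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pts = np.concatenate([a, b])
    ecdf = lambda s, x: np.mean(s <= x)
    return max(abs(ecdf(a, x) - ecdf(b, x)) for x in pts)


class TestKS:
    def test_identical_samples_d_zero(self, rng):
        x = rng.standard_normal(40)
        res = ks_two_sample(x, x.copy())
        assert res.statistic == 0.0 and res.pvalue == pytest.approx(1.0)

    def test_disjoint_supports_d_one(self):
        res = ks_two_sample([1.0, 2.0], [5.0, 6.0, 7.0])
        assert res.statistic == 1.0
        assert (res.n1, res.n2) == (2, 3)

    def test_matches_brute_force_sweep(self, rng):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        assert ks_two_sample(a, b).statistic == pytest.approx(brute_force_ks(a, b))
        for _ in range(20):
            a = rng.standard_normal(int(rng.integers(2, 30)))
            b = rng.standard_normal(int(rng.integers(2, 30))) + rng.uniform(-1, 1)
            assert ks_two_sample(a, b).statistic == pytest.approx(
                brute_force_ks(a, b), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.exponential(1.0, 50)
        b = rng.exponential(2.0, 60)
        d1 = ks_two_sample(a, b).statistic
        d2 = ks_two_sample(np.log(a), np.log(b)).statistic
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


def _summary(label, pis, units="weight"):
    gens = [[make_generator([(0, 1), (1, 2), (2, 3), (0, 3)],
                            birth=1, death=2, birth_w=0.9, death_w=0.9 - p)
             for p in pis]]
    return GroupSummary(group_label=label, subject_generators=gens, units=units)


class TestDensity:
    def test_single_point_density_one_bin(self):
        s = _summary("g", [0.3])
        table = pooled_density(s, "persistence", bins=5)
        assert table["count"].sum() == 1
        mass = (table["density"] * (table["bin_high"] - table["bin_low"])).sum()
        assert mass == pytest.approx(1.0)

    def test_uniform_points_flat_within_binomial_error(self, rng):
        pis = rng.uniform(0.1, 0.5, 4000)
        table = pooled_density(_summary("g", pis), "persistence", bins=8)
        p_bin = 1 / 8
        expect = 4000 * p_bin
        tol = 4 * np.sqrt(4000 * p_bin * (1 - p_bin))
        inner = table["count"].to_numpy()[1:-1]      # edge bins clip the range
        assert np.all(np.abs(inner - expect) < tol)

    def test_log_density_missing_not_minus_inf(self):
        table = pooled_density(_summary("g", [0.1, 0.1, 0.4]), "persistence",
                               bins=10)
        empty = table[table["count"] == 0]
        assert empty["log10_density"].isna().all()
        assert np.isfinite(table[table["count"] > 0]["log10_density"]).all()

    def test_birth_death_joint_normalizes(self, rng):
        s = _summary("g", rng.uniform(0.1, 0.5, 100))
        table = pooled_density(s, "birth_death", bins=5)
        mass = (table["density"] *
                (table["birth_high"] - table["birth_low"]) *
                (table["death_high"] - table["death_low"])).sum()
        assert mass == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        s = GroupSummary("g", [[]])
        with pytest.raises(ValueError):
            pooled_density(s, "persistence")


class TestFit:
    def _pair(self, slope, noise, rng, n=60):
        net_f = WeightedNetwork.from_nodes([f"n{i}" for i in range(n + 1)])
        net_p = WeightedNetwork.from_nodes([f"n{i}" for i in range(n + 1)])
        freqs = rng.integers(1, 30, n).astype(float)
        for i, f in enumerate(freqs):
            net_f.add_edge(f"n{i}", f"n{i + 1}", f, create_nodes=False)
            net_p.add_edge(f"n{i}", f"n{i + 1}",
                           slope * f + noise * rng.standard_normal(),
                           create_nodes=False)
        return (Scaffold(net_f, "frequency", "rank"),
                Scaffold(net_p, "persistence", "rank"))

    def test_exact_linearity(self, rng):
        freq, pers = self._pair(0.23, 0.0, rng)
        fit, table = frequency_persistence_fit(freq, pers)
        assert fit.slope == pytest.approx(0.23)
        assert fit.r_squared == pytest.approx(1.0)
        assert len(table) == fit.n

    def test_constant_frequency_degenerate(self):
        g = make_generator([(0, 1), (1, 2), (2, 3), (0, 3)], birth=1, death=4)
        freq = frequency_scaffold([g])
        pers = persistence_scaffold([g])
        fit, _ = frequency_persistence_fit(freq, pers)
        assert fit.degenerate

    def test_noisy_recovery_within_stderr(self, rng):
        freq, pers = self._pair(0.3, 0.5, rng, n=300)
        fit, _ = frequency_persistence_fit(freq, pers)
        assert abs(fit.slope - 0.3) < 3 * fit.stderr

    def test_edge_set_mismatch_rejected(self, rng):
        g1 = make_generator([(0, 1), (1, 2), (2, 3), (0, 3)])
        g2 = make_generator([(4, 5), (5, 6), (6, 7), (4, 7)])
        with pytest.raises(ValueError, match="edge set"):
            frequency_persistence_fit(frequency_scaffold([g1]),
                                      persistence_scaffold([g2]))


class TestSlopeTest:
    def test_identical_fits_statistic_zero(self, rng):
        freqs = np.arange(1.0, 50.0)
        from scipy import stats
        res = stats.linregress(freqs, 0.23 * freqs + 0.01 * np.sin(freqs))
        fit = FitResult(res.slope, res.intercept, res.rvalue ** 2, res.stderr,
                        len(freqs))
        t, p = slope_difference_test(fit, fit)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_distinct_slopes_large_n_significant(self, rng):
        from scipy import stats
        x = rng.uniform(1, 30, 13_000)
        ya = 0.23 * x + 0.05 * rng.standard_normal(x.size)
        yb = 0.30 * x + 0.05 * rng.standard_normal(x.size)
        ra = stats.linregress(x, ya)
        rb = stats.linregress(x, yb)
        fa = FitResult(ra.slope, ra.intercept, ra.rvalue ** 2, ra.stderr, x.size)
        fb = FitResult(rb.slope, rb.intercept, rb.rvalue ** 2, rb.stderr, x.size)
        t, p = slope_difference_test(fa, fb)
        assert p < 1e-10

    def test_swapped_arguments_negate_statistic(self, rng):
        from scipy import stats
        x = np.arange(1.0, 40.0)
        ra = stats.linregress(x, 0.2 * x + 0.1 * np.cos(x))
        rb = stats.linregress(x, 0.3 * x + 0.1 * np.sin(x))
        fa = FitResult(ra.slope, ra.intercept, ra.rvalue ** 2, ra.stderr, x.size)
        fb = FitResult(rb.slope, rb.intercept, rb.rvalue ** 2, rb.stderr, x.size)
        t1, p1 = slope_difference_test(fa, fb)
        t2, p2 = slope_difference_test(fb, fa)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_degenerate_fit_rejected(self):
        good = FitResult(0.2, 0.0, 1.0, 0.01, 10)
        bad = FitResult(np.nan, np.nan, np.nan, np.nan, 10, degenerate=True)
        with pytest.raises(DegenerateFitError):
            slope_difference_test(good, bad)


def _block_scaffold(blocks, w_in=10.0, w_out=0.5, rng=None):
    nodes = [f"b{b}n{i}" for b, size in enumerate(blocks) for i in range(size)]
    net = WeightedNetwork.from_nodes(nodes)
    by_block = {}
    for b, size in enumerate(blocks):
        by_block[b] = [f"b{b}n{i}" for i in range(size)]
        members = by_block[b]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                net.add_edge(members[i], members[j], w_in, create_nodes=False)
    for b in range(len(blocks) - 1):
        net.add_edge(by_block[b][0], by_block[b + 1][0], w_out, create_nodes=False)
    return Scaffold(net, "persistence", "rank"), by_block


class TestCommunities:
    def test_two_cliques_weak_bridge(self):
        s, blocks = _block_scaffold([5, 5])
        part, q = modularity_communities(s, seed=0)
        assert len(set(part.values())) == 2
        assert len({part[n] for n in blocks[0]}) == 1
        assert q > 0.3

    def test_single_clique_one_community(self):
        s, _ = _block_scaffold([6])
        part, _ = modularity_communities(s, seed=0)
        assert set(part.values()) == {0}

    def test_planted_four_blocks_recovered_across_seeds(self):
        s, blocks = _block_scaffold([6, 6, 6, 6])
        truth = {n: b for b, ns in blocks.items() for n in ns}
        from sklearn.metrics import adjusted_rand_score
        scores = []
        for seed in range(20):
            part, _ = modularity_communities(s, seed=seed)
            names = sorted(part)
            scores.append(adjusted_rand_score(
                [truth[n] for n in names], [part[n] for n in names]))
        assert np.mean(scores) >= 0.95

    def test_empty_scaffold_rejected(self):
        net = WeightedNetwork.from_nodes(["a"])
        with pytest.raises(ValueError):
            modularity_communities(Scaffold(net, "persistence", "rank"))


class TestCrossGroupEdges:
    def test_identical_scaffolds(self):
        s, blocks = _block_scaffold([4, 4])
        part, _ = modularity_communities(s, seed=0)
        rep = cross_group_edge_report(s, s, part, w_min=1.0)
        assert rep.n_shared == rep.n_edges_ref == rep.n_edges_other == 12
        assert rep.n_between_communities == 0   # only the weak bridge crosses

    def test_disjoint_edge_sets(self):
        g1 = make_generator([(0, 1), (1, 2), (2, 3), (0, 3)])
        g2 = make_generator([(4, 5), (5, 6), (6, 7), (4, 7)])
        nodes = [str(i) for i in range(8)]
        s1 = persistence_scaffold([g1], nodes)
        s2 = persistence_scaffold([g2], nodes)
        rep = cross_group_edge_report(s1, s2, {n: 0 for n in nodes}, 0.0)
        assert rep.n_shared == 0

    def test_planted_counts_recovered_exactly(self, rng):
        # fixture mirroring the published truncated-scaffold counts:
        # reference keeps 165 edges, other keeps 374, 29 shared, 217 of
        # the other's edges run between reference communities
        n = 60
        nodes = [f"r{i}" for i in range(n)]
        # two communities of 30; within-pairs vs between-pairs
        part = {f"r{i}": (0 if i < 30 else 1) for i in range(n)}
        within = [(i, j) for i in range(n) for j in range(i + 1, n)
                  if (i < 30) == (j < 30)]
        between = [(i, j) for i in range(n) for j in range(i + 1, n)
                   if (i < 30) != (j < 30)]
        rng.shuffle(within)
        rng.shuffle(between)
        shared = [within.pop() for _ in range(29)]
        ref_only = [within.pop() for _ in range(165 - 29)]
        other_between = [between.pop() for _ in range(217)]
        other_within = [within.pop() for _ in range(374 - 29 - 217)]

        def scaffold_from(pairs, w=100.0):
            net = WeightedNetwork.from_nodes(nodes)
            for i, j in pairs:
                net.add_edge(f"r{i}", f"r{j}", w, create_nodes=False)
            return Scaffold(net, "persistence", "rank")

        s_ref = scaffold_from(shared + ref_only)
        s_other = scaffold_from(shared + other_between + other_within)
        rep = cross_group_edge_report(s_ref, s_other, part, w_min=80.0)
        assert rep.n_edges_ref == 165
        assert rep.n_edges_other == 374
        assert rep.n_shared == 29
        assert rep.n_between_communities == 217

    def test_node_universe_mismatch(self):
        s1 = persistence_scaffold([make_generator([(0, 1), (1, 2), (2, 3), (0, 3)])],
                                  ["a", "b", "c", "d"])
        s2 = persistence_scaffold([make_generator([(0, 1), (1, 2), (2, 3), (0, 3)])],
                                  ["w", "x", "y", "z"])
        with pytest.raises(ValueError, match="universe"):
            cross_group_edge_report(s1, s2, {}, 0.0)
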