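"""Entropy statistic, bootstrap null, Gamma fits, p/q-values, hotspot calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from famhotspot import (
    build_consensus,
    build_null,
    call_hotspots,
    correct_qvalues,
    fit_gamma,
    global_pvalue,
    pool_mutations,
    position_pvalues,
    sampling_weights,
    shannon_entropy,
    simulate_null,
)
from famhotspot.alignment import MultipleAlignment, MutationProfile
from famhotspot.hotspot import NoMutationsError
from tests.conftest import make_mutation


def brute_force_bh(pvals):
    """Independent textbook BH: p * m / rank with backward cumulative min."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((1, 1, 1, 1), math.log(4)),
            ((5, 0, 0, 0), 0.0),
            ((3, 1), -(0.75 * math.log(0.75) + 0.25 * math.log(0.25))),
        ],
    )
    def test_known_values(self, counts, expected):
        assert shannon_entropy(np.array(counts)) == pytest.approx(expected, abs=1e-12)

    def test_empty_profile_raises(self):
        with pytest.raises(NoMutationsError):
            shannon_entropy(np.zeros(5))

    @settings(derandomize=True, max_examples=100)
    @given(counts=st.lists(st.integers(0, 50), min_size=1, max_size=80).filter(lambda c: sum(c) > 0))
    def test_entropy_bounds(self, counts):
        h = shannon_entropy(np.array(counts, float))
        support = sum(1 for c in counts if c > 0)
        assert -1e-12 <= h <= math.log(support) + 1e-12 <= math.log(len(counts)) + 1e-12


class TestSamplingWeights:
    def test_uniform_coverage(self):
        assert np.allclose(sampling_weights(np.full(10, 7)), 0.1)

    def test_zero_coverage_columns_get_zero_weight(self):
        assert np.allclose(sampling_weights(np.array([2, 0, 2])), [0.5, 0, 0.5])

    def test_normalization(self):
        rng = np.random.default_rng(0)
        cov = rng.integers(0, 30, size=200)
        cov[0] = 1
        assert abs(sampling_weights(cov).sum() - 1.0) < 1e-12

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            sampling_weights(np.zeros(4))


class TestSimulateNull:
    def test_degenerate_weight_concentrates_everything(self):
        boot = simulate_null(np.array([0.0, 1.0, 0.0]), N=9, n_boot=50, seed=1)
        assert np.all(boot[:, 1] == 9)
        assert np.all(boot[:, [0, 2]] == 0)

    def test_every_replicate_sums_to_N(self):
        rng = np.random.default_rng(5)
        w = rng.dirichlet(np.ones(40))
        boot = simulate_null(w, N=33, n_boot=400, seed=2)
        assert np.all(boot.sum(axis=1) == 33)

    def test_reproducible_under_seed(self):
        w = np.full(20, 0.05)
        a = simulate_null(w, 10, n_boot=30, seed=9)
        b = simulate_null(w, 10, n_boot=30, seed=9)
        assert np.array_equal(a, b)

    def test_moments_match_multinomial_theory(self):
        rng = np.random.default_rng(7)
        w = rng.dirichlet(np.ones(30))
        N, n_boot = 40, 10_000
        boot = simulate_null(w, N, n_boot=n_boot, seed=3)
        mean = boot.mean(axis=0)
        se = np.sqrt(N * w * (1 - w) / n_boot)
        assert np.all(np.abs(mean - N * w) <= 3 * se + 1e-9)


class TestFitGamma:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        x = rng.gamma(2.0, 3.0, size=10_000)
        fit = fit_gamma(x)
        assert fit.shape == pytest.approx(2.0, abs=0.1)
        assert fit.scale == pytest.approx(3.0, abs=0.15)

    def test_agrees_with_scipy_mle(self):
        rng = np.random.default_rng(13)
        x = rng.gamma(1.7, 0.8, size=5000)
        fit = fit_gamma(x)
        sh, _, sc = stats.gamma.fit(x, floc=0)
        assert fit.shape == pytest.approx(sh, rel=1e-3)
        assert fit.scale == pytest.approx(sc, rel=1e-3)

    def test_constant_samples_degenerate(self):
        assert fit_gamma(np.full(100, 2.5)) is None

    def test_zeros_dropped_before_fit(self):
        rng = np.random.default_rng(17)
        x = np.concatenate([rng.gamma(2.0, 1.0, size=2000), np.zeros(50)])
        fit = fit_gamma(x)
        assert fit is not None and fit.shape == pytest.approx(2.0, abs=0.2)

    def test_too_few_values_degenerate(self):
        assert fit_gamma([1.0]) is None
        assert fit_gamma([0.0, 0.0, 1.0]) is None


class TestGlobalPvalue:
    def test_maximal_clustering_is_extreme(self):
        null = build_null(np.full(50, 0.02), N=40, n_boot=1000, seed=21)
        assert global_pvalue(0.0, null) < 1e-6

    def test_null_median_gives_half(self):
        null = build_null(np.full(50, 0.02), N=40, n_boot=2000, seed=22)
        med = float(np.median(null.boot_entropies))
        assert global_pvalue(med, null) == pytest.approx(0.5, abs=0.05)

    def test_degenerate_null_uses_empirical_tail(self):
        # single-column weights: every replicate entropy is 0
        null = build_null(np.array([1.0]), N=5, n_boot=200, seed=23)
        assert null.entropy_null is None
        assert global_pvalue(0.0, null) == pytest.approx(1.0)


class TestPositionPvalues:
    def test_zero_count_gives_one(self):
        null = build_null(np.full(20, 0.05), N=30, n_boot=500, seed=31)
        counts = np.zeros(20, int)
        counts[3] = 30
        p = position_pvalues(counts, null)
        assert p[0] == 1.0
        assert p[3] < 1e-6

    def test_zero_weight_column_gets_one_with_warning(self):
        w = np.array([0.5, 0.0, 0.5])
        null = build_null(w, N=10, n_boot=300, seed=32)
        counts = np.array([5, 3, 2])
        with pytest.warns(UserWarning, match="zero-weight"):
            p = position_pvalues(counts, null)
        assert p[1] == 1.0

    def test_planted_hotspot_small_everything_else_uniformish(self):
        K, N = 100, 50
        w = np.full(K, 1.0 / K)
        rng = np.random.default_rng(33)
        counts = rng.multinomial(N - 15, w)
        counts[40] += 15
        null = build_null(w, N, n_boot=1000, seed=34)
        p = position_pvalues(counts, null)
        assert p[40] < 1e-4
        others = np.delete(p, 40)
        assert others.min() > 1e-4

    def test_monotone_in_observed_count(self):
        K = 30
        null = build_null(np.full(K, 1 / K), N=25, n_boot=800, seed=35)
        base = np.zeros(K, int)
        prev = 1.1
        for n_i in (1, 3, 6, 12, 25):
            c = base.copy()
            c[7] = n_i
            p = position_pvalues(c, null)[7]
            assert p <= prev + 1e-15
            prev = p


class TestCorrectQvalues:
    def test_worked_bh_example(self):
        q = correct_qvalues(np.array([0.01, 0.02, 0.03, 0.04]), np.ones(4))
        assert np.allclose(q, 0.04)

    def test_single_gated_column(self):
        q = correct_qvalues(np.array([0.03, 0.5]), np.array([0.9, 0.05]))
        assert q[0] == pytest.approx(0.03)
        assert np.isnan(q[1])

    def test_identical_pvalues_fixed_point(self):
        q = correct_qvalues(np.full(6, 0.2), np.ones(6))
        assert np.allclose(q, 0.2)

    def test_gate_is_strict(self):
        q = correct_qvalues(np.array([0.01, 0.01]), np.array([0.1, 0.100001]))
        assert np.isnan(q[0]) and not np.isnan(q[1])

    def test_no_gated_columns_warns(self):
        with pytest.warns(UserWarning, match="Trident gate"):
            q = correct_qvalues(np.array([0.01]), np.array([0.0]))
        assert np.isnan(q).all()

    @settings(derandomize=True, max_examples=150)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60), st.randoms(use_true_random=False))
    def test_matches_brute_force_bh_with_ties(self, pv, rnd):
        pv = np.array(pv)
        if rnd.random() < 0.3 and len(pv) > 1:  # inject ties
            pv[: len(pv) // 2] = pv[0]
        q = correct_qvalues(pv, np.ones(len(pv)))
        assert np.allclose(q, brute_force_bh(pv), atol=1e-12)


class TestCallHotspots:
    def _setup(self, counts_at=4, n=12):
        aln = MultipleAlignment(["a", "b"], ["MKTAYIAKQR", "MKTAYIAKQR"])
        consensus = build_consensus(aln)
        muts = [make_mutation("a", ref="Y", pos=5, alt="C", sample=f"S{i}") for i in range(n)]
        profile, _ = pool_mutations(aln, muts)
        null = build_null(sampling_weights(consensus), max(profile.N, 1), n_boot=500, seed=41)
        return profile, consensus, null, aln

    def test_contributors_reverse_mapped(self):
        profile, consensus, null, aln = self._setup()
        res = call_hotspots(profile, consensus, null, aln)
        row = res.table[res.table["column"] == 5].iloc[0]
        assert row["n_mut"] == 12
        assert all(g == "a" and p == 5 for g, p, _s, _t in row["contributors"])
        assert res.global_p is not None

    def test_empty_profile_is_nothing_to_test(self):
        aln = MultipleAlignment(["a"], ["MKTAY"])
        consensus = build_consensus(aln)
        profile = MutationProfile(np.zeros(5, int), [[] for _ in range(5)])
        null = build_null(sampling_weights(consensus), 1, n_boot=100, seed=42)
        res = call_hotspots(profile, consensus, null, aln)
        assert res.nothing_to_test and res.global_p is None
        assert len(res.significant()) == 0 or res.significant().equals(res.table)

    def test_q_geq_p_where_defined(self):
        profile, consensus, null, aln = self._setup()
        res = call_hotspots(profile, consensus, null, aln)
        t = res.table.dropna(subset=["q"])
        assert np.all(t["q"].to_numpy() >= t["p"].to_numpy() - 1e-15)

    def test_deterministic_under_seed(self):
        a = self._setup()
        b = self._setup()
        ra = call_hotspots(*a)
        rb = call_hotspots(*b)
        assert ra.table.drop(columns="contributors").equals(rb.table.drop(columns="contributors"))
        assert ra.global_p == rb.global_p
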