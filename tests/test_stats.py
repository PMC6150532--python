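"""Statistics: Mann-Whitney against brute-force and scipy oracles, the
Monte-Carlo sex-difference index, and the supporting summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from usvdyad.stats import (
    ValidationError,
    ks_nongaussian,
    mann_whitney,
    median_iqr,
    monte_carlo_index,
    pearson,
    per_animal_medians,
    session_counts,
    sex_index,
    vocalizer_split,
)
from usvdyad.synth import SexEffectSpec, simulate_feature_table


class TestMannWhitney:
    def test_disjoint_triples_exact_p(self):
        # brute force: U = 0 occurs for 1 of C(6,3) = 20 assignments,
        # doubled to 0.1
        r = mann_whitney([1, 2, 3], [4, 5, 6])
        assert r.u == 0
        assert r.p == pytest.approx(0.1)
        assert r.method == "exact"

    def test_identical_multisets_give_p_one(self):
        r = mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.z == 0
        assert r.p == 1.0

    def test_large_shifted_samples_are_detected(self, rng):
        x = rng.normal(0, 1, 5000)
        y = rng.normal(1, 1, 5000)
        assert mann_whitney(x, y).p < 1e-3

    def test_exact_branch_matches_scipy(self, rng):
        for n in range(2, 9):
            x = rng.normal(0, 1, n)
            y = rng.normal(0.5, 1, n)
            mine = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_asymptotic_branch_matches_scipy(self, rng):
        for _ in range(5):
            x = rng.normal(0, 1, 40)
            y = rng.normal(0.3, 1, 55)
            mine = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert mine.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_branch_handles_ties(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [2.0, 3.0, 3.0, 4.0]
        r = mann_whitney(x, y)
        assert r.method == "exact"
        assert 0.0 < r.p <= 1.0

    def test_exact_vs_asymptotic_where_the_approximation_holds(self):
        """Full U sweep: the normal approximation tracks enumeration to
        0.02 for n >= 5 per group; below that the exact distribution is too
        coarse (worst case 0.09 at n = 2) though alpha = 0.05 decisions
        still agree away from the knife edge."""
        from itertools import combinations

        for n in range(5, 9):
            ranks = np.arange(1, 2 * n + 1)
            offset = n * (n + 1) / 2
            us = np.array([sum(c) - offset for c in combinations(ranks, n)])
            for u in range(n * n + 1):
                exact = min(1.0, 2 * min((us <= u).sum(), (us >= u).sum()) / len(us))
                mean, var = n * n / 2, n * n * (2 * n + 1) / 12
                cc = 0.5 if u != mean else 0.0
                z = (u - mean - np.sign(u - mean) * cc) / np.sqrt(var)
                approx = min(1.0, 2 * sps.norm.sf(abs(z)))
                assert abs(exact - approx) <= 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])


class TestMedianIQR:
    def test_odd_sample(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_singleton_collapses(self):
        assert median_iqr([7.9]) == (7.9, 7.9, 7.9)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            median_iqr([])


class TestSexIndex:
    def test_equal_medians_give_zero(self):
        assert sex_index(5.0, 5.0) == 0.0

    def test_pooled_median_worked_example(self):
        # (7.9 - 6.1) / (7.9 + 6.1)
        assert sex_index(7.9, 6.1) == pytest.approx(0.1286, abs=5e-5)

    @settings(deadline=None)
    @given(
        m=st.floats(0.001, 1e6, allow_nan=False),
        f=st.floats(0.001, 1e6, allow_nan=False),
    )
    def test_antisymmetric_and_bounded(self, m, f):
        i = sex_index(m, f)
        assert -1.0 <= i <= 1.0
        assert i == pytest.approx(-sex_index(f, m), rel=1e-12)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            sex_index(0.0, 0.0)


@pytest.fixture(scope="module")
def balanced_table():
    return simulate_feature_table(
        n_sessions=1, counts_per_sex={"male": 3000, "female": 3000}, seed=31
    )


class TestMonteCarloIndex:

    def test_equal_sexes_straddle_zero(self):
        eff = SexEffectSpec()
        for feat in ("bandwidth_hz", "duration_ms", "amplitude_mv", "low_freq_hz"):
            getattr(eff, feat)["female"] = getattr(eff, feat)["male"]
        eff.slope_hz_per_s["female"] = eff.slope_hz_per_s["male"]
        table = simulate_feature_table(
            n_sessions=1, counts_per_sex={"male": 50_000, "female": 50_000}, effects=eff, seed=32
        )
        dist = monte_carlo_index(table, "bandwidth_hz", seed=33)
        # straddles zero (~50% positive), allowing for the finite table's
        # own median offset
        assert 400 <= dist.n_positive <= 600

    def test_strong_effect_gives_all_positive(self, balanced_table):
        # default male bandwidth median is ~30% above female
        dist = monte_carlo_index(balanced_table, "bandwidth_hz", seed=34)
        assert dist.n_positive == 1000

    def test_slope_shift_makes_values_nonnegative_and_preserves_order(self, balanced_table):
        dist = monte_carlo_index(balanced_table, "slope_hz_per_s", seed=35)
        slopes = balanced_table["slope_hz_per_s"].to_numpy()
        shifted = slopes + dist.slope_shift_constant
        assert shifted.min() == pytest.approx(0.0, abs=1e-9)
        # adding a constant cannot reorder medians
        assert np.argsort(slopes[:50]).tolist() == np.argsort(shifted[:50]).tolist()

    def test_same_seed_reproduces_indices(self, balanced_table):
        d1 = monte_carlo_index(balanced_table, "bandwidth_hz", seed=36)
        d2 = monte_carlo_index(balanced_table, "bandwidth_hz", seed=36)
        np.testing.assert_array_equal(d1.indices, d2.indices)

    def test_insufficient_signals_rejected(self):
        table = simulate_feature_table(
            n_sessions=1, counts_per_sex={"male": 600, "female": 100}, seed=37
        )
        with pytest.raises(ValidationError, match="female=100"):
            monte_carlo_index(table, "bandwidth_hz")

    def test_counts_partition_samples(self, balanced_table):
        dist = monte_carlo_index(balanced_table, "duration_ms", seed=38)
        assert dist.n_positive + dist.n_negative + dist.n_zero == 1000


class TestPearson:
    def test_perfect_linear_association(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x)
        assert r == pytest.approx(1.0)

    def test_independent_draws_near_zero(self, rng):
        x = rng.normal(0, 1, 10_000)
        y = rng.normal(0, 1, 10_000)
        r, _ = pearson(x, y)
        assert abs(r) < 0.03

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestVocalizerSplit:
    def test_above_threshold_is_high(self):
        assert vocalizer_split({"s": 3318})["s"] == "high"

    def test_exactly_2200_is_low(self):
        assert vocalizer_split({"s": 2200})["s"] == "low"

    def test_all_below_are_low(self):
        out = vocalizer_split({"a": 100, "b": 477})
        assert set(out.values()) == {"low"}


class TestKS:
    def test_normal_draws_are_accepted(self, rng):
        # p should not be systematically tiny on genuinely normal data
        ps = [ks_nongaussian(rng.normal(0, 1, 1000)) for _ in range(10)]
        assert np.median(ps) > 0.05

    def test_lognormal_draws_are_rejected(self, rng):
        assert ks_nongaussian(np.exp(rng.normal(0, 1, 1000))) < 0.01

    def test_constant_sample_is_degenerate(self):
        assert np.isnan(ks_nongaussian(np.ones(20)))


class TestPerAnimalAndCounts:
    def test_constant_feature_gives_constant_medians(self):
        table = simulate_feature_table(n_sessions=3, seed=41)
        table["bandwidth_hz"] = np.where(table["emitter"] == "male", 8000.0, 6000.0)
        table["high_freq_hz"] = table["low_freq_hz"] + table["bandwidth_hz"]
        med = per_animal_medians(table, "bandwidth_hz")
        assert (med.loc[med["emitter"] == "male", "median"] == 8000.0).all()
        assert len(med) == 6  # one male + one female point per session

    def test_thirteen_sessions_give_13_plus_13_points(self):
        table = simulate_feature_table(n_sessions=13, seed=42)
        med = per_animal_medians(table, "bandwidth_hz")
        assert (med["emitter"] == "male").sum() == 13
        assert (med["emitter"] == "female").sum() == 13

    def test_session_counts_match_groupby(self):
        table = simulate_feature_table(n_sessions=4, seed=43)
        counts = session_counts(table)
        direct = table.groupby(["date", "emitter"]).size()
        for _, row in counts.iterrows():
            assert row["count"] == direct.loc[(row["date"], row["emitter"])]

    def test_count_correlation_on_correlated_generator(self):
        table = simulate_feature_table(n_sessions=13, seed=44)
        counts = session_counts(table).pivot(index="date", columns="emitter", values="count")
        r, p = pearson(counts["male"], counts["female"])
        assert r > 0.5
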