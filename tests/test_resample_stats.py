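import itertools

import numpy as np
import pytest

import surfdelta as sd
from surfdelta.resample_stats import ad_2samp, format_p
from surfdelta.synth import sample_potential_pair


class TestTwoSampleP:
    def test_identical_samples_ks_p_one(self):
        x = np.array([0.3, -1.2, 0.8, 2.0, -0.4])
        assert sd.two_sample_p(x, x.copy(), "ks") == 1.0

    def test_symmetry_under_sample_exchange(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=40), rng.normal(0.5, size=40)
        for test in ("t", "ks", "ad"):
            assert sd.two_sample_p(x, y, test) == pytest.approx(
                sd.two_sample_p(y, x, test), rel=1e-12
            )

    def test_constant_equal_samples_p_one_all_tests(self):
        x = np.full(10, 3.3)
        for test in ("t", "ks", "ad"):
            assert sd.two_sample_p(x, x.copy(), test) == 1.0

    def test_constant_unequal_samples_t_zero(self):
        assert sd.two_sample_p(np.full(5, 1.0), np.full(5, 2.0), "t") == 0.0

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="at least 2"):
            sd.two_sample_p([1.0], [1.0, 2.0], "t")

    def test_ad_p_matches_exhaustive_permutation_oracle_small_n(self):
        """Asymptotic AD p vs the exhaustive label-permutation distribution.

        At n=5+5 all C(10,5) reassignments are enumerable; the asymptotic
        interpolation is only approximate at such sizes, so agreement is
        checked as bounded absolute deviation plus rank agreement.
        """
        rng = np.random.default_rng(7)
        asym, perm = [], []
        for _ in range(6):
            x = rng.normal(size=5)
            y = rng.normal(loc=1.0, size=5)
            stat, p, _ = ad_2samp(x, y)
            pooled = np.concatenate([x, y])
            stats = []
            for c in itertools.combinations(range(10), 5):
                mask = np.zeros(10, bool)
                mask[list(c)] = True
                stats.append(ad_2samp(pooled[mask], pooled[~mask])[0])
            p_perm = float(np.mean(np.array(stats) >= stat - 1e-12))
            asym.append(p)
            perm.append(p_perm)
        asym, perm = np.array(asym), np.array(perm)
        assert np.abs(asym - perm).max() < 0.15
        from scipy.stats import spearmanr
        # round so that numerically-coincident p-values tie identically
        assert spearmanr(np.round(asym, 6), np.round(perm, 6)).statistic > 0.99

    def test_ad_p_matches_permutation_oracle_moderate_n(self):
        """At n=30+30 the asymptotic p tracks 2e4 random permutations closely."""
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(0.5, size=30)
        stat, p, _ = ad_2samp(x, y)
        pooled = np.concatenate([x, y])
        count = 0
        B = 20000
        for _ in range(B):
            perm = rng.permutation(60)
            count += ad_2samp(pooled[perm[:30]], pooled[perm[30:]])[0] >= stat - 1e-12
        p_perm = count / B
        assert p == pytest.approx(p_perm, abs=0.01)

    def test_ad_extrapolation_monotone_and_flagged(self):
        # far separated samples push the statistic beyond the published
        # knots; p must keep decreasing, never snap back up or clip
        rng = np.random.default_rng(1)
        ps = []
        for shift in (5.0, 20.0, 100.0):
            x = rng.normal(size=100)
            y = rng.normal(loc=shift, size=100)
            _, p, extrap = ad_2samp(x, y)
            ps.append(p)
            assert extrap
        assert ps[0] < 1e-3
        assert ps[0] >= ps[1] >= ps[2]


class TestPaperStyleSignificanceCalls:
    """Threshold behaviour on representative printed p-values."""

    def test_table_row_t_not_significant_ad_significant(self):
        # a whole-surface comparison can be invisible to the t test while
        # decisive for AD
        assert not sd.is_significant(4.38e-1, 0.01)
        assert sd.is_significant(1.06e-7, 0.01)

    def test_threshold_is_strict(self):
        assert not sd.is_significant(0.01, 0.01)

    def test_clearly_nonsignificant_value(self):
        assert not sd.is_significant(8.7e-1, 0.01)

    def test_p_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            sd.is_significant(1.5)


class TestResampledComparison:
    def test_identical_samples_zero_shift(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        r = sd.resampled_comparison(x, x.copy(),
                                    sd.ResamplingConfig(n_iterations=20, seed=1))
        assert r.median_shift == 0.0
        assert not any(r.significant().values())

    def test_seed_determinism_bit_identical(self):
        x, y = sample_potential_pair(400, 0.3, seed=5)
        cfg = sd.ResamplingConfig(n_iterations=50, seed=42)
        a = sd.resampled_comparison(x, y, cfg)
        b = sd.resampled_comparison(x, y, cfg)
        assert np.array_equal(a.per_iteration_p, b.per_iteration_p)
        assert (a.p_t, a.p_ks, a.p_ad) == (b.p_t, b.p_ks, b.p_ad)

    def test_swap_symmetry_negates_shift(self):
        x, y = sample_potential_pair(400, 0.7, seed=6)
        cfg = sd.ResamplingConfig(n_iterations=30, seed=3)
        fwd = sd.resampled_comparison(x, y, cfg)
        rev = sd.resampled_comparison(y, x, cfg)
        assert rev.median_shift == pytest.approx(-fwd.median_shift)
        # aggregated p-values agree in distribution, not bit-for-bit (the
        # draws differ), so compare significance calls
        assert fwd.significant() == rev.significant()

    def test_median_p_aggregation_is_row_median(self):
        x, y = sample_potential_pair(300, 0.2, seed=7)
        r = sd.resampled_comparison(x, y, sd.ResamplingConfig(n_iterations=25, seed=0))
        med = np.median(r.per_iteration_p, axis=1)
        assert (r.p_t, r.p_ks, r.p_ad) == tuple(med)

    def test_fisher_aggregation_warns_about_dependence(self):
        x, y = sample_potential_pair(300, 0.2, seed=8)
        r = sd.resampled_comparison(
            x, y, sd.ResamplingConfig(n_iterations=25, seed=0, aggregation="fisher")
        )
        assert any("independent" in w for w in r.warnings)
        assert 0 <= r.p_ad <= 1

    def test_without_replacement_needs_large_enough_samples(self):
        x, y = sample_potential_pair(50, 0.0, seed=9)
        with pytest.raises(ValueError, match="with_replacement"):
            sd.resampled_comparison(
                x, y, sd.ResamplingConfig(n_points=100, with_replacement=False)
            )

    def test_median_shift_uses_full_samples(self):
        # a shift recovered to ~1% at n=1e4 cannot come from 100-point draws
        x, y = sample_potential_pair(10_000, 1.0, seed=10)
        r = sd.resampled_comparison(x, y, sd.ResamplingConfig(n_iterations=5, seed=0))
        assert r.median_shift == pytest.approx(np.median(y) - np.median(x))

    def test_null_median_p_does_not_drift_with_more_iterations(self):
        """More resampling iterations must not manufacture significance."""
        x, y = sample_potential_pair(5000, 0.0, seed=11)
        p_small = sd.resampled_comparison(
            x, y, sd.ResamplingConfig(n_iterations=100, seed=1)).p_ad
        p_large = sd.resampled_comparison(
            x, y, sd.ResamplingConfig(n_iterations=1000, seed=1)).p_ad
        assert p_small > 0.05 and p_large > 0.05
        assert abs(p_large - p_small) < 0.25


def test_format_p_three_significant_digits_and_underflow():
    assert format_p(1.06e-7) == "1.06e-07"
    assert format_p(0.0) == "<1e-300"
    assert format_p(4.2e-301) == "<1e-300"
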