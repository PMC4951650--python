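"""Avalanche statistics: extraction, distributions, cutoff and dimension
fits, collapse, and the maximum-likelihood power-law test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corticrit.avalanches import (
    collapse,
    cumulative_distribution,
    extract_avalanches,
    fit_cutoff,
    fit_dimension,
    fit_two_range,
    log_binned_pdf,
    ml_powerlaw_test,
    sample_discrete_powerlaw,
)


class TestExtraction:
    @pytest.mark.parametrize(
        "A,sizes",
        [([0, 3, 5, 0, 2, 0], [8, 2]),
         ([1, 1, 1], [3]),
         ([0, 0, 0], []),
         ([5], [5]),
         ([0, 1, 0, 1, 0, 1], [1, 1, 1])],
    )
    def test_hand_examples(self, A, sizes):
        out = extract_avalanches(np.array(A))
        assert out.sizes.tolist() == sizes

    def test_onsets_and_offsets_bound_runs(self):
        out = extract_avalanches(np.array([0, 3, 5, 0, 0, 2, 0]))
        assert out.onsets.tolist() == [1, 5]
        assert out.offsets.tolist() == [2, 5]

    @given(st.lists(st.integers(min_value=0, max_value=20), min_size=1, max_size=300))
    @settings(max_examples=200, deadline=None)
    def test_partition_conserves_activity(self, A):
        arr = np.array(A)
        out = extract_avalanches(arr)
        assert out.sizes.sum() == arr.sum()
        assert np.all(out.sizes >= 1)

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            extract_avalanches(np.array([1, -1, 2]))


class TestDistributions:
    def test_ccdf_hand_example(self):
        d = cumulative_distribution(np.array([1, 1, 2, 4]))
        assert d.s.tolist() == [1, 2, 4]
        assert d.ccdf.tolist() == [1.0, 0.5, 0.25]

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_ccdf_matches_bruteforce_tally(self, sizes):
        arr = np.array(sizes)
        d = cumulative_distribution(arr)
        for s, F in zip(d.s, d.ccdf):
            assert F == pytest.approx(np.mean(arr >= s))
        assert np.all(np.diff(d.ccdf) < 1e-15)  # non-increasing
        assert d.ccdf[0] == 1.0

    def test_powerlaw_sample_has_expected_ccdf_slope(self, rng):
        # alpha = 1.5 pdf -> cumulative slope -(alpha-1) = -0.5 in mid-range
        sz = sample_discrete_powerlaw(1.5, 1, 1_000_000, 200_000, rng)
        d = cumulative_distribution(sz)
        m = (d.s >= 10) & (d.s <= 100)  # far below the truncation: pure slope
        slope = np.polyfit(np.log10(d.s[m].astype(float)), np.log10(d.ccdf[m]), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.05)

    def test_log_binned_pdf_normalised(self, rng):
        sz = sample_discrete_powerlaw(1.5, 1, 1000, 20_000, rng)
        centers, dens = log_binned_pdf(sz)
        assert np.all(dens >= 0) and np.all(np.diff(centers) > 0)


class TestCutoffFit:
    def test_recovers_known_truncated_powerlaw(self, rng):
        """Generator truth: alpha within 0.05, cutoff within 20%."""
        alpha, Z = 1.5, 2000
        sz = sample_discrete_powerlaw(alpha, 1, Z, 300_000, rng)
        fit = fit_cutoff(sz)
        assert fit.converged
        assert fit.alpha == pytest.approx(alpha, abs=0.05)
        assert fit.Z == pytest.approx(Z, rel=0.2)

    def test_untruncated_powerlaw_gives_no_spurious_cutoff(self, rng):
        sz = sample_discrete_powerlaw(1.8, 1, 10_000_000, 50_000, rng)
        fit = fit_cutoff(sz)
        assert fit.Z > sz.max()

    def test_degenerate_c2_flagged(self):
        from corticrit.avalanches import _cutoff_from_coeffs

        Z, msg = _cutoff_from_coeffs(0.5, 1.5, 0.0)
        assert np.isinf(Z) and "undefined" in msg
        Z, msg = _cutoff_from_coeffs(0.5, 1.5, 0.1)  # same sign: no root
        assert np.isinf(Z) and msg

    def test_narrow_range_flagged_not_fitted(self):
        fit = fit_cutoff(np.array([3, 3, 4, 4, 5]))
        assert not fit.converged and "narrow" in fit.message

    def test_two_range_split_recovers_both_slopes(self, rng):
        """Mixture with distinct exponents below/above the breakpoint."""
        lo = sample_discrete_powerlaw(1.4, 1, 196, 200_000, rng)
        hi = sample_discrete_powerlaw(1.9, 197, 20_000, 20_000, rng)
        below, above = fit_two_range(np.concatenate([lo, hi]), breakpoint=196)
        assert below.alpha == pytest.approx(1.4, abs=0.15)
        assert above.alpha == pytest.approx(1.9, abs=0.25)


class TestDimensionFit:
    def test_exact_quadratic_scaling(self):
        fit = fit_dimension({L: 3 * L ** 2 for L in (10, 20, 40, 80)})
        assert fit.D == pytest.approx(2.0, rel=1e-12)
        assert fit.amplitude == pytest.approx(3.0, rel=1e-9)

    def test_constant_cutoff_means_dimension_zero(self):
        fit = fit_dimension({10: 55.0, 20: 55.0, 40: 55.0})
        assert fit.D == pytest.approx(0.0, abs=1e-12)

    def test_too_few_sizes_rejected(self):
        with pytest.raises(ValueError):
            fit_dimension({10: 5.0, 20: 9.0})


class TestCollapse:
    def test_identical_distributions_collapse_perfectly_at_D0(self, rng):
        sz = sample_discrete_powerlaw(1.5, 1, 500, 50_000, rng)
        d = cumulative_distribution(sz)
        res = collapse({10: d, 20: d, 40: d}, alpha=1.5, D=0.0)
        assert res.quality == pytest.approx(0.0, abs=1e-12)

    def test_true_exponents_minimise_quality_on_grid(self, rng):
        """Grid-search oracle: synthetic truncated power laws with known
        (alpha, D) score best at the truth."""
        alpha, D = 1.5, 1.0
        dists = {
            L: cumulative_distribution(
                sample_discrete_powerlaw(alpha, 1, int(50 * L ** D), 150_000, rng))
            for L in (10, 20, 40)
        }
        truth = collapse(dists, alpha, D).quality
        for a, d_ in [(1.2, 1.0), (1.8, 1.0), (1.5, 0.3), (1.5, 1.7), (2.0, 2.0)]:
            assert truth < collapse(dists, a, d_).quality

    def test_single_size_rejected(self, rng):
        d = cumulative_distribution(sample_discrete_powerlaw(1.5, 1, 100, 1000, rng))
        with pytest.raises(ValueError):
            collapse({10: d}, 1.5, 1.0)


class TestMLPowerlawTest:
    def test_recovers_alpha_and_accepts_true_powerlaw(self, rng):
        sz = sample_discrete_powerlaw(1.5, 1, 1000, 10_000, rng)
        res = ml_powerlaw_test(sz, 1, 1000, n_boot=100, rng=rng)
        assert res.alpha == pytest.approx(1.5, abs=0.05)
        assert res.p_value > 0.1

    def test_rejects_exponential_sample(self, rng):
        sz = np.ceil(rng.exponential(20.0, size=5000)).astype(int)
        res = ml_powerlaw_test(sz, 1, int(sz.max()), n_boot=100, rng=rng)
        assert res.p_value < 0.05

    def test_insufficient_data_rejected(self, rng):
        with pytest.raises(ValueError):
            ml_powerlaw_test(np.arange(1, 60), 1, 100, rng=rng)

    def test_mle_and_cutoff_fit_agree_on_synthetic_truth(self, rng):
        """Estimator consistency within joint uncertainties."""
        sz = sample_discrete_powerlaw(1.6, 1, 5000, 100_000, rng)
        a_ml = ml_powerlaw_test(sz, 1, 5000, n_boot=0 or 10, rng=rng).alpha
        a_cut = fit_cutoff(sz).alpha
        assert a_ml == pytest.approx(a_cut, abs=0.15)
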