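"""KDE probability estimation and the Rényi entropy spectrum."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import gaussian_kde

from bretropy.renyi import (
    ALPHA_GRID,
    KdeParams,
    ProbabilityDistribution,
    coarse_grain,
    estimate_pdf,
    renyi_entropy,
    renyi_spectrum,
    silverman_bandwidth,
)
from bretropy.sampen import DegenerateInputError

from .oracles import naive_renyi


def _dirichlet(n, seed):
    return np.random.default_rng(seed).dirichlet(np.ones(n))


class TestRenyiEntropy:
    def test_uniform_distribution_is_fixed_point_of_spectrum(self):
        p = np.full(4, 0.25)
        for a in ALPHA_GRID:
            assert renyi_entropy(p, a) == pytest.approx(math.log(4), rel=1e-12)

    def test_point_mass_has_zero_entropy(self):
        p = np.array([1.0, 0.0, 0.0])
        assert renyi_entropy(p, 2) == pytest.approx(0.0, abs=1e-12)
        assert renyi_entropy(p, math.inf) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_collision_and_min_entropy(self):
        p = np.array([0.5, 0.25, 0.25])
        assert renyi_entropy(p, 2) == pytest.approx(-math.log(0.375), rel=1e-12)
        assert renyi_entropy(p, math.inf) == pytest.approx(-math.log(0.5), rel=1e-12)

    def test_special_orders(self):
        p = _dirichlet(20, 3)
        assert renyi_entropy(p, 0) == pytest.approx(math.log(20), rel=1e-12)
        assert renyi_entropy(p, 1) == pytest.approx(float(-(p * np.log(p)).sum()), rel=1e-12)
        assert renyi_entropy(p, math.inf) == pytest.approx(-math.log(p.max()), rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_summation_on_random_distributions(self, seed):
        p = _dirichlet(50, seed)
        for a in ALPHA_GRID:
            assert renyi_entropy(p, a) == pytest.approx(naive_renyi(p, a), rel=1e-10)

    def test_negative_order_with_zero_mass_diverges(self):
        with pytest.raises(ValueError, match="diverges"):
            renyi_entropy(np.array([0.5, 0.5, 0.0]), -2)

    def test_shannon_limit_continuity(self):
        p = _dirichlet(30, 11)
        h1 = renyi_entropy(p, 1)
        assert abs(renyi_entropy(p, 1 + 1e-6) - h1) <= 1e-4
        assert abs(renyi_entropy(p, 1 - 1e-6) - h1) <= 1e-4

    @settings(max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 500), n=st.integers(3, 60))
    def test_spectrum_non_increasing_in_alpha(self, seed, n):
        """Classical property: H_alpha is non-increasing in the order."""
        p = _dirichlet(n, seed)
        h = [renyi_entropy(p, a) for a in ALPHA_GRID]
        assert all(h[i] >= h[i + 1] - 1e-9 for i in range(len(h) - 1))

    def test_base_cancels_in_normalized_spectrum(self):
        p = _dirichlet(40, 5)
        h0_nats, h0_bits = math.log(len(p)), math.log2(len(p))
        for a in ALPHA_GRID:
            nats = renyi_entropy(p, a) / h0_nats
            bits = renyi_entropy(p, a, base=2) / h0_bits
            assert nats == pytest.approx(bits, abs=1e-12)


class TestKde:
    def test_probabilities_positive_and_normalized(self, rng):
        dist = estimate_pdf(rng.standard_normal(60))
        assert len(dist) == 60
        assert abs(dist.p.sum() - 1.0) <= 1e-12
        assert np.all(dist.p > 0)

    def test_silverman_bandwidth_closed_form(self, rng):
        x = rng.standard_normal(100)
        s = x.std(ddof=1)
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        expected = 0.9 * min(s, iqr / 1.34) * 100 ** (-0.2)
        assert silverman_bandwidth(x) == pytest.approx(expected, rel=1e-12)

    def test_bimodal_series_yields_bimodal_probabilities(self, rng):
        x = np.concatenate([rng.normal(0.0, 0.02, 25), rng.normal(1.0, 0.02, 25)])
        dist = estimate_pdf(x)
        mid = np.argmin(np.abs(dist.support - 0.5))
        lo_mode = dist.p[dist.support < 0.25].max()
        hi_mode = dist.p[dist.support > 0.75].max()
        assert dist.p[mid] < lo_mode and dist.p[mid] < hi_mode

    def test_density_agrees_with_scipy_at_same_bandwidth(self, rng):
        """Cross-check against scipy's KDE forced to the same bandwidth."""
        x = rng.standard_normal(80)
        h = silverman_bandwidth(x)
        dist = estimate_pdf(x)
        ref = gaussian_kde(x, bw_method=h / x.std(ddof=1))(dist.support)
        assert np.allclose(dist.p, ref / ref.sum(), rtol=1e-8)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            estimate_pdf(np.full(20, 2.0))

    def test_bad_support_count_rejected(self):
        with pytest.raises(ValueError):
            KdeParams(n_support=1)


class TestSpectrum:
    def test_equal_mass_distribution_normalizes_to_one(self):
        p = np.full(25, 1.0 / 25)
        h0 = math.log(25)
        for a in ALPHA_GRID:
            assert renyi_entropy(p, a) / h0 == pytest.approx(1.0, rel=1e-12)

    def test_spectrum_on_simulated_trace(self, small_experiment_set):
        trace = small_experiment_set.traces[0]
        spec = renyi_spectrum(trace.segment("post_stim"))
        assert spec.alpha_grid == ALPHA_GRID
        assert spec.h0 == pytest.approx(math.log(len(trace.segment("post_stim"))))
        assert np.all(np.diff(spec.h_raw) <= 1e-9)
        # min-entropy is the floor of the normalized spectrum
        assert spec.h_norm[-1] == pytest.approx(spec.h_norm.min(), abs=1e-12)
        for a in (1.0, 2.0, 10.0):
            assert 0.0 < spec.value_at(a) <= 1.0 + 1e-12

    def test_probability_distribution_validation(self):
        with pytest.raises(ValueError, match="sum"):
            ProbabilityDistribution(np.arange(3.0), np.array([0.5, 0.2, 0.2]))
        with pytest.raises(ValueError, match="non-negative"):
            ProbabilityDistribution(np.arange(3.0), np.array([1.2, -0.1, -0.1]))


class TestCoarseGrain:
    def test_identity_at_scale_one(self, rng):
        x = rng.standard_normal(30)
        assert np.array_equal(coarse_grain(x, 1), x)

    def test_pairwise_means(self):
        out = coarse_grain(np.array([1.0, 3.0, 5.0, 7.0] * 5), 2)
        assert np.allclose(out[:2], [2.0, 6.0])
        assert len(out) == 10

    def test_length_floor(self):
        assert len(coarse_grain(np.arange(32.0), 3)) == 10

    def test_too_short_for_scale(self):
        with pytest.raises(ValueError):
            coarse_grain(np.arange(25.0), 3)
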