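"""Unit and property tests for the fractal-dimension estimators."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import pdist

from fractalbci import (DegenerateSignalError, EpochTooShortError, RadiusSpec,
                        correlation_dimension, correlation_integral,
                        delay_embed, gen_fbm, gpfd, hfd, hfd_batch,
                        higuchi_curve_length)


# ---------------------------------------------------------------------------
# delay embedding
# ---------------------------------------------------------------------------

class TestDelayEmbed:
    def test_vector_count_and_dimension(self, rng):
        emb = delay_embed(rng.standard_normal(1500), tau=50, M=3)
        assert emb.vectors.shape == (1400, 3)
        assert emb.Np == 1400

    def test_m1_is_identity(self, rng):
        x = rng.standard_normal(40)
        emb = delay_embed(x, tau=7, M=1)
        assert np.array_equal(emb.vectors.ravel(), x)

    def test_layout_matches_definition(self):
        emb = delay_embed([1, 2, 3, 4, 5], tau=1, M=2)
        assert np.array_equal(emb.vectors, [[1, 2], [2, 3], [3, 4], [4, 5]])

    def test_too_short_raises(self):
        with pytest.raises(EpochTooShortError, match="epoch too short"):
            delay_embed(np.arange(10.0), tau=5, M=3)

    @pytest.mark.parametrize("tau,M", [(0, 2), (1, 0)])
    def test_invalid_parameters(self, tau, M):
        with pytest.raises(ValueError):
            delay_embed(np.arange(100.0), tau=tau, M=M)


# ---------------------------------------------------------------------------
# correlation integral
# ---------------------------------------------------------------------------

class TestCorrelationIntegral:
    def test_all_pairs_inside(self):
        emb = delay_embed([0.0, 1.0], tau=1, M=1)
        assert correlation_integral(emb, r=2.0) == 1.0

    def test_radius_below_minimum_distance(self, rng):
        emb = delay_embed(rng.standard_normal(50), tau=1, M=2)
        assert correlation_integral(emb, r=1e-12) == 0.0

    def test_three_point_fraction(self):
        emb = delay_embed([0.0, 1.0, 2.0], tau=1, M=1)
        assert correlation_integral(emb, r=1.5) == pytest.approx(2.0 / 3.0)

    def test_distance_equal_to_radius_excluded(self):
        # Heaviside H(0) = 0: the pair at distance exactly 1 does not count
        emb = delay_embed([0.0, 1.0], tau=1, M=1)
        assert correlation_integral(emb, r=1.0) == 0.0

    def test_invalid_radius(self):
        emb = delay_embed([0.0, 1.0], tau=1, M=1)
        with pytest.raises(ValueError, match="radius"):
            correlation_integral(emb, r=0.0)

    @pytest.mark.parametrize("n,tau,M", [(60, 1, 2), (201, 3, 4), (300, 7, 2)])
    def test_matches_naive_double_loop(self, rng, n, tau, M):
        """Exact agreement with an O(Np^2) pair count on short signals."""
        x = rng.standard_normal(n)
        emb = delay_embed(x, tau, M)
        d = pdist(emb.vectors)
        grid = np.concatenate([np.geomspace(d.min(), d.max(), 12),
                               d[:5]])  # includes radii exactly at distances
        for r in grid[grid > 0]:
            count = 0
            for i in range(emb.Np):
                for j in range(i + 1, emb.Np):
                    if np.sqrt(np.sum((emb.vectors[i] - emb.vectors[j]) ** 2)) < r:
                        count += 1
            naive = count / (emb.Np * (emb.Np - 1) / 2)
            assert correlation_integral(emb, r) == naive


# ---------------------------------------------------------------------------
# correlation dimension and GPFD
# ---------------------------------------------------------------------------

class TestCorrelationDimension:
    def test_line_segment_dimension_one(self):
        # a ramp embeds onto a straight line: d_c ~ 1
        curve = correlation_dimension(np.linspace(0, 1, 600), tau=5, M=2)
        assert curve.slope == pytest.approx(1.0, abs=0.1)

    def test_plane_filling_dimension_two(self, rng):
        # iid noise fills the 2-D embedding plane: d_c ~ 2
        curve = correlation_dimension(rng.standard_normal(1200), tau=3, M=2)
        assert curve.slope == pytest.approx(2.0, abs=0.25)

    def test_identical_points_flat_curve_with_explicit_grid(self):
        spec = RadiusSpec(radii=np.array([0.5, 1.0, 2.0]))
        curve = correlation_dimension(np.zeros(100), tau=1, M=2, radius_spec=spec)
        assert np.all(curve.values == 1.0)
        assert curve.slope == 0.0

    def test_zero_diameter_attractor_raises(self):
        with pytest.raises((DegenerateSignalError, ValueError)):
            correlation_dimension(np.zeros(100), tau=1, M=2)

    def test_curve_monotone_and_bounded(self, rng):
        curve = correlation_dimension(rng.standard_normal(400), tau=2, M=3)
        assert np.all(np.diff(curve.values) >= 0)
        assert np.all((curve.values >= 0) & (curve.values <= 1))

    def test_subsampled_vectors_agree(self, rng):
        x = np.cumsum(rng.standard_normal(1500))
        full = correlation_dimension(x, tau=50, M=3).slope
        capped = correlation_dimension(x, tau=50, M=3, max_vectors=600).slope
        assert capped == pytest.approx(full, abs=0.15)


class TestGPFD:
    def test_sinusoid_limit_cycle(self):
        # 7.3 Hz at fs=500: period incommensurate with tau=50
        x = np.sin(2 * np.pi * 7.3 * np.arange(1500) / 500.0)
        res = gpfd(x, tau=50)
        assert res.fd == pytest.approx(1.0, abs=0.15)

    def test_white_noise_does_not_saturate(self, rng):
        res = gpfd(rng.standard_normal(1500), tau=50, M_max=10)
        assert not res.saturated
        dcs = [dc for _, dc in res.dc_trajectory]
        assert len(dcs) == 9  # M = 2..10
        assert np.all(np.diff(dcs) > 0)  # d_c keeps growing with M

    def test_fd_equals_last_trajectory_entry(self, rng):
        res = gpfd(np.cumsum(rng.standard_normal(1200)), tau=40)
        assert res.fd == res.dc_trajectory[-1][1]
        assert res.M_final == res.dc_trajectory[-1][0]

    def test_saturation_consistency(self):
        x = np.sin(2 * np.pi * 7.3 * np.arange(1500) / 500.0)
        res = gpfd(x, tau=50)
        if res.saturated:
            dcs = dict(res.dc_trajectory)
            assert abs(dcs[res.M_final] - dcs[res.M_final - 1]) < res.epsilon

    def test_matches_correlation_dimension_bitwise(self, rng):
        x = np.cumsum(rng.standard_normal(900))
        res = gpfd(x, tau=30, M_max=5)
        for M, dc in res.dc_trajectory:
            assert dc == correlation_dimension(x, tau=30, M=M).slope

    def test_infeasible_embedding_stops_flagged(self, rng):
        # tau so large that M=4 is infeasible: stops at the last feasible M
        res = gpfd(rng.standard_normal(200), tau=60, M_max=50)
        assert res.M_final <= 4
        assert not res.saturated

    def test_constant_signal_raises(self):
        with pytest.raises(DegenerateSignalError):
            gpfd(np.ones(500), tau=10)

    def test_eeg_like_surrogate_stops_in_soft_range(self):
        # correlated-noise surrogate at the analysis defaults: the
        # saturation loop ends somewhere in the tens of dimensions
        x = gen_fbm(1500, 0.3, seed=4)
        x += 0.1 * np.random.default_rng(4).standard_normal(1500)
        res = gpfd(x, tau=50, epsilon=1e-3)
        assert 10 <= res.M_final <= 30

    def test_amplitude_invariance(self):
        x = gen_fbm(1200, 0.4, seed=7)
        assert abs(gpfd(x, tau=40).fd - gpfd(5.0 * x, tau=40).fd) < 1e-9

    @given(st.integers(0, 1000))
    def test_terminates_for_any_signal(self, seed):
        x = np.random.default_rng(seed).standard_normal(240)
        res = gpfd(x, tau=3, M_max=8)
        assert 2 <= res.M_final <= 8
        assert np.isfinite(res.fd)


# ---------------------------------------------------------------------------
# Higuchi
# ---------------------------------------------------------------------------

class TestHiguchiCurveLength:
    def test_constant_signal_zero_length(self):
        assert higuchi_curve_length(np.full(100, 3.0), m=1, k=5) == 0.0

    @pytest.mark.parametrize("a,m,k", [(1.0, 1, 1), (2.5, 2, 7), (0.3, 4, 10)])
    def test_linear_ramp_closed_form(self, a, m, k):
        N = 300
        y = a * np.arange(N)
        assert higuchi_curve_length(y, m, k) == pytest.approx(a * (N - 1) / k)

    def test_k1_is_total_variation(self, rng):
        y = rng.standard_normal(120)
        tv = np.abs(np.diff(y)).sum()
        assert higuchi_curve_length(y, m=1, k=1) == pytest.approx(tv)

    def test_interval_exceeding_signal(self):
        with pytest.raises(ValueError, match="interval exceeds"):
            higuchi_curve_length(np.arange(10.0), m=1, k=10)


class TestHFD:
    def test_ramp_fd_exactly_one(self):
        res = hfd(np.arange(1500, dtype=float), kmax=100)
        assert res.fd == pytest.approx(1.0, abs=1e-9)
        assert res.fit_r2 == pytest.approx(1.0, abs=1e-12)

    def test_white_noise_fd_near_two(self):
        vals = [hfd(np.random.default_rng(s).standard_normal(1500), 100).fd
                for s in range(5)]
        assert np.mean(vals) == pytest.approx(2.0, abs=0.1)

    def test_fbm_fd_matches_two_minus_hurst(self):
        vals = [hfd(gen_fbm(1500, 0.5, seed=s), 100).fd for s in range(5)]
        assert np.mean(vals) == pytest.approx(1.5, abs=0.1)

    def test_lengths_match_curve_length_average(self, rng):
        y = rng.standard_normal(400)
        res = hfd(y, kmax=15)
        for k in (1, 4, 9, 15):
            mean_lm = np.mean([higuchi_curve_length(y, m, k)
                               for m in range(1, k + 1)])
            assert res.lengths[k - 1] == pytest.approx(mean_lm, rel=1e-12)

    def test_batch_matches_single(self, rng):
        Y = rng.standard_normal((4, 800))
        batch = hfd_batch(Y, kmax=60)
        singles = [hfd(y, kmax=60).fd for y in Y]
        assert np.allclose(batch, singles, atol=1e-12)

    def test_amplitude_invariance(self):
        y = gen_fbm(1000, 0.6, seed=3)
        assert abs(hfd(y).fd - hfd(7.0 * y).fd) < 1e-9

    def test_constant_input_raises(self):
        with pytest.raises(DegenerateSignalError, match="zero curve length"):
            hfd(np.ones(500))

    def test_kmax_bounds(self):
        with pytest.raises(ValueError):
            hfd(np.arange(100.0), kmax=50)

    def test_lengths_positive_for_nonconstant_input(self, rng):
        res = hfd(rng.standard_normal(600), kmax=40)
        assert np.all(res.lengths > 0)
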