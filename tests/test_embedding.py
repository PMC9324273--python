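import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rqalen as rq


def brute_autocorr_crossing(x):
    """Independent O(n*k) autocorrelation oracle: first lag below 1/e."""
    xm = x - x.mean()
    var = np.dot(xm, xm)
    k = 1
    while np.dot(xm[:-k], xm[k:]) / var >= 1 / math.e:
        k += 1
    return k


class TestEstimateDelay:
    def test_white_noise_decorrelates_at_lag_one(self):
        rng = np.random.default_rng(0)
        ts = rq.TimeSeries(rng.standard_normal(500), 1.0)
        assert rq.estimate_delay(ts) == 1

    def test_cosine_matches_autocorrelation_oracle(self):
        period, n = 100, 10_000
        x = np.cos(2 * np.pi * np.arange(n) / period)
        lag = rq.estimate_delay(rq.TimeSeries(x, 1.0))
        assert lag == brute_autocorr_crossing(x)
        closed_form = math.ceil(period * math.acos(1 / math.e) / (2 * np.pi))
        assert abs(lag - closed_form) <= 1  # finite-n bias of the estimator

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            rq.estimate_delay(rq.TimeSeries(np.full(100, 3.0), 1.0))

    def test_invariant_under_constant_offset(self):
        rng = np.random.default_rng(3)
        x = np.sin(np.arange(400) / 7.0) + 0.2 * rng.standard_normal(400)
        base = rq.estimate_delay(rq.TimeSeries(x, 1.0))
        shifted = rq.estimate_delay(rq.TimeSeries(x + 123.4, 1.0))
        assert base == shifted


class TestDelayEmbed:
    @pytest.mark.parametrize(
        "values,m,tau,expected",
        [
            ([1, 2, 3, 4, 5], 2, 1, [[1, 2], [2, 3], [3, 4], [4, 5]]),
            ([1, 2, 3, 4, 5], 1, 3, [[1], [2], [3], [4], [5]]),
            ([1, 2, 3, 4, 5, 6], 3, 2, [[1, 3, 5], [2, 4, 6]]),
        ],
    )
    def test_examples(self, values, m, tau, expected):
        traj = rq.delay_embed(rq.TimeSeries(np.array(values, float), 1.0),
                              rq.EmbeddingSpec(m, tau))
        assert traj.points.tolist() == expected
        assert len(traj) == len(values) - (m - 1) * tau

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            rq.delay_embed(rq.TimeSeries(np.arange(6.0), 1.0), rq.EmbeddingSpec(4, 2))

    @settings(deadline=None, max_examples=50)
    @given(
        n=st.integers(5, 60),
        m=st.integers(1, 4),
        tau=st.integers(1, 5),
        seed=st.integers(0, 2**16),
    )
    def test_count_formula_and_first_coordinate(self, n, m, tau, seed):
        if n <= (m - 1) * tau:
            return
        x = np.random.default_rng(seed).standard_normal(n)
        traj = rq.delay_embed(rq.TimeSeries(x, 1.0), rq.EmbeddingSpec(m, tau))
        assert len(traj) == n - (m - 1) * tau
        np.testing.assert_array_equal(traj.points[:, 0], x[: len(traj)])


class TestAttractorDiameter:
    def test_two_points(self):
        traj = rq.EmbeddedTrajectory(np.array([[0.0, 0.0], [3.0, 4.0]]),
                                     rq.EmbeddingSpec(2, 1))
        assert rq.attractor_diameter(traj) == pytest.approx(5.0)

    def test_coincident_points_give_zero(self):
        traj = rq.EmbeddedTrajectory(np.ones((5, 2)), rq.EmbeddingSpec(2, 1))
        assert rq.attractor_diameter(traj) == 0.0

    @pytest.mark.parametrize("norm", ["euclidean", "chebyshev"])
    def test_matches_brute_force_all_pairs(self, norm):
        rng = np.random.default_rng(11)
        pts = rng.uniform(size=(100, 2))
        traj = rq.EmbeddedTrajectory(pts, rq.EmbeddingSpec(2, 1))
        ords = {"euclidean": 2, "chebyshev": np.inf}[norm]
        best = max(
            np.linalg.norm(pts[i] - pts[j], ord=ords)
            for i in range(100)
            for j in range(i + 1, 100)
        )
        assert rq.attractor_diameter(traj, norm) == pytest.approx(best)

    def test_translation_invariant_and_scale_linear(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((50, 3))
        traj = rq.EmbeddedTrajectory(pts, rq.EmbeddingSpec(3, 1))
        d = rq.attractor_diameter(traj)
        shifted = rq.EmbeddedTrajectory(pts + 7.5, rq.EmbeddingSpec(3, 1))
        scaled = rq.EmbeddedTrajectory(pts * 3.0, rq.EmbeddingSpec(3, 1))
        assert rq.attractor_diameter(shifted) == pytest.approx(d)
        assert rq.attractor_diameter(scaled) == pytest.approx(3.0 * d)

    def test_single_point_rejected(self):
        traj = rq.EmbeddedTrajectory(np.zeros((1, 2)), rq.EmbeddingSpec(2, 1))
        with pytest.raises(ValueError, match="two points"):
            rq.attractor_diameter(traj)


class TestAverageCycle:
    def test_fixed_ppg_convention(self):
        ts = rq.TimeSeries(np.sin(np.arange(1000)), 409.6)
        assert rq.average_cycle(ts, "fixed", 0.8) == pytest.approx(327.68)

    def test_sine_period_recovered_empirically(self):
        x = np.sin(2 * np.pi * np.arange(2000) / 100)
        cyc = rq.average_cycle(rq.TimeSeries(x, 100.0), "empirical")
        assert cyc == pytest.approx(100.0, abs=0.5)

    def test_too_few_peaks_rejected(self):
        x = np.sin(2 * np.pi * np.arange(150) / 100)  # 1.5 periods
        with pytest.raises(ValueError, match="cannot estimate cycle"):
            rq.average_cycle(rq.TimeSeries(x, 1.0), "empirical")

    def test_fixed_mode_requires_positive_duration(self):
        ts = rq.TimeSeries(np.sin(np.arange(100.0)), 1.0)
        with pytest.raises(ValueError):
            rq.average_cycle(ts, "fixed", None)
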