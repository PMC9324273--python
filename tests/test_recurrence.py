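import numpy as np
import pytest

import rqalen as rq
from conftest import random_trajectory


def two_point_traj(d):
    pts = np.array([[0.0, 0.0], [d * 0.6, d * 0.8]])
    return rq.EmbeddedTrajectory(pts, rq.EmbeddingSpec(2, 1))


def spec_with_eps(eps, theiler=1, norm="euclidean"):
    return rq.RecurrenceSpec(0.1, eps, theiler, norm)


class TestRecurrenceMatrix:
    def test_two_points_within_threshold(self):
        rm = rq.recurrence_matrix(two_point_traj(5.0), spec_with_eps(6.0))
        assert rm.matrix.astype(int).tolist() == [[1, 1], [1, 1]]

    def test_two_points_beyond_threshold(self):
        rm = rq.recurrence_matrix(two_point_traj(5.0), spec_with_eps(4.0))
        assert rm.matrix.astype(int).tolist() == [[1, 0], [0, 1]]

    def test_tie_at_threshold_is_non_recurrent(self):
        rm = rq.recurrence_matrix(two_point_traj(5.0), spec_with_eps(5.0))
        assert rm.matrix.astype(int).tolist() == [[1, 0], [0, 1]]

    def test_matches_brute_force_thresholding(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(size=(50, 2))
        traj = rq.EmbeddedTrajectory(pts, rq.EmbeddingSpec(2, 1))
        eps = 0.1 * rq.attractor_diameter(traj)
        rm = rq.recurrence_matrix(traj, spec_with_eps(eps))
        expected = np.array(
            [[np.linalg.norm(p - q) < eps for q in pts] for p in pts]
        )
        np.testing.assert_array_equal(rm.matrix, expected)
        np.testing.assert_array_equal(rm.matrix, rm.matrix.T)
        assert rm.matrix.diagonal().all()

    def test_size_cap_enforced(self):
        traj = rq.EmbeddedTrajectory(
            np.random.default_rng(0).standard_normal((5001, 1)),
            rq.EmbeddingSpec(1, 1),
        )
        with pytest.raises(ValueError, match="streaming"):
            rq.recurrence_matrix(traj, spec_with_eps(1.0))


class TestDiagonalHistogram:
    def test_constant_series_five_points(self):
        # all-ones 5x5 matrix, theiler=1: each off-diagonal is one maximal
        # line, both triangles counted
        ts = rq.TimeSeries(np.zeros(5) + 2.0, 1.0)
        traj = rq.delay_embed(ts, rq.EmbeddingSpec(1, 1))
        hist = rq.diagonal_histogram(traj, spec_with_eps(0.5, theiler=1))
        assert hist.as_dict() == {4: 2, 3: 2, 2: 2, 1: 2}

    def test_theiler_covering_matrix_gives_empty_histogram(self):
        traj = random_trajectory(np.random.default_rng(1), n=30, dim=2)
        hist = rq.diagonal_histogram(traj, spec_with_eps(10.0, theiler=30))
        assert hist.as_dict() == {}

    def test_matches_matrix_rle_on_noisy_rossler_segment(self):
        ts = rq.simulate_rossler(rq.RosslerConfig(theta=0.3, n_out=200, seed=9))
        traj = rq.delay_embed(ts, rq.EmbeddingSpec(3, 5))
        rec = rq.RecurrenceSpec.from_trajectory(traj, 0.1, 1)
        streaming = rq.diagonal_histogram(traj, rec)
        oracle = rq.histogram_from_matrix(rq.recurrence_matrix(traj, rec))
        np.testing.assert_array_equal(streaming.counts, oracle.counts)

    @pytest.mark.parametrize("theiler", [0, 1, 3])
    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_random_trajectories(self, seed, theiler):
        rng = np.random.default_rng(seed)
        traj = random_trajectory(rng)
        eps = max(1e-6, float(rng.uniform(0.05, 0.5)) * rq.attractor_diameter(traj))
        spec = spec_with_eps(eps, theiler=theiler)
        streaming = rq.diagonal_histogram(traj, spec)
        oracle = rq.histogram_from_matrix(rq.recurrence_matrix(traj, spec))
        np.testing.assert_array_equal(streaming.counts, oracle.counts)

    @pytest.mark.parametrize("theiler", [0, 1, 2])
    def test_conservation_equals_direct_cell_count(self, theiler):
        rng = np.random.default_rng(21)
        traj = random_trajectory(rng, n=80, dim=2)
        spec = rq.RecurrenceSpec.from_trajectory(traj, 0.15, theiler)
        hist = rq.diagonal_histogram(traj, spec)
        rm = rq.recurrence_matrix(traj, spec)
        i, j = np.indices(rm.matrix.shape)
        outside_band = np.abs(i - j) >= theiler
        assert hist.total_recurrent_points == int(rm.matrix[outside_band].sum())

    def test_counts_even_with_theiler_window(self):
        rng = np.random.default_rng(8)
        traj = random_trajectory(rng, n=90, dim=3)
        spec = rq.RecurrenceSpec.from_trajectory(traj, 0.2, 1)
        hist = rq.diagonal_histogram(traj, spec)
        assert all(c % 2 == 0 for c in hist.as_dict().values())

    def test_recurrent_mass_monotone_in_epsilon(self):
        rng = np.random.default_rng(13)
        traj = random_trajectory(rng, n=100, dim=2)
        diam = rq.attractor_diameter(traj)
        masses = [
            rq.diagonal_histogram(traj, spec_with_eps(f * diam)).total_recurrent_points
            for f in (0.05, 0.1, 0.2, 0.4, 0.8)
        ]
        assert masses == sorted(masses)

    def test_csv_serialization_with_sidecar(self, tmp_path):
        traj = random_trajectory(np.random.default_rng(5), n=40, dim=2)
        spec = rq.RecurrenceSpec.from_trajectory(traj, 0.2, 1)
        hist = rq.diagonal_histogram(traj, spec)
        out = tmp_path / "hist.csv"
        hist.to_csv(out)
        lines = out.read_text().splitlines()
        assert lines[0] == "length,count"
        parsed = {int(l.split(",")[0]): int(l.split(",")[1]) for l in lines[1:]}
        assert parsed == hist.as_dict()
        import json

        sidecar = json.loads((tmp_path / "hist.csv.json").read_text())
        assert sidecar["theiler"] == 1 and sidecar["n_points"] == 40
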