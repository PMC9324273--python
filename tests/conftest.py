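"""Shared fixtures.

The heavy pipeline objects (50,000-point Rossler runs, the synthetic PPG
recording and their recurrence structures) are session-scoped so the
reference computation happens once per test run.
"""

from __future__ import annotations

import pytest

import rqalen as rq


def full_pipeline(ts, dimension, lmin=2, epsilon=0.1, theiler=1):
    """Embed, threshold at 10% of diameter, and quantify one series."""
    tau = rq.estimate_delay(ts)
    traj = rq.delay_embed(ts, rq.EmbeddingSpec(dimension, tau))
    rec = rq.RecurrenceSpec.from_trajectory(traj, epsilon, theiler)
    hist = rq.diagonal_histogram(traj, rec)
    measures = rq.compute_measures(hist, rq.RQAConfig(lmin))
    return {"tau": tau, "traj": traj, "rec": rec, "hist": hist, "measures": measures}


@pytest.fixture(scope="session")
def rossler_clean():
    """Noise-free Rossler x series, 50,000 points at 200 Hz."""
    return rq.simulate_rossler(rq.RosslerConfig(theta=0.0, n_out=50_000))


@pytest.fixture(scope="session")
def rossler_reference(rossler_clean):
    """Reference pipeline state for the clean 50,000-point series."""
    return full_pipeline(rossler_clean, dimension=3)


@pytest.fixture(scope="session")
def ppg_default():
    """Default synthetic PPG recording (5 min at 409.6 Hz)."""
    return rq.simulate_ppg(rq.PPGSimConfig(seed=5))


def random_trajectory(rng, n=None, dim=None):
    n = n if n is not None else int(rng.integers(10, 120))
    dim = dim if dim is not None else int(rng.integers(1, 4))
    pts = rng.standard_normal((n, dim))
    return rq.EmbeddedTrajectory(pts, rq.EmbeddingSpec(dim, 1))
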