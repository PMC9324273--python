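"""Time-delay embedding of scalar time series.

A scalar series :math:`\\{x_i\\}_{i=1}^{n}` sampled uniformly at rate ``fs``
is reconstructed into an ``m``-dimensional trajectory of points

.. math::

    X_j = (x_j, x_{j+\\tau}, x_{j+2\\tau}, \\dots, x_{j+(m-1)\\tau}),
    \\qquad j = 1, \\dots, N, \\quad N = n - (m-1)\\tau,

where ``tau`` is the delay in samples.  The delay is chosen as the first lag
at which the normalized autocorrelation of the signal drops below ``1/e``;
the embedding dimension is taken as given (4 for near-infrared PPG signals,
3 for the Rossler system by default).

This module also provides the attractor geometry needed downstream: the
attractor diameter (maximum pairwise distance between trajectory points,
which calibrates the recurrence threshold) and the average cycle length
(mean time for the trajectory to complete one loop, the natural unit for
expressing recording lengths).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.signal import find_peaks

__all__ = [
    "TimeSeries",
    "EmbeddingSpec",
    "EmbeddedTrajectory",
    "autocorrelation",
    "estimate_delay",
    "delay_embed",
    "attractor_diameter",
    "average_cycle",
]

#: Hard cap on trajectory size for exact all-pairs diameter computation.
MAX_DIAMETER_POINTS = 60_000


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    values
        Ordered samples, arbitrary signal units.
    sampling_rate
        Samples per second (Hz), strictly positive.
    label
        Free-text description carried through to outputs.
    """

    values: np.ndarray
    sampling_rate: float
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.ndim != 1:
            raise ValueError("time series must be one-dimensional")
        if values.size < 2:
            raise ValueError("time series needs at least two samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contains non-finite values")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return len(self) / self.sampling_rate

    def segment(self, start: int, length: int, label: str | None = None) -> "TimeSeries":
        """Contiguous sub-series of ``length`` samples starting at ``start``."""
        if start < 0 or start + length > len(self):
            raise ValueError(
                f"segment [{start}, {start + length}) out of range for n={len(self)}"
            )
        return TimeSeries(
            self.values[start : start + length],
            self.sampling_rate,
            label if label is not None else self.label,
        )


@dataclass(frozen=True)
class EmbeddingSpec:
    """Delay-embedding parameters: dimension ``m`` and lag ``tau`` (samples)."""

    dimension: int
    lag: int

    def __post_init__(self) -> None:
        if int(self.dimension) < 1:
            raise ValueError("dimension must be >= 1")
        if int(self.lag) < 1:
            raise ValueError("lag must be >= 1")
        object.__setattr__(self, "dimension", int(self.dimension))
        object.__setattr__(self, "lag", int(self.lag))

    @property
    def span(self) -> int:
        """Number of samples covered by one embedded point minus one."""
        return (self.dimension - 1) * self.lag


@dataclass(frozen=True)
class EmbeddedTrajectory:
    """Delay-reconstructed trajectory: an ``(N, m)`` array of points."""

    points: np.ndarray
    spec: EmbeddingSpec

    def __post_init__(self) -> None:
        points = np.ascontiguousarray(self.points, dtype=np.float64)
        object.__setattr__(self, "points", points)
        if points.ndim != 2 or points.shape[1] != self.spec.dimension:
            raise ValueError("points must be an (N, m) array matching the spec")
        if points.shape[0] < 1:
            raise ValueError("trajectory must contain at least one point")

    def __len__(self) -> int:
        return int(self.points.shape[0])

    @property
    def count(self) -> int:
        return len(self)


def autocorrelation(values: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation at lags ``0 .. max_lag``.

    The mean is removed once globally and the lag-``k`` covariance is divided
    by ``n`` (biased estimator), then normalized by the lag-0 value so that
    the result at lag 0 is exactly 1.  Computed via FFT.
    """
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    x = x - x.mean()
    var = np.dot(x, x)
    if var == 0:
        raise ValueError("zero variance")
    nfft = 1 << int(np.ceil(np.log2(2 * n - 1)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return acov / var


def estimate_delay(ts: TimeSeries) -> int:
    """First lag at which the autocorrelation falls below ``1/e``.

    Raises
    ------
    ValueError
        If the series is constant ("zero variance") or the autocorrelation
        never drops below ``1/e`` within ``n/2`` lags ("no decorrelation").
    """
    n = len(ts)
    if n < 3:
        raise ValueError("need at least 3 samples to estimate a delay")
    max_lag = n // 2
    rho = autocorrelation(ts.values, max_lag)
    below = np.flatnonzero(rho[1:] < 1.0 / math.e)
    if below.size == 0:
        raise ValueError("no decorrelation: autocorrelation stays above 1/e")
    return int(below[0] + 1)


def delay_embed(ts: TimeSeries, spec: EmbeddingSpec) -> EmbeddedTrajectory:
    """Embed a scalar series into ``m`` dimensions with lag ``tau``.

    Point ``j`` (1-based) is ``(x_j, x_{j+tau}, ..., x_{j+(m-1)tau})``; the
    trajectory has ``N = n - (m-1) tau`` points.
    """
    n = len(ts)
    if n <= spec.span:
        raise ValueError(
            f"series too short for embedding: n={n} <= (m-1)*tau={spec.span}"
        )
    count = n - spec.span
    cols = [ts.values[k * spec.lag : k * spec.lag + count] for k in range(spec.dimension)]
    return EmbeddedTrajectory(np.column_stack(cols), spec)


@njit(cache=True)
def _max_pairwise_euclidean(points):  # pragma: no cover - numba kernel
    n, m = points.shape
    best = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = 0.0
            for k in range(m):
                diff = points[i, k] - points[j, k]
                d += diff * diff
            if d > best:
                best = d
    return best ** 0.5


@njit(cache=True)
def _max_pairwise_chebyshev(points):  # pragma: no cover - numba kernel
    n, m = points.shape
    best = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = 0.0
            for k in range(m):
                diff = abs(points[i, k] - points[j, k])
                if diff > d:
                    d = diff
            if d > best:
                best = d
    return best


def attractor_diameter(traj: EmbeddedTrajectory, norm: str = "euclidean") -> float:
    """Exact maximum pairwise distance between trajectory points.

    Evaluated exhaustively over all pairs; trajectories above
    ``MAX_DIAMETER_POINTS`` points are rejected rather than approximated.
    """
    if len(traj) < 2:
        raise ValueError("need at least two points")
    if len(traj) > MAX_DIAMETER_POINTS:
        raise ValueError(
            f"trajectory too large for exact diameter (N={len(traj)} > "
            f"{MAX_DIAMETER_POINTS})"
        )
    if norm == "euclidean":
        return float(_max_pairwise_euclidean(traj.points))
    if norm == "chebyshev":
        return float(_max_pairwise_chebyshev(traj.points))
    raise ValueError(f"unknown norm {norm!r}")


def _dominant_period(ts: TimeSeries) -> int:
    """Dominant oscillation period in samples, from the autocorrelation's
    first local maximum after lag 0."""
    max_lag = len(ts) // 2
    rho = autocorrelation(ts.values, max_lag)
    peaks, _ = find_peaks(rho[1:])
    if peaks.size == 0:
        raise ValueError("cannot estimate cycle: no periodicity in autocorrelation")
    return int(peaks[0] + 1)


def average_cycle(
    ts: TimeSeries,
    mode: str = "empirical",
    fixed_seconds: float | None = None,
) -> float:
    """Average cycle length of the signal, in samples.

    ``mode='fixed'`` converts a known cycle duration to samples (the PPG
    convention: a 0.8 s cardiac cycle at 409.6 Hz is 327.68 samples).
    ``mode='empirical'`` detects oscillation peaks — local maxima above the
    signal median, separated by at least half the dominant period estimated
    from the autocorrelation — and returns the mean inter-peak interval.
    """
    if mode == "fixed":
        if fixed_seconds is None or not fixed_seconds > 0:
            raise ValueError("fixed mode requires fixed_seconds > 0")
        return fixed_seconds * ts.sampling_rate
    if mode != "empirical":
        raise ValueError(f"unknown mode {mode!r}")
    period = _dominant_period(ts)
    min_sep = max(1, period // 2)
    peaks, _ = find_peaks(
        ts.values, height=float(np.median(ts.values)), distance=min_sep
    )
    if peaks.size < 3:
        raise ValueError("cannot estimate cycle: fewer than 3 detectable peaks")
    return float(np.mean(np.diff(peaks)))
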