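"""Benchmark signal generators.

Two generators provide the study conditions for the length-assessment
pipeline:

* a chaotic Rossler system with adjustable measurement noise — the
  classical three-variable flow

  .. math::

      \\dot x = -y - z, \\qquad
      \\dot y = x + a y, \\qquad
      \\dot z = b + z (x - c),

  with ``a = b = 0.2, c = 5.7``, integrated with fourth-order Runge-Kutta
  at ``dt = 0.001`` (1000 Hz) and decimated by a factor of 5 (effective
  rate 200 Hz).  Noise imitating measurement noise is then injected into
  every recorded sample, ``x_i <- x_i + theta * A * gamma_i`` with
  ``gamma_i ~ Uniform(-1, 1)`` and ``A`` the half peak-to-peak amplitude
  of the clean ``x`` series, so ``theta`` is a noise-to-signal amplitude
  ratio (0 = clean, 0.5 = noise excursions half the signal's).  Injecting
  noise of this strength into the integrator state instead is numerically
  divergent — the ``z`` equation's exponential spike amplifies sustained
  excursions of ``x`` beyond ``c`` until the state overflows — which is
  why the perturbation is applied to the recorded solution.

* a synthetic photoplethysmogram (PPG): a quasi-periodic pulse train at a
  0.8 s mean cardiac cycle sampled at 409.6 Hz, with beat-to-beat interval
  and amplitude variability, a stereotyped two-component pulse shape
  (systolic wave plus a smaller delayed dicrotic wave), slow baseline
  wander, and additive white measurement noise.  It is a statistical
  stand-in for resting transmission-mode near-infrared PPG recordings: it
  reproduces their quasi-periodicity, variability and noise floor, not
  their physiology.

Plain decimation (sample dropping, no anti-alias filter) emulates
lower-rate acquisition of the same signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .embedding import TimeSeries

__all__ = [
    "RosslerConfig",
    "PPGSimConfig",
    "simulate_rossler",
    "simulate_ppg",
    "decimate",
]


@dataclass(frozen=True)
class RosslerConfig:
    """Rossler integration and noise-injection settings.

    ``theta`` is the noise-to-signal amplitude ratio of the uniform noise
    added to every recorded ``x`` sample; the study range is 0 (clean) to
    0.5.  ``noise_amplitude`` is the absolute amplitude ``A`` the uniform
    draws are scaled by (``theta * A * U(-1, 1)``); by default it is the
    half peak-to-peak amplitude of the clean ``x`` output of the same
    configuration.  ``transient`` pre-decimation steps are discarded to
    shed the initial condition.
    """

    a: float = 0.2
    b: float = 0.2
    c: float = 5.7
    dt: float = 0.001
    subsample: int = 5
    theta: float = 0.0
    n_out: int = 50_000
    seed: int = 0
    transient: int = 10_000
    initial_state: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_amplitude: float | None = None

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.subsample < 1:
            raise ValueError("subsample must be >= 1")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.n_out < 1:
            raise ValueError("n_out must be >= 1")
        if self.transient < 0:
            raise ValueError("transient must be >= 0")

    @property
    def output_rate(self) -> float:
        """Sampling rate of the decimated output (Hz)."""
        return 1.0 / (self.dt * self.subsample)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "a", "b", "c", "dt", "subsample", "theta", "n_out", "seed",
            "transient", "noise_amplitude",
        )}
        d["initial_state"] = list(self.initial_state)
        return d


@njit(cache=True)
def _rossler_rk4(n_steps, dt, a, b, c, x0, y0, z0):
    # pragma: no cover - numba kernel
    out = np.empty(n_steps)
    x, y, z = x0, y0, z0
    for i in range(n_steps):
        # classic RK4 on (x, y, z)
        k1x = -y - z
        k1y = x + a * y
        k1z = b + z * (x - c)

        x2 = x + 0.5 * dt * k1x
        y2 = y + 0.5 * dt * k1y
        z2 = z + 0.5 * dt * k1z
        k2x = -y2 - z2
        k2y = x2 + a * y2
        k2z = b + z2 * (x2 - c)

        x3 = x + 0.5 * dt * k2x
        y3 = y + 0.5 * dt * k2y
        z3 = z + 0.5 * dt * k2z
        k3x = -y3 - z3
        k3y = x3 + a * y3
        k3z = b + z3 * (x3 - c)

        x4 = x + dt * k3x
        y4 = y + dt * k3y
        z4 = z + dt * k3z
        k4x = -y4 - z4
        k4y = x4 + a * y4
        k4z = b + z4 * (x4 - c)

        x = x + dt * (k1x + 2.0 * k2x + 2.0 * k3x + k4x) / 6.0
        y = y + dt * (k1y + 2.0 * k2y + 2.0 * k3y + k4y) / 6.0
        z = z + dt * (k1z + 2.0 * k2z + 2.0 * k3z + k4z) / 6.0

        out[i] = x
        if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
            out[0] = np.nan
            out[1] = float(i)
            return out
    return out


def simulate_rossler(cfg: RosslerConfig = RosslerConfig()) -> TimeSeries:
    """Integrate the Rossler system and return the (noisy) ``x`` series.

    The returned series holds ``n_out`` samples of ``x`` after transient
    removal and decimation by ``cfg.subsample``; its sampling rate is
    ``1 / (dt * subsample)``.  With ``theta > 0``, every recorded sample
    receives an independent uniform perturbation of amplitude
    ``theta * noise_amplitude`` (seeded).  With ``theta = 0`` the output
    is deterministic and independent of the seed.
    """
    n_steps = cfg.transient + cfg.n_out * cfg.subsample
    x0, y0, z0 = cfg.initial_state
    x = _rossler_rk4(n_steps, cfg.dt, cfg.a, cfg.b, cfg.c, x0, y0, z0)
    if np.isnan(x[0]):
        raise FloatingPointError(
            f"Rossler integration blew up at step {int(x[1])}"
        )
    x = x[cfg.transient :: cfg.subsample][: cfg.n_out]
    if cfg.theta > 0:
        amp = cfg.noise_amplitude
        if amp is None:
            amp = float(x.max() - x.min()) / 2.0
        rng = np.random.default_rng(cfg.seed)
        x = x + cfg.theta * amp * rng.uniform(-1.0, 1.0, x.size)
    return TimeSeries(x, cfg.output_rate, label=f"rossler theta={cfg.theta}")


@dataclass(frozen=True)
class PPGSimConfig:
    """Synthetic PPG settings.

    The pulse template is a systolic Gaussian wave plus a smaller, delayed
    dicrotic Gaussian; amplitudes are in arbitrary units with the systolic
    peak normalized to 1.  ``cycle_variability`` and ``amp_variability``
    are coefficients of variation of the beat-to-beat interval and
    amplitude.  ``baseline_wander`` emulates respiratory drift;
    ``noise_sd`` is the white measurement-noise standard deviation.
    """

    sampling_rate: float = 409.6
    duration: float = 300.0
    mean_cycle: float = 0.8
    cycle_variability: float = 0.02
    amp_variability: float = 0.03
    systolic_amp: float = 1.0
    systolic_width: float = 0.09
    systolic_delay: float = 0.18
    dicrotic_amp: float = 0.35
    dicrotic_width: float = 0.12
    dicrotic_delay: float = 0.45
    baseline_amp: float = 0.1
    baseline_freq: float = 0.25
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.sampling_rate > 0 and self.duration > 0 and self.mean_cycle > 0):
            raise ValueError("rates and durations must be positive")
        if self.cycle_variability < 0 or self.amp_variability < 0:
            raise ValueError("variabilities must be >= 0")
        if self.systolic_width <= 0 or self.dicrotic_width <= 0:
            raise ValueError("degenerate morphology: non-positive pulse width")
        if self.noise_sd < 0 or self.baseline_amp < 0:
            raise ValueError("noise and wander amplitudes must be >= 0")

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "sampling_rate", "duration", "mean_cycle", "cycle_variability",
                "amp_variability", "systolic_amp", "systolic_width",
                "systolic_delay", "dicrotic_amp", "dicrotic_width",
                "dicrotic_delay", "baseline_amp", "baseline_freq",
                "noise_sd", "seed",
            )
        }


def simulate_ppg(cfg: PPGSimConfig = PPGSimConfig()) -> TimeSeries:
    """Generate a synthetic quasi-periodic PPG-like recording.

    Beat onsets follow a jittered renewal process around ``mean_cycle``
    (intervals clipped to stay positive); each beat adds a two-Gaussian
    pulse scaled by per-beat amplitude jitter; sinusoidal baseline wander
    and white noise are superimposed.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.sampling_rate))
    t = np.arange(n) / cfg.sampling_rate

    # beat onsets: renewal process, intervals bounded away from zero
    n_beats = int(np.ceil(cfg.duration / cfg.mean_cycle)) + 3
    intervals = rng.normal(cfg.mean_cycle, cfg.cycle_variability * cfg.mean_cycle, n_beats)
    intervals = np.clip(intervals, 0.3 * cfg.mean_cycle, 2.0 * cfg.mean_cycle)
    onsets = np.concatenate(([0.0], np.cumsum(intervals)))
    onsets = onsets[onsets < cfg.duration + cfg.mean_cycle]

    signal = np.zeros(n)
    amps = 1.0 + cfg.amp_variability * rng.standard_normal(onsets.size)
    half_window = cfg.dicrotic_delay + 4 * cfg.dicrotic_width
    for onset, amp in zip(onsets, amps):
        lo = max(0, int((onset - 0.1) * cfg.sampling_rate))
        hi = min(n, int((onset + half_window) * cfg.sampling_rate) + 1)
        if lo >= hi:
            continue
        dt_beat = t[lo:hi] - onset
        pulse = cfg.systolic_amp * np.exp(
            -0.5 * ((dt_beat - cfg.systolic_delay) / cfg.systolic_width) ** 2
        ) + cfg.dicrotic_amp * np.exp(
            -0.5 * ((dt_beat - cfg.dicrotic_delay) / cfg.dicrotic_width) ** 2
        )
        signal[lo:hi] += amp * pulse

    if cfg.baseline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        signal += cfg.baseline_amp * np.sin(2 * np.pi * cfg.baseline_freq * t + phase)
    if cfg.noise_sd > 0:
        signal += cfg.noise_sd * rng.standard_normal(n)
    return TimeSeries(signal, cfg.sampling_rate, label="synthetic ppg")


def decimate(ts: TimeSeries, factor: int) -> TimeSeries:
    """Keep every ``factor``-th sample starting at the first.

    Plain subsampling without anti-alias filtering; the sampling rate is
    divided by ``factor``.
    """
    if int(factor) < 1:
        raise ValueError("factor must be >= 1")
    factor = int(factor)
    if factor == 1:
        return ts
    return TimeSeries(ts.values[::factor], ts.sampling_rate / factor, ts.label)
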