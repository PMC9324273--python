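"""Minimal recording-length assessment for RQA features.

The central question: how long must a recording be before the diagonal-line
RQA features (DET, Lmax, L, ENTR) computed from it stop depending on its
length?  The procedure:

1. Compute reference measures :math:`S_T` once from a long reference
   segment of length ``T`` (ideally more than 100 average cycles of the
   reconstructed trajectory).
2. For each tested length ``l < T``, draw ``n_segments`` random segments
   of the series, compute each feature :math:`S_l` per segment with the
   *same* embedding lag and the *same* absolute recurrence threshold as
   the reference, and average the relative error

   .. math::

       E_l = \\frac{|S_l - S_T|}{S_T} \\times 100\\%.

3. The minimal usable length for a feature at an error budget (e.g. 5% or
   1%) is the smallest tested length whose mean error is at or below the
   budget *and stays below it at every longer tested length* (a stable
   crossing, robust to non-monotone error curves).

Reusing the reference threshold and lag across segments isolates the pure
length effect: per-segment re-estimation would mix in the sampling noise of
the threshold and lag themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embedding import (
    EmbeddingSpec,
    TimeSeries,
    delay_embed,
    estimate_delay,
)
from .recurrence import RecurrenceSpec, diagonal_histogram
from .rqa import RQAConfig, RQAMeasures, compute_measures

__all__ = [
    "MEASURE_NAMES",
    "ScanConfig",
    "ErrorCurve",
    "relative_error",
    "scan",
    "lower_limit",
]

MEASURE_NAMES = ("DET", "Lmax", "L", "ENTR")

_FIELD_BY_MEASURE = {
    "DET": "det",
    "Lmax": "lmax",
    "L": "mean_line",
    "ENTR": "entr",
}


def relative_error(s_l: float, s_t: float) -> float:
    """Relative error ``|s_l - s_t| / s_t * 100`` in percent.

    The reference ``s_t`` must be defined and non-zero.
    """
    if s_t is None or s_l is None:
        raise ValueError("reference undefined: cannot compute relative error")
    if s_t == 0:
        raise ValueError("reference undefined: reference value is zero")
    return abs(s_l - s_t) / abs(s_t) * 100.0


@dataclass(frozen=True)
class ScanConfig:
    """Length-scan protocol.

    ``lengths`` is the strictly increasing grid of tested segment lengths
    (points), each at most the reference length ``reference_length``
    (``None``: the full series).  ``n_segments`` random segments are drawn
    per length (seeded).  ``cycle_length`` (samples per average cycle) is
    used to express lengths in cycles; recordings shorter than about
    3 average cycles cannot hold a separated cycle fragment, so grids
    reaching below that floor trigger a warning.
    """

    lengths: tuple[int, ...]
    n_segments: int = 100
    seed: int = 0
    reference_length: int | None = None
    error_thresholds: tuple[float, ...] = (5.0, 1.0)
    cycle_length: float | None = None

    def __post_init__(self) -> None:
        lengths = tuple(int(l) for l in self.lengths)
        object.__setattr__(self, "lengths", lengths)
        if len(lengths) == 0:
            raise ValueError("lengths must be non-empty")
        if any(b <= a for a, b in zip(lengths, lengths[1:])):
            raise ValueError("lengths must be strictly increasing")
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.reference_length is not None and lengths[-1] > self.reference_length:
            raise ValueError("tested lengths must not exceed the reference length")
        if self.cycle_length is not None and lengths[0] < 3 * self.cycle_length:
            warnings.warn(
                f"smallest tested length {lengths[0]} is below 3 average cycles "
                f"({3 * self.cycle_length:.0f} samples); line statistics may be "
                "dominated by too few trajectory loops",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ErrorCurve:
    """Mean relative error per feature and tested length, plus provenance.

    ``errors[measure]`` is an ``(n_lengths, n_segments)`` array of
    per-segment relative errors (NaN where the segment's measure was
    undefined); ``mean_errors[measure]`` averages over the defined
    segments.
    """

    lengths: np.ndarray
    errors: dict[str, np.ndarray]
    reference: RQAMeasures
    reference_length: int
    cycle_length: float | None
    metadata: dict = field(default_factory=dict)

    @property
    def mean_errors(self) -> dict[str, np.ndarray]:
        out = {}
        for name, err in self.errors.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[name] = np.nanmean(err, axis=1)
        return out

    @property
    def n_defined(self) -> dict[str, np.ndarray]:
        return {
            name: np.sum(~np.isnan(err), axis=1) for name, err in self.errors.items()
        }

    def in_cycles(self, length_points: float) -> float | None:
        if self.cycle_length is None:
            return None
        return length_points / self.cycle_length

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: measure, length_points, length_cycles,
        mean_error_pct, n_defined."""
        rows = []
        means = self.mean_errors
        ndef = self.n_defined
        for name in self.errors:
            for i, length in enumerate(self.lengths):
                rows.append(
                    {
                        "measure": name,
                        "length_points": int(length),
                        "length_cycles": self.in_cycles(length),
                        "mean_error_pct": means[name][i],
                        "n_defined": int(ndef[name][i]),
                    }
                )
        return pd.DataFrame(rows)

    def lower_limits_table(
        self, thresholds: tuple[float, ...] = (5.0, 1.0)
    ) -> pd.DataFrame:
        """Minimal qualifying length per measure and threshold."""
        rows = []
        for name in self.errors:
            for thr in thresholds:
                try:
                    pts, cyc = lower_limit(self, name, thr)
                except ValueError:
                    pts, cyc = None, None
                rows.append(
                    {
                        "measure": name,
                        "threshold_pct": thr,
                        "length_points": pts,
                        "length_cycles": cyc,
                    }
                )
        return pd.DataFrame(rows)


def _segment_measures(
    ts: TimeSeries,
    start: int,
    length: int,
    emb: EmbeddingSpec,
    rec: RecurrenceSpec,
    rqa_cfg: RQAConfig,
) -> RQAMeasures:
    seg = ts.segment(start, length)
    traj = delay_embed(seg, emb)
    hist = diagonal_histogram(traj, rec)
    return compute_measures(hist, rqa_cfg)


def scan(
    ts: TimeSeries,
    emb: EmbeddingSpec | None,
    rec_spec: RecurrenceSpec | None,
    rqa_cfg: RQAConfig,
    cfg: ScanConfig,
    *,
    dimension: int = 3,
    epsilon_fraction: float = 0.1,
    theiler: int = 1,
    norm: str = "euclidean",
) -> ErrorCurve:
    """Run the full length scan on one series.

    If ``emb`` is ``None`` the lag is estimated once from the full series
    (autocorrelation 1/e rule) with the given ``dimension``.  If
    ``rec_spec`` is ``None`` the recurrence threshold is resolved once
    from the reference trajectory (``epsilon_fraction`` of its diameter)
    and reused, unchanged, for every segment.
    """
    n = len(ts)
    ref_len = cfg.reference_length if cfg.reference_length is not None else n
    if n < ref_len:
        raise ValueError(f"series length {n} is below reference length {ref_len}")
    if cfg.cycle_length is not None and ref_len < 100 * cfg.cycle_length:
        warnings.warn(
            f"reference length {ref_len} is below 100 average cycles; "
            "reference measures may not be converged",
            stacklevel=2,
        )

    if emb is None:
        emb = EmbeddingSpec(dimension, estimate_delay(ts))
    ref_traj = delay_embed(ts.segment(0, ref_len), emb)
    if rec_spec is None:
        rec_spec = RecurrenceSpec.from_trajectory(
            ref_traj, epsilon_fraction, theiler, norm
        )
    reference = compute_measures(diagonal_histogram(ref_traj, rec_spec), rqa_cfg)
    ref_values = {
        name: getattr(reference, attr) for name, attr in _FIELD_BY_MEASURE.items()
    }
    for name, val in ref_values.items():
        if val is None or val == 0:
            raise ValueError(f"reference measure {name} undefined or zero")

    rng = np.random.default_rng(cfg.seed)
    n_lengths = len(cfg.lengths)
    errors = {
        name: np.full((n_lengths, cfg.n_segments), np.nan) for name in MEASURE_NAMES
    }
    flagged: list[int] = []
    for i, length in enumerate(cfg.lengths):
        n_starts = n - length + 1
        k = min(cfg.n_segments, n_starts)
        starts = rng.choice(n_starts, size=k, replace=False)
        any_defined = False
        for j, start in enumerate(starts):
            meas = _segment_measures(ts, int(start), length, emb, rec_spec, rqa_cfg)
            for name, attr in _FIELD_BY_MEASURE.items():
                val = getattr(meas, attr)
                if val is not None:
                    errors[name][i, j] = relative_error(val, ref_values[name])
                    any_defined = True
        if not any_defined:
            flagged.append(int(length))

    return ErrorCurve(
        lengths=np.asarray(cfg.lengths, dtype=np.int64),
        errors=errors,
        reference=reference,
        reference_length=ref_len,
        cycle_length=cfg.cycle_length,
        metadata={
            "embedding": {"dimension": emb.dimension, "lag": emb.lag},
            "recurrence": rec_spec.to_dict(),
            "lmin": rqa_cfg.lmin,
            "seed": cfg.seed,
            "n_segments": cfg.n_segments,
            "segments_may_overlap": True,
            "reference_segment_drawable": True,
            "all_undefined_lengths": flagged,
        },
    )


def lower_limit(
    curve: ErrorCurve, measure: str, threshold: float
) -> tuple[int, float | None]:
    """Smallest tested length whose mean error is <= ``threshold`` (%) and
    stays at or below it for every longer tested length.

    Returns ``(length_points, length_cycles)``; cycles is ``None`` when no
    cycle length is attached to the curve.
    """
    if measure not in curve.errors:
        raise ValueError(f"unknown measure {measure!r}")
    means = curve.mean_errors[measure]
    ok = np.asarray(means) <= threshold
    # stable crossing: all longer tested lengths also qualify
    stable = np.logical_and.accumulate(ok[::-1])[::-1]
    idx = np.flatnonzero(stable)
    if idx.size == 0:
        raise ValueError(
            f"{measure} at {threshold}%: not attainable within tested range"
        )
    length = int(curve.lengths[idx[0]])
    return length, curve.in_cycles(length)
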