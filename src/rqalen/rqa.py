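"""Diagonal-line RQA measures: DET, Lmax, L, ENTR.

All four features are functionals of the diagonal-line histogram
:math:`P(\\varepsilon, l)`:

* determinism
  :math:`DET = \\sum_{l \\ge l_{min}} l P(l) \\; / \\; \\sum_{l \\ge 1} l P(l)`
  — the fraction of recurrent points lying on diagonal lines of length at
  least :math:`l_{min}` (the denominator deliberately includes isolated
  recurrent points, i.e. lines of length 1);
* maximal line length :math:`L_{max} = \\max\\{l : P(l) > 0,\\ l \\ge l_{min}\\}`,
  whose inverse is a proxy for trajectory divergence;
* average line length
  :math:`L = \\sum_{l \\ge l_{min}} l P(l) \\; / \\; \\sum_{l \\ge l_{min}} P(l)`,
  a proxy for mean prediction time;
* entropy :math:`ENTR = -\\sum_l p(l) \\ln p(l)` (nats) of the line-length
  distribution :math:`p(l) = P(l) / N_l` restricted to
  :math:`l \\ge l_{min}`, with :math:`N_l` the number of qualifying lines.

Measures that are undefined on a given histogram (no recurrent points, or
no line reaching ``lmin``) are reported as ``None`` with a reason — never
as 0, since 0 is a meaningful value for ENTR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .recurrence import DiagonalHistogram

__all__ = [
    "RQAConfig",
    "RQAMeasures",
    "determinism",
    "max_line",
    "mean_line",
    "entropy",
    "compute_measures",
]

#: Conventional determinism criterion: DET above this marks a signal
#: as deterministic.
DETERMINISM_THRESHOLD = 0.9


@dataclass(frozen=True)
class RQAConfig:
    """Minimum diagonal line length ``lmin`` (>= 2)."""

    lmin: int = 2

    def __post_init__(self) -> None:
        if int(self.lmin) < 2:
            raise ValueError("lmin must be >= 2")
        object.__setattr__(self, "lmin", int(self.lmin))


@dataclass(frozen=True)
class RQAMeasures:
    """The four diagonal-line features plus bookkeeping.

    ``None`` fields are undefined on the source histogram; ``reasons``
    records why.
    """

    det: float | None
    lmax: int | None
    mean_line: float | None
    entr: float | None
    n_lines: int
    lmin: int
    n_points: int
    reasons: tuple[str, ...] = ()

    @property
    def inv_lmax(self) -> float | None:
        """Divergence proxy 1 / Lmax."""
        return None if self.lmax is None else 1.0 / self.lmax

    def is_deterministic(self, threshold: float = DETERMINISM_THRESHOLD) -> bool | None:
        """Conventional classification: DET above ``threshold`` (default
        0.9) is taken as a sign of determinism.  ``None`` if DET is
        undefined."""
        return None if self.det is None else bool(self.det > threshold)

    def as_record(self) -> dict:
        rec = asdict(self)
        rec["inv_lmax"] = self.inv_lmax
        rec["reasons"] = list(self.reasons)
        return rec

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        rec = self.as_record()
        if extra:
            rec.update(extra)
        Path(path).write_text(json.dumps(rec, indent=2) + "\n")

    def to_csv(self, path: str | Path, extra: dict | None = None) -> None:
        """One-row CSV with the flat measure record."""
        rec = self.as_record()
        rec.pop("reasons")
        if extra:
            rec.update(extra)
        cols = list(rec)
        with open(path, "w") as fh:
            fh.write(",".join(cols) + "\n")
            fh.write(",".join("" if rec[c] is None else str(rec[c]) for c in cols) + "\n")


def _sums(hist: DiagonalHistogram, lmin: int) -> tuple[int, int, int]:
    """(sum_{l>=1} l P(l), sum_{l>=lmin} l P(l), N_l)."""
    counts = hist.counts
    lengths = np.arange(counts.size, dtype=np.int64)
    total = int(np.dot(lengths, counts))
    qual = int(np.dot(lengths[lmin:], counts[lmin:]))
    n_lines = int(counts[lmin:].sum())
    return total, qual, n_lines


def determinism(hist: DiagonalHistogram, cfg: RQAConfig = RQAConfig()) -> float:
    """Fraction of recurrent points on diagonal lines of length >= lmin."""
    total, qual, _ = _sums(hist, cfg.lmin)
    if total == 0:
        raise ValueError("undefined: histogram has no recurrent points")
    return qual / total


def max_line(hist: DiagonalHistogram, cfg: RQAConfig = RQAConfig()) -> int:
    """Largest line length with a positive count and l >= lmin."""
    nz = np.flatnonzero(hist.counts[cfg.lmin :])
    if nz.size == 0:
        raise ValueError("undefined: no diagonal line reaches lmin")
    return int(nz[-1] + cfg.lmin)


def mean_line(hist: DiagonalHistogram, cfg: RQAConfig = RQAConfig()) -> float:
    """Length-weighted mean of diagonal lines with l >= lmin."""
    _, qual, n_lines = _sums(hist, cfg.lmin)
    if n_lines == 0:
        raise ValueError("undefined: no diagonal line reaches lmin")
    return qual / n_lines


def entropy(hist: DiagonalHistogram, cfg: RQAConfig = RQAConfig()) -> float:
    """Shannon entropy (nats) of the line-length distribution for
    l >= lmin; exactly 0 when a single distinct length is present."""
    counts = hist.counts[cfg.lmin :]
    n_lines = counts.sum()
    if n_lines == 0:
        raise ValueError("undefined: no diagonal line reaches lmin")
    p = counts[counts > 0] / n_lines
    return float(-np.sum(p * np.log(p)))


def compute_measures(hist: DiagonalHistogram, cfg: RQAConfig = RQAConfig()) -> RQAMeasures:
    """All four measures from one histogram, with undefined ones as None."""
    total, qual, n_lines = _sums(hist, cfg.lmin)
    reasons: list[str] = []
    det = lmax = mline = entr = None
    if total == 0:
        reasons.append("det undefined: histogram has no recurrent points")
    else:
        det = qual / total
    if n_lines == 0:
        reasons.append("lmax/mean_line/entr undefined: no line reaches lmin")
    else:
        lmax = max_line(hist, cfg)
        mline = qual / n_lines
        entr = entropy(hist, cfg)
    return RQAMeasures(
        det=det,
        lmax=lmax,
        mean_line=mline,
        entr=entr,
        n_lines=n_lines,
        lmin=cfg.lmin,
        n_points=hist.n_points,
        reasons=tuple(reasons),
    )
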