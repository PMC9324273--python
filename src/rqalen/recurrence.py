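"""Recurrence plots and diagonal-line histograms.

The recurrence matrix of an embedded trajectory marks every pair of points
closer than a threshold:

.. math::

    R_{i,j}(\\varepsilon) = \\begin{cases}
        1 & \\text{if } \\lVert X_i - X_j \\rVert < \\varepsilon \\\\
        0 & \\text{otherwise.}
    \\end{cases}

The threshold is conventionally a fixed fraction (10%) of the attractor
diameter.  The statistics used downstream depend only on the histogram
``P(l)`` of maximal diagonal runs of recurrent cells, so for long
trajectories the histogram is accumulated diagonal by diagonal without ever
materializing the N x N matrix; the explicit matrix is kept only as a
small-N verification oracle.

A Theiler window excludes diagonals within ``theiler`` offsets of the line
of identity (``i = j``), whose trivial self-recurrences would otherwise
dominate every line statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from .embedding import EmbeddedTrajectory, attractor_diameter

__all__ = [
    "RecurrenceSpec",
    "RecurrenceMatrix",
    "DiagonalHistogram",
    "recurrence_matrix",
    "diagonal_histogram",
    "histogram_from_matrix",
]

#: recurrence_matrix is a verification oracle; larger N must stream.
MAX_MATRIX_POINTS = 5_000


@dataclass(frozen=True)
class RecurrenceSpec:
    """Recurrence-plot parameters.

    ``epsilon_fraction`` is the threshold as a fraction of the attractor
    diameter; ``epsilon_absolute`` is the resolved threshold in signal
    units.  ``theiler`` is the half-width of the excluded band around the
    line of identity (default 1: the LOI itself is excluded).  Points at
    distance exactly ``epsilon_absolute`` are non-recurrent (strict ``<``).
    """

    epsilon_fraction: float
    epsilon_absolute: float
    theiler: int = 1
    norm: str = "euclidean"

    def __post_init__(self) -> None:
        if not 0 < self.epsilon_fraction <= 1:
            raise ValueError("epsilon_fraction must be in (0, 1]")
        if not self.epsilon_absolute > 0:
            raise ValueError("epsilon_absolute must be positive")
        if self.theiler < 0:
            raise ValueError("theiler must be >= 0")
        if self.norm not in ("euclidean", "chebyshev"):
            raise ValueError(f"unknown norm {self.norm!r}")

    @classmethod
    def from_trajectory(
        cls,
        traj: EmbeddedTrajectory,
        epsilon_fraction: float = 0.1,
        theiler: int = 1,
        norm: str = "euclidean",
    ) -> "RecurrenceSpec":
        """Resolve the absolute threshold from the trajectory's diameter."""
        diameter = attractor_diameter(traj, norm=norm)
        if diameter == 0:
            raise ValueError("degenerate trajectory: zero diameter")
        return cls(epsilon_fraction, epsilon_fraction * diameter, theiler, norm)

    def to_dict(self) -> dict:
        return {
            "epsilon_fraction": self.epsilon_fraction,
            "epsilon_absolute": self.epsilon_absolute,
            "theiler": self.theiler,
            "norm": self.norm,
        }


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Explicit binary recurrence matrix (small-N oracle).

    The Theiler exclusion is *not* applied here; consumers apply it when
    extracting line statistics.
    """

    matrix: np.ndarray
    spec: RecurrenceSpec

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("recurrence matrix must be square")


@dataclass(frozen=True)
class DiagonalHistogram:
    """Histogram ``P(l)`` of maximal diagonal line lengths.

    ``counts[l]`` is the number of maximal runs of length ``l`` of
    consecutive recurrent cells along diagonals with offset
    ``|i - j| >= theiler``, counted over both triangles of the matrix.
    """

    counts: np.ndarray
    n_points: int
    spec: RecurrenceSpec

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")

    def as_dict(self) -> dict[int, int]:
        """Sparse ``{length: count}`` view of the non-zero bins."""
        lengths = np.flatnonzero(self.counts)
        return {int(l): int(self.counts[l]) for l in lengths if l > 0}

    @property
    def total_recurrent_points(self) -> int:
        """Number of recurrent cells outside the Theiler band:
        conservation gives ``sum_l l * P(l)``."""
        lengths = np.arange(self.counts.size, dtype=np.int64)
        return int(np.dot(lengths, self.counts))

    def to_csv(self, path: str | Path) -> None:
        """Two-column CSV (length, count) with a JSON sidecar holding the
        recurrence parameters."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("length,count\n")
            for l, c in sorted(self.as_dict().items()):
                fh.write(f"{l},{c}\n")
        sidecar = {"n_points": self.n_points, **self.spec.to_dict()}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2) + "\n"
        )


def recurrence_matrix(
    traj: EmbeddedTrajectory, spec: RecurrenceSpec
) -> RecurrenceMatrix:
    """Explicit recurrence matrix by full pairwise thresholding.

    Intended as a verification oracle for small trajectories; trajectories
    above ``MAX_MATRIX_POINTS`` points must use :func:`diagonal_histogram`.
    """
    n = len(traj)
    if n < 2:
        raise ValueError("need at least two points")
    if n > MAX_MATRIX_POINTS:
        raise ValueError(
            f"use streaming histogram: N={n} exceeds matrix cap {MAX_MATRIX_POINTS}"
        )
    metric = "euclidean" if spec.norm == "euclidean" else "chebyshev"
    dist = cdist(traj.points, traj.points, metric=metric)
    return RecurrenceMatrix(dist < spec.epsilon_absolute, spec)


@njit(cache=True)
def _diagonal_line_counts_euclidean(points, eps, start_offset, counts):
    # pragma: no cover - numba kernel
    n, m = points.shape
    eps2 = eps * eps
    for offset in range(start_offset, n):
        run = 0
        for j in range(n - offset):
            d = 0.0
            for k in range(m):
                diff = points[j, k] - points[j + offset, k]
                d += diff * diff
            if d < eps2:
                run += 1
            else:
                if run > 0:
                    counts[run] += 2
                run = 0
        if run > 0:
            counts[run] += 2


@njit(cache=True)
def _diagonal_line_counts_chebyshev(points, eps, start_offset, counts):
    # pragma: no cover - numba kernel
    n, m = points.shape
    for offset in range(start_offset, n):
        run = 0
        for j in range(n - offset):
            d = 0.0
            for k in range(m):
                diff = abs(points[j, k] - points[j + offset, k])
                if diff > d:
                    d = diff
            if d < eps:
                run += 1
            else:
                if run > 0:
                    counts[run] += 2
                run = 0
        if run > 0:
            counts[run] += 2


def diagonal_histogram(
    traj: EmbeddedTrajectory, spec: RecurrenceSpec
) -> DiagonalHistogram:
    """Streaming histogram of maximal diagonal recurrence lines.

    Diagonals with offset ``|i - j| < theiler`` are excluded (default
    ``theiler = 1`` removes exactly the line of identity).  Proceeds
    diagonal by diagonal, computing distances on the fly and run-length
    encoding the recurrent cells, so memory stays O(N).  Runs touching the
    matrix border are delimited as if out-of-range cells were non-recurrent.
    The upper triangle is counted and doubled (the lower triangle mirrors
    it); with ``theiler = 0`` the line of identity — always one run of
    length N — is added once, so that conservation
    ``sum_l l P(l) = #recurrent cells outside the Theiler band`` holds for
    every ``theiler``.
    """
    n = len(traj)
    if n < 2:
        raise ValueError("need at least two points")
    counts = np.zeros(n + 1, dtype=np.int64)
    if spec.theiler < n:
        start_offset = max(spec.theiler, 1)
        if spec.norm == "euclidean":
            _diagonal_line_counts_euclidean(
                traj.points, spec.epsilon_absolute, start_offset, counts
            )
        else:
            _diagonal_line_counts_chebyshev(
                traj.points, spec.epsilon_absolute, start_offset, counts
            )
        if spec.theiler == 0:
            counts[n] += 1
    return DiagonalHistogram(counts, n, spec)


def histogram_from_matrix(rm: RecurrenceMatrix, theiler: int | None = None) -> DiagonalHistogram:
    """Run-length encode the diagonals of an explicit recurrence matrix.

    Independent of the streaming path; used as its verification oracle.
    """
    theiler = rm.spec.theiler if theiler is None else theiler
    n = rm.matrix.shape[0]
    counts = np.zeros(n + 1, dtype=np.int64)

    def _runs(diag: np.ndarray) -> np.ndarray:
        padded = np.concatenate(([False], diag, [False])).astype(np.int8)
        edges = np.diff(padded)
        return np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)

    for offset in range(max(theiler, 1), n):
        for diag in (np.diagonal(rm.matrix, offset), np.diagonal(rm.matrix, -offset)):
            for length in _runs(diag):
                counts[length] += 1
    if theiler == 0:
        for length in _runs(np.diagonal(rm.matrix, 0)):
            counts[length] += 1
    spec = RecurrenceSpec(
        rm.spec.epsilon_fraction, rm.spec.epsilon_absolute, theiler, rm.spec.norm
    )
    return DiagonalHistogram(counts, n, spec)


def plot_recurrence_matrix(rm: RecurrenceMatrix, ax=None):
    """Small-N debug plot of an explicit recurrence matrix."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(rm.matrix, origin="lower", cmap="binary", interpolation="none")
    ax.set_xlabel("j")
    ax.set_ylabel("i")
    return ax
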