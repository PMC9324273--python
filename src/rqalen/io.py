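"""Reading and writing one-column series files and run metadata.

The series format is deliberately minimal: one sample value per line,
optionally preceded by comment lines starting with ``#``.  A header line
``# rate=<Hz>`` carries the sampling rate; a rate passed by the caller
overrides the header.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .embedding import TimeSeries

__all__ = ["read_series", "write_series"]

_RATE_RE = re.compile(r"#\s*rate\s*=\s*([0-9.eE+-]+)")


def read_series(
    path: str | Path, rate: float | None = None, label: str | None = None
) -> TimeSeries:
    """Read a one-column text/CSV series file.

    ``rate`` overrides any ``# rate=<Hz>`` header; if neither is present
    the file cannot be interpreted and an error is raised.  Non-numeric
    rows are reported with their line number.
    """
    path = Path(path)
    header_rate: float | None = None
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _RATE_RE.match(line)
                if m:
                    header_rate = float(m.group(1))
                continue
            # tolerate a trailing comma from single-column CSV exports
            token = line.rstrip(",")
            try:
                values.append(float(token))
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value {line!r}"
                ) from None
    resolved = rate if rate is not None else header_rate
    if resolved is None:
        raise ValueError(
            f"{path}: no sampling rate (no '# rate=' header and no override)"
        )
    return TimeSeries(
        np.asarray(values), resolved, label if label is not None else path.stem
    )


def write_series(
    ts: TimeSeries, path: str | Path, sidecar: dict | None = None
) -> None:
    """Write a series with a ``# rate=`` header; optionally a JSON sidecar
    (``<path>.json``) holding generator config and seed for provenance."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# rate={float(ts.sampling_rate)!r}\n")
        if ts.label:
            fh.write(f"# label={ts.label}\n")
        for v in ts.values:
            fh.write(f"{float(v)!r}\n")
    if sidecar is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2) + "\n"
        )
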