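"""Reading and writing angle CSV files.

Format: one angle per line, optional single header line, comment lines
starting with '#'.  Degrees by default (the unit biologists report bearings
in); radians on request.
"""
from __future__ import annotations

import os

import numpy as np

from .core import CircularDataError, CircularSample

__all__ = ["read_angles", "write_angles"]


def read_angles(path, unit: str = "degrees", label: str | None = None) -> CircularSample:
    """Read a one-column angle CSV into a CircularSample.

    Blank lines and lines starting with '#' are skipped; a single
    non-numeric first line is treated as a header.
    """
    values = []
    first_data_line = True
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            token = line.split(",")[0].strip()
            try:
                values.append(float(token))
            except ValueError:
                if first_data_line:
                    first_data_line = False
                    continue  # header
                raise CircularDataError(f"unparseable angle {token!r} in {path}") from None
            first_data_line = False
    if not values:
        raise CircularDataError(f"no angles found in {path}")
    if label is None:
        label = os.path.splitext(os.path.basename(str(path)))[0]
    return CircularSample(values, unit=unit, label=label)


def write_angles(path, sample, unit: str = "degrees", header: bool = True, comment: str | None = None):
    """Write angles to a one-column CSV (degrees by default)."""
    if isinstance(sample, CircularSample):
        angles = sample.angles
    else:
        angles = np.asarray(sample, dtype=float)
    out = np.rad2deg(angles) if unit == "degrees" else angles
    with open(path, "w", encoding="utf-8") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        if header:
            fh.write(f"angle_{unit}\n")
        for v in out:
            fh.write(f"{v:.12g}\n")
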