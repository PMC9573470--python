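"""Reading and writing I/Q slow-time records as delimited text.

Format: comma-separated columns ``time_s,i,q`` with a one-line header.
Values are written with 12 significant digits so a round trip preserves
them to that precision. Only 1-D (slow-time-only) records are supported;
matrix records have no canonical flat text layout.
"""

from __future__ import annotations

import os

import numpy as np

from .simulate import BasebandSignal

__all__ = ["write_iq", "read_iq"]

_HEADER = "time_s,i,q"


def write_iq(signal: BasebandSignal, path: str | os.PathLike) -> None:
    """Write a 1-D baseband record to delimited text."""
    if signal.samples.ndim != 1:
        raise ValueError("only slow-time-only (1-D) records can be written as I/Q text")
    table = np.column_stack(
        [signal.times, signal.samples.real, signal.samples.imag]
    )
    np.savetxt(path, table, fmt="%.11e", delimiter=",", header=_HEADER, comments="")


def read_iq(path: str | os.PathLike, sample_rate: float | None = None) -> BasebandSignal:
    """Read an I/Q text record; sample rate is inferred from the time
    column unless given explicitly."""
    table = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if table.shape[1] != 3:
        raise ValueError("expected three columns: time_s,i,q")
    t, i, q = table.T
    if sample_rate is None:
        if len(t) < 2:
            raise ValueError("cannot infer sample rate from fewer than 2 samples")
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise ValueError("time column must be strictly increasing")
        sample_rate = 1.0 / dt
    return BasebandSignal(samples=i + 1j * q, sample_rate=sample_rate, source="loaded")
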