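"""Core time-series container for luminescence recordings.

A trace is a strictly increasing time grid in hours plus a signal in
counts/s and free-form provenance metadata (well id, cell line, reporter,
perturbation). Every analysis stage consumes and returns this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .errors import FormatError


@dataclass
class TimeSeriesTrace:
    """One luminescence recording.

    Parameters
    ----------
    t : ndarray
        Time grid in hours, strictly increasing, ``t[0] >= 0``.
    y : ndarray
        Signal in counts/s, same length as ``t``.
    meta : dict
        Free-form key/value provenance (``well``, ``cell_line``,
        ``reporter``, ``perturbation``, ...).
    """

    t: np.ndarray
    y: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.y.ndim != 1:
            raise FormatError("trace t and y must be one-dimensional")
        if len(self.t) != len(self.y):
            raise FormatError(
                f"t and y lengths differ: {len(self.t)} vs {len(self.y)}"
            )
        if len(self.t) < 2:
            raise FormatError("a trace needs at least two samples")
        if self.t[0] < 0:
            raise FormatError("time grid must start at t >= 0 h")
        if not np.all(np.diff(self.t) > 0):
            raise FormatError("time grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Span of the recording in hours."""
        return float(self.t[-1] - self.t[0])

    @property
    def dt(self) -> float:
        """Median sampling interval in hours."""
        return float(np.median(np.diff(self.t)))

    def window(self, t_start: float, t_end: float) -> "TimeSeriesTrace":
        """Restrict to ``t_start <= t < t_end`` (hours, absolute)."""
        mask = (self.t >= t_start) & (self.t < t_end)
        if mask.sum() < 2:
            raise FormatError(
                f"window [{t_start}, {t_end}) h retains fewer than 2 samples"
            )
        return TimeSeriesTrace(self.t[mask], self.y[mask], dict(self.meta))

    def copy_with(self, y: np.ndarray) -> "TimeSeriesTrace":
        """Same grid and metadata, new signal."""
        return TimeSeriesTrace(self.t.copy(), np.asarray(y, float), dict(self.meta))
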