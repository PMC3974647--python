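"""Detrending and windowing ahead of rhythm fitting.

The analysis convention is: drop the first recorded cycle (distorted by the
medium-change transient), optionally restrict to an analysis window, then
subtract an ordinary-least-squares polynomial baseline (order 1 by
default). Time is kept in absolute hours throughout — the grid is never
re-zeroed — so that calendar-day windows such as the day-3-to-5 amplitude
window remain meaningful after exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, InvalidParameterError
from .trace import TimeSeriesTrace

__all__ = ["DetrendConfig", "exclude_initial", "fit_baseline", "detrend",
           "amplitude_window"]

AMPLITUDE_WINDOW = (48.0, 120.0)   # day 3 through day 5, days 1-indexed


@dataclass(frozen=True)
class DetrendConfig:
    """Detrending configuration.

    ``exclude_initial_h`` defaults to 24 h ("first cycle"); ``poly_order``
    is the baseline polynomial order (1 = linear, the standard protocol);
    ``window`` optionally restricts the analysis to absolute hours
    ``[t_start, t_end)`` after exclusion and before baseline fitting.
    """

    exclude_initial_h: float = 24.0
    poly_order: int = 1
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.exclude_initial_h < 0:
            raise InvalidParameterError("exclude_initial_h must be >= 0")
        if self.poly_order not in (0, 1, 2, 3):
            raise InvalidParameterError(
                f"poly_order must be in {{0,1,2,3}}, got {self.poly_order}")
        if self.window is not None and self.window[0] >= self.window[1]:
            raise InvalidParameterError("window must be ordered (start < end)")


def exclude_initial(trace: TimeSeriesTrace, hours: float) -> TimeSeriesTrace:
    """Drop all samples with ``t < hours``; absolute time is preserved."""
    if hours < 0:
        raise InvalidParameterError("exclusion span must be >= 0 h")
    if hours == 0:
        return trace
    mask = trace.t >= hours
    if mask.sum() < max(2, 0.2 * len(trace)):
        raise InsufficientDataError(
            f"excluding the first {hours} h would consume >= 80% of a "
            f"{trace.duration:.1f} h trace")
    return TimeSeriesTrace(trace.t[mask], trace.y[mask], dict(trace.meta))


def fit_baseline(trace: TimeSeriesTrace, poly_order: int = 1) -> np.ndarray:
    """OLS polynomial baseline coefficients, lowest order first.

    Returns ``c`` such that baseline(t) = sum_k c[k] * t**k.
    """
    if len(trace) <= poly_order + 1:
        raise InsufficientDataError(
            f"{len(trace)} samples cannot constrain an order-{poly_order} "
            "baseline")
    # polyfit is OLS on the Vandermonde design; highest order first
    coeffs = np.polyfit(trace.t, trace.y, deg=poly_order)
    if not np.all(np.isfinite(coeffs)):
        raise np.linalg.LinAlgError(
            "baseline fit produced non-finite coefficients "
            f"(order {poly_order}, n={len(trace)})")
    return coeffs[::-1]


def evaluate_baseline(coeffs: np.ndarray, t: np.ndarray) -> np.ndarray:
    return np.polyval(np.asarray(coeffs)[::-1], t)


def detrend(trace: TimeSeriesTrace, config: DetrendConfig = DetrendConfig(),
            ) -> TimeSeriesTrace:
    """Exclusion -> optional window -> baseline subtraction, in that order.

    The baseline is fitted on the analysis window only, mirroring the
    day-3-to-5 amplitude protocol.
    """
    out = exclude_initial(trace, config.exclude_initial_h)
    if config.window is not None:
        out = out.window(*config.window)
    coeffs = fit_baseline(out, config.poly_order)
    return out.copy_with(out.y - evaluate_baseline(coeffs, out.t))


def amplitude_window(trace: TimeSeriesTrace,
                     min_periods: float = 1.5,
                     nominal_period: float = 24.0) -> TimeSeriesTrace:
    """Day-3-to-5 amplitude protocol: restrict to t in [48, 120) h and
    linearly detrend within the window.

    Day counting is 1-indexed from recording start, so "day 3 to day 5" is
    the half-open span [48 h, 120 h). The window must cover at least
    ``min_periods`` nominal periods.
    """
    t0, t1 = AMPLITUDE_WINDOW
    covered = (min(trace.t[-1], t1) - max(trace.t[0], t0))
    if covered < min_periods * nominal_period:
        raise InsufficientDataError(
            f"trace covers only {max(covered, 0.0):.1f} h of the "
            f"[{t0:.0f}, {t1:.0f}) h amplitude window "
            f"(need >= {min_periods * nominal_period:.0f} h)")
    win = trace.window(t0, t1)
    coeffs = fit_baseline(win, poly_order=1)
    return win.copy_with(win.y - evaluate_baseline(coeffs, win.t))
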