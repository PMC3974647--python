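"""Damped-sinusoid rhythm fitting.

The model fitted to a detrended trace is

    y(t) = c0 + c1*t + A * exp(-(t - t_ref)/(24*tau)) * cos(2*pi*(t - phi)/T)

with the period ``T`` bounded to the circadian band, ``phi`` the peak time
in hours (reported modulo ``T``), ``A`` the amplitude referenced to the
start of the fitted window ``t_ref``, and ``tau`` the damping constant in
days (damping rate = 1/tau per day). The residual linear term (c0, c1)
absorbs imperfect detrending and is dropped when the input is declared
pre-detrended.

Goodness of fit is percent variance explained, 100*(1 - RSS/TSS), and a
trace is called rhythmic when GOF exceeds the configured threshold
(80% by default — the conventional cutoff for persistent reporter rhythms).

The optimisation is deterministic: a Lomb-Scargle periodogram proposes up
to three candidate periods, each combined with four phase offsets
(0, T/4, T/2, 3T/4 around the initial peak estimate), every start is
refined by bounded least squares, and the best residual sum of squares
wins, with ties broken by smaller |c1| then smaller damping rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize, signal

from . import preprocess
from .errors import InsufficientDataError, InvalidParameterError, NoSignalError
from .preprocess import DetrendConfig
from .trace import TimeSeriesTrace

__all__ = ["FitConfig", "DampedSineFit", "periodogram", "initial_guess",
           "fit_damped_sine", "windowed_gof", "amplitude_day3to5",
           "fit_plate", "condition_summary"]

_TAU_MIN, _TAU_MAX = 0.05, 100.0   # days


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the damped-sine fit."""

    period_bounds: tuple[float, float] = (16.0, 40.0)
    gof_threshold: float = 80.0       # percent variance explained
    max_iter: int = 1000              # max residual evaluations per start
    multistart: int = 4               # phase restarts per candidate period
    n_period_peaks: int = 3           # periodogram peaks tried
    include_trend: bool = True        # fit residual linear term (c0, c1)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.period_bounds
        if not (0 < lo < hi):
            raise InvalidParameterError(
                f"period bounds must be ordered and positive, got {self.period_bounds}")
        if not (0.0 < self.gof_threshold < 100.0):
            raise InvalidParameterError("gof_threshold must be in (0, 100)")


@dataclass
class DampedSineFit:
    """Fitted damped-sinusoid parameters plus goodness of fit."""

    T: float                 # period, h
    phi: float               # peak time, h, modulo T
    A: float                 # amplitude at window start, counts/s
    tau: float               # damping constant, days
    c0: float                # residual baseline intercept
    c1: float                # residual baseline slope
    gof: float               # percent variance explained, 0-100
    rss: float               # residual sum of squares
    n_obs: int               # samples fitted
    t_ref: float             # window start the amplitude is referenced to, h
    rhythmic: bool
    ok: bool = True          # False for a fit-failure placeholder
    meta: dict = field(default_factory=dict)

    @property
    def damping_rate(self) -> float:
        """Damping rate = 1/damping constant, per day (exact identity)."""
        return 1.0 / self.tau

    @property
    def phi_rad(self) -> float:
        """Phase in radians, 2*pi*phi/T."""
        return 2.0 * math.pi * self.phi / self.T

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        env = self.A * np.exp(-(t - self.t_ref) / (24.0 * self.tau))
        return (self.c0 + self.c1 * t
                + env * np.cos(2.0 * np.pi * (t - self.phi) / self.T))

    def amplitude_at(self, t: float) -> float:
        """Fitted envelope amplitude at absolute time ``t`` hours."""
        return self.A * math.exp(-(t - self.t_ref) / (24.0 * self.tau))

    @classmethod
    def failure(cls, n_obs: int, t_ref: float, reason: str) -> "DampedSineFit":
        return cls(T=np.nan, phi=np.nan, A=np.nan, tau=np.nan, c0=np.nan,
                   c1=np.nan, gof=0.0, rss=np.nan, n_obs=n_obs, t_ref=t_ref,
                   rhythmic=False, ok=False, meta={"error": reason})


# ---------------------------------------------------------------------------
# periodogram and initialization

def periodogram(trace: TimeSeriesTrace,
                period_bounds: tuple[float, float] = (16.0, 40.0),
                n_freq: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Lomb-Scargle periodogram on a period grid inside ``period_bounds``.

    Returns (periods, power) with periods increasing.
    """
    lo, hi = period_bounds
    freqs = np.linspace(1.0 / hi, 1.0 / lo, n_freq)
    y = trace.y - trace.y.mean()
    power = signal.lombscargle(trace.t, y, 2.0 * np.pi * freqs)
    periods = 1.0 / freqs[::-1]
    return periods, power[::-1]


def _top_periods(periods: np.ndarray, power: np.ndarray, k: int) -> list[float]:
    """Top-k local maxima of the periodogram; ties resolve to shorter periods."""
    peaks, _ = signal.find_peaks(power)
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(power))])
    # stable sort: primary key descending power, secondary ascending period
    order = sorted(peaks, key=lambda i: (-power[i], periods[i]))
    return [float(periods[i]) for i in order[:k]]


def initial_guess(trace: TimeSeriesTrace,
                  period_bounds: tuple[float, float] = (16.0, 40.0),
                  n_peaks: int = 3) -> dict:
    """Initial parameter estimates for the damped-sine fit.

    T candidates come from the Lomb-Scargle periodogram (global argmax
    first, ties toward shorter periods); A from a robust envelope estimate
    over the first candidate period; phi from the first smoothed peak; tau
    from a log-linear fit of the cycle-peak envelope, floored at 0.5 day.
    """
    y = trace.y
    scale = max(1.0, float(np.mean(y * y)))
    if np.var(y) <= (np.finfo(float).eps * 100.0) ** 2 * scale:
        raise NoSignalError("trace variance is at the machine floor (flat signal)")
    if trace.duration < 2.0 * period_bounds[0]:
        raise InsufficientDataError(
            f"trace spans {trace.duration:.1f} h; need >= 2x the lower "
            f"period bound ({2 * period_bounds[0]:.0f} h)")
    periods, power = periodogram(trace, period_bounds)
    T_cands = _top_periods(periods, power, n_peaks)
    T0 = T_cands[0]

    first = trace.t <= trace.t[0] + T0
    yc = y - y.mean()
    A0 = float(np.quantile(np.abs(yc[first]), 0.95))
    A0 = max(A0, 1e-12)

    # smoothed peak near the window start -> phase
    win = max(3, int(round(2.0 / max(trace.dt, 1e-6))) | 1)
    kernel = np.ones(win) / win
    smooth = np.convolve(yc, kernel, mode="same")
    i_peak = int(np.argmax(smooth[first]))
    phi0 = float(trace.t[i_peak])

    tau0 = _envelope_tau(trace.t, smooth, T0)
    return {"T_candidates": T_cands, "T": T0, "A": A0, "phi": phi0, "tau": tau0}


def _envelope_tau(t: np.ndarray, smooth: np.ndarray, T0: float) -> float:
    """Damping-constant guess from a log-linear fit of cycle-peak heights."""
    dt = float(np.median(np.diff(t)))
    dist = max(1, int(round(0.8 * T0 / dt)))
    peaks, _ = signal.find_peaks(smooth, distance=dist)
    peaks = peaks[smooth[peaks] > 0]
    if len(peaks) < 2:
        return 2.0
    slope = np.polyfit(t[peaks], np.log(smooth[peaks]), 1)[0]
    if slope >= 0:
        return _TAU_MAX / 2
    tau = -1.0 / (24.0 * slope)
    return float(np.clip(tau, 0.5, _TAU_MAX / 2))


# ---------------------------------------------------------------------------
# the fit

def _pack_model(t: np.ndarray, t_ref: float, include_trend: bool):
    two_pi = 2.0 * np.pi

    if include_trend:
        def model(p):
            A, T, phi, tau, c0, c1 = p
            return (c0 + c1 * t
                    + A * np.exp(-(t - t_ref) / (24.0 * tau))
                    * np.cos(two_pi * (t - phi) / T))
    else:
        def model(p):
            A, T, phi, tau = p
            return (A * np.exp(-(t - t_ref) / (24.0 * tau))
                    * np.cos(two_pi * (t - phi) / T))
    return model


def _pack_jacobian(t: np.ndarray, t_ref: float, include_trend: bool):
    """Analytic Jacobian of the residuals w.r.t. (A, T, phi, tau[, c0, c1])."""
    two_pi = 2.0 * np.pi

    def jac(p):
        A, T, phi, tau = p[0], p[1], p[2], p[3]
        arg = two_pi * (t - phi) / T
        E = np.exp(-(t - t_ref) / (24.0 * tau))
        C, S = np.cos(arg), np.sin(arg)
        cols = [
            E * C,                                 # dA
            A * E * S * arg / T,                   # dT
            A * E * S * two_pi / T,                # dphi
            A * E * C * (t - t_ref) / (24.0 * tau ** 2),  # dtau
        ]
        if include_trend:
            cols += [np.ones_like(t), t]
        return np.column_stack(cols)

    return jac


def fit_damped_sine(trace: TimeSeriesTrace,
                    config: FitConfig = FitConfig()) -> DampedSineFit:
    """Fit the damped sinusoid to a detrended trace.

    Deterministic given (trace, config). Non-convergence from every start
    yields a fit-failure result (``ok=False``, ``rhythmic=False``) rather
    than an exception; a flat input raises :class:`NoSignalError`.
    """
    lo, hi = config.period_bounds
    guess = initial_guess(trace, config.period_bounds, config.n_period_peaks)
    t, y = trace.t, trace.y
    t_ref = float(t[0])
    model = _pack_model(t, t_ref, config.include_trend)
    jac = _pack_jacobian(t, t_ref, config.include_trend)

    def residuals(p):
        return model(p) - y

    A0, tau0 = guess["A"], guess["tau"]
    n_par = 6 if config.include_trend else 4
    lower = [0.0, lo, -np.inf, _TAU_MIN] + ([-np.inf, -np.inf] if config.include_trend else [])
    upper = [np.inf, hi, np.inf, _TAU_MAX] + ([np.inf, np.inf] if config.include_trend else [])

    solutions = []
    phase_fracs = [i / config.multistart for i in range(config.multistart)]
    for T0 in guess["T_candidates"]:
        T0 = float(np.clip(T0, lo + 1e-9, hi - 1e-9))
        for frac in phase_fracs:
            phi0 = guess["phi"] + frac * T0
            x0 = [A0, T0, phi0, tau0] + ([0.0, 0.0] if config.include_trend else [])
            try:
                sol = optimize.least_squares(
                    residuals, x0, jac=jac, bounds=(lower, upper),
                    method="trf", max_nfev=config.max_iter, x_scale="jac")
            except Exception:
                continue
            if not np.all(np.isfinite(sol.x)):
                continue
            rss = float(np.sum(sol.fun ** 2))
            p = sol.x
            c1_abs = abs(p[5]) if config.include_trend else 0.0
            solutions.append((rss, c1_abs, 1.0 / p[3], p))

    n_obs = len(y)
    if not solutions:
        return DampedSineFit.failure(n_obs, t_ref, "no start converged")

    # best RSS; near-ties (1e-9 relative) broken by |c1| then damping rate
    best_rss = min(s[0] for s in solutions)
    tol = max(best_rss * 1e-9, 1e-300)
    contenders = [s for s in solutions if s[0] <= best_rss + tol]
    rss, _, _, p = min(contenders, key=lambda s: (s[1], s[2]))

    if config.include_trend:
        A, T, phi, tau, c0, c1 = p
    else:
        (A, T, phi, tau), c0, c1 = p, 0.0, 0.0
    phi = float(phi % T)

    tss = float(np.sum((y - y.mean()) ** 2))
    gof = 100.0 * max(0.0, 1.0 - rss / tss) if tss > 0 else 0.0
    gof = min(gof, 100.0)
    return DampedSineFit(
        T=float(T), phi=phi, A=float(A), tau=float(tau),
        c0=float(c0), c1=float(c1), gof=gof, rss=rss, n_obs=n_obs,
        t_ref=t_ref, rhythmic=bool(gof > config.gof_threshold))


def windowed_gof(trace: TimeSeriesTrace, fit: DampedSineFit,
                 t_start: float, t_end: float) -> float:
    """Percent variance explained by an existing fit inside a time window."""
    mask = (trace.t >= t_start) & (trace.t < t_end)
    if mask.sum() < 4:
        return 0.0
    y = trace.y[mask]
    resid = y - fit.predict(trace.t[mask])
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0:
        return 0.0
    return float(np.clip(100.0 * (1.0 - np.sum(resid ** 2) / tss), 0.0, 100.0))


def amplitude_day3to5(raw_trace: TimeSeriesTrace,
                      config: FitConfig = FitConfig()) -> float:
    """Rhythm amplitude from the day-3-to-5 protocol.

    The raw trace is restricted to [48, 120) h, linearly detrended within
    the window, and fitted; the returned amplitude is referenced to the
    window start (48 h).
    """
    win = preprocess.amplitude_window(raw_trace)
    fit = fit_damped_sine(win, config)
    if not fit.ok:
        raise InsufficientDataError("amplitude fit did not converge")
    return fit.A


# ---------------------------------------------------------------------------
# plates

_LATE_WINDOW_H = 48.0


def fit_plate(record, detrend_cfg: DetrendConfig = DetrendConfig(),
              fit_cfg: FitConfig = FitConfig(),
              with_amplitude: bool = True) -> pd.DataFrame:
    """Per-well pipeline exclude -> detrend -> fit for a whole plate.

    Individual well failures are recorded in the ``error`` column and never
    abort the plate. The returned frame has one row per well with the
    fitted parameters, overall and final-48-h goodness of fit, and (when
    ``with_amplitude``) the day-3-to-5 amplitude.
    """
    rows = []
    for well in record.wells:
        raw = record.traces[well]
        info = record.condition_of(well)
        row = {
            "well": well,
            "cell_line": info.cell_line,
            "reporter": info.reporter,
            "perturbation": info.perturbation,
            "is_control": info.is_control,
            "error": "",
        }
        try:
            det = preprocess.detrend(raw, detrend_cfg)
            fit = fit_damped_sine(det, fit_cfg)
            late = windowed_gof(det, fit, det.t[-1] - _LATE_WINDOW_H,
                                det.t[-1] + 1e-9)
            row.update(
                period_h=fit.T, phase_h=fit.phi, amplitude=fit.A,
                damping_constant_d=fit.tau,
                damping_rate_per_d=(fit.damping_rate if fit.ok else np.nan),
                gof_pct=fit.gof, late_gof_pct=late,
                rhythmic=fit.rhythmic, rss=fit.rss, n_obs=fit.n_obs,
            )
            if not fit.ok:
                row["error"] = fit.meta.get("error", "fit failure")
            if with_amplitude:
                try:
                    row["amp_day3to5"] = amplitude_day3to5(raw, fit_cfg)
                except Exception as exc:  # window too short, etc.
                    row["amp_day3to5"] = np.nan
                    row["error"] = (row["error"] + "; " if row["error"] else "") \
                        + f"amplitude: {exc}"
        except Exception as exc:
            row.update(period_h=np.nan, phase_h=np.nan, amplitude=np.nan,
                       damping_constant_d=np.nan, damping_rate_per_d=np.nan,
                       gof_pct=0.0, late_gof_pct=0.0, rhythmic=False,
                       rss=np.nan, n_obs=len(raw), error=str(exc))
            if with_amplitude:
                row["amp_day3to5"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def condition_summary(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-condition summary: mean +/- SD of period over rhythmic wells only."""
    out = []
    for (cell_line, pert), sub in fits.groupby(["cell_line", "perturbation"]):
        rhythmic = sub[sub["rhythmic"].astype(bool)]
        out.append({
            "cell_line": cell_line,
            "perturbation": pert,
            "n_wells": len(sub),
            "n_rhythmic": len(rhythmic),
            "mean_period_h": rhythmic["period_h"].mean(),
            "sd_period_h": rhythmic["period_h"].std(ddof=1),
            "mean_gof_pct": rhythmic["gof_pct"].mean(),
        })
    return pd.DataFrame(out)
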