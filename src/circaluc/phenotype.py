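"""Knockdown phenotype classification against non-specific controls.

Each perturbation is compared with the plate's NS (non-specific shRNA)
control wells and assigned labels from the screen vocabulary:

* ``WT``    control-like (standalone)
* ``Short`` / ``Long``  period significantly shorter/longer than control
* ``LA`` / ``HA``       low / high rhythm amplitude
* ``RD``    rapid damping — damping rate well above control AND loss of
            rhythmicity in the final 48 h (only transiently rhythmic)
* ``AR``    arrhythmic — fewer than half the wells pass the GOF cutoff
            (standalone)

Period, RD, and amplitude labels are combinable (e.g. "Short, LA",
"Short, RD", "RD, LA"); AR and WT stand alone. All numeric cutoffs are
package choices collected in :class:`PhenotypeRules` — screens of this
kind historically assigned labels by expert judgment, so the defaults are
deliberately conservative and fully configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError
from .preprocess import DetrendConfig
from .rhythm import DampedSineFit, FitConfig, fit_plate

__all__ = ["PhenotypeRules", "PeriodComparison", "ControlReference",
           "PhenotypeCall", "compare_periods", "classify",
           "classify_fit_table", "phenotype_plate", "phenotype_matrix"]

PERIOD_LABELS = ("Short", "Long")
AMP_LABELS = ("LA", "HA")


@dataclass(frozen=True)
class PhenotypeRules:
    """Classification cutoffs (all configurable)."""

    ar_rhythmic_frac: float = 0.5   # AR when < this fraction of wells rhythmic
    rd_factor: float = 2.5          # RD when median rate > factor * control mean
    min_delta_h: float = 0.5        # minimum period shift for Short/Long
    p_threshold: float = 0.01       # Welch p cutoff for Short/Long
    amp_low: float = 0.5            # LA when amplitude ratio below
    amp_high: float = 1.5           # HA when amplitude ratio above
    gof_threshold: float = 80.0     # rhythmicity cutoff for the late window


@dataclass
class PeriodComparison:
    """Welch two-sample comparison of fitted periods (b minus a)."""

    delta: float
    t_stat: float
    p: float
    n_a: int
    n_b: int
    testable: bool = True
    reason: str = ""

    @classmethod
    def not_testable(cls, n_a: int, n_b: int, reason: str) -> "PeriodComparison":
        return cls(np.nan, np.nan, np.nan, n_a, n_b, testable=False,
                   reason=reason)


def _periods(fits) -> np.ndarray:
    """Extract fitted periods from fits, a results frame, or raw numbers."""
    if isinstance(fits, pd.DataFrame):
        sub = fits[fits["rhythmic"].astype(bool)] if "rhythmic" in fits else fits
        return sub["period_h"].to_numpy(float)
    vals = []
    for f in fits:
        if isinstance(f, DampedSineFit):
            if f.rhythmic:
                vals.append(f.T)
        else:
            vals.append(float(f))
    return np.asarray(vals, float)


def compare_periods(fits_a, fits_b) -> PeriodComparison:
    """Welch two-sample t-test on fitted periods; delta = mean(b) - mean(a).

    Accepts lists of :class:`DampedSineFit` (non-rhythmic fits are
    excluded), result frames from :func:`~circaluc.rhythm.fit_plate`, or
    plain period arrays. Fewer than two usable periods on either side
    yields a not-testable result instead of an exception.
    """
    a, b = _periods(fits_a), _periods(fits_b)
    if len(a) < 2 or len(b) < 2:
        return PeriodComparison.not_testable(
            len(a), len(b), "fewer than 2 rhythmic fits in a group")
    delta = float(b.mean() - a.mean())
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        # degenerate but well-defined: identical constants -> no difference
        p = 1.0 if delta == 0 else 0.0
        t = 0.0 if delta == 0 else np.inf * np.sign(delta)
        return PeriodComparison(delta, float(t), p, len(a), len(b))
    t, p = stats.ttest_ind(b, a, equal_var=False)
    return PeriodComparison(delta, float(t), float(p), len(a), len(b))


@dataclass
class ControlReference:
    """Summary of the NS control wells (rhythmic controls only)."""

    periods: np.ndarray
    mean_T: float
    sd_T: float
    median_amp_day3to5: float
    median_amp_fit: float
    mean_damping_rate: float
    n: int

    @classmethod
    def from_fit_table(cls, fits: pd.DataFrame) -> "ControlReference":
        ctrl = fits[fits["is_control"].astype(bool)
                    & fits["rhythmic"].astype(bool)]
        if len(ctrl) < 2:
            raise InsufficientDataError(
                f"control reference needs >= 2 rhythmic NS wells, "
                f"got {len(ctrl)}")
        periods = ctrl["period_h"].to_numpy(float)
        amp35 = (ctrl["amp_day3to5"].to_numpy(float)
                 if "amp_day3to5" in ctrl else ctrl["amplitude"].to_numpy(float))
        return cls(
            periods=periods,
            mean_T=float(periods.mean()),
            sd_T=float(periods.std(ddof=1)),
            median_amp_day3to5=float(np.nanmedian(amp35)),
            median_amp_fit=float(ctrl["amplitude"].median()),
            mean_damping_rate=float(ctrl["damping_rate_per_d"].mean()),
            n=len(ctrl),
        )


@dataclass
class PhenotypeCall:
    """A phenotype label set with the quantitative evidence behind it."""

    labels: tuple[str, ...]
    delta_T: float = np.nan
    amp_ratio: float = np.nan
    damping_ratio: float = np.nan
    p_period: float = np.nan
    fraction_rhythmic: float = np.nan
    notes: str = ""

    def __post_init__(self) -> None:
        labels = set(self.labels)
        if not labels:
            raise InvalidParameterError("a phenotype call needs >= 1 label")
        if "Short" in labels and "Long" in labels:
            raise InvalidParameterError("Short and Long are mutually exclusive")
        if "LA" in labels and "HA" in labels:
            raise InvalidParameterError("LA and HA are mutually exclusive")
        for solo in ("AR", "WT"):
            if solo in labels and len(labels) > 1:
                raise InvalidParameterError(f"{solo} is a standalone label")

    @property
    def label(self) -> str:
        """Canonical string, ordered period -> RD -> amplitude."""
        order = {"Short": 0, "Long": 0, "RD": 1, "LA": 2, "HA": 2,
                 "WT": 3, "AR": 3}
        return ", ".join(sorted(self.labels, key=lambda l: order[l]))


def classify(kd_fits: pd.DataFrame, control: ControlReference,
             rules: PhenotypeRules = PhenotypeRules()) -> PhenotypeCall:
    """Classify one perturbation's wells against the control reference.

    Decision cascade:

    1. **AR** if fewer than ``ar_rhythmic_frac`` of the wells are rhythmic.
    2. **RD** if the median damping rate exceeds ``rd_factor`` times the
       control mean *and* the median final-48-h GOF falls below the
       rhythmicity threshold (transiently rhythmic only). RD does not stop
       the cascade: period and amplitude labels can accompany it.
    3. **Short**/**Long** if Welch p < ``p_threshold`` and the period shift
       magnitude is at least ``min_delta_h``.
    4. **LA**/**HA** from the amplitude ratio to control — day-3-to-5
       amplitudes normally; fitted window-start amplitudes for RD wells,
       whose day-3-to-5 amplitude is collapsed by the damping itself.
    5. **WT** when nothing else applies.
    """
    if len(kd_fits) == 0:
        raise InsufficientDataError("empty knockdown fit set")
    rhythmic = kd_fits[kd_fits["rhythmic"].astype(bool)]
    frac = len(rhythmic) / len(kd_fits)
    if frac < rules.ar_rhythmic_frac:
        return PhenotypeCall(("AR",), fraction_rhythmic=frac,
                             notes=f"{len(rhythmic)}/{len(kd_fits)} wells rhythmic")

    labels: list[str] = []
    notes: list[str] = []

    med_rate = float(rhythmic["damping_rate_per_d"].median())
    damping_ratio = med_rate / control.mean_damping_rate
    is_rd = False
    if damping_ratio > rules.rd_factor:
        med_late = float(rhythmic["late_gof_pct"].median())
        if med_late < rules.gof_threshold:
            is_rd = True
            labels.append("RD")
            notes.append(f"late-window GOF {med_late:.0f}%")

    comp = compare_periods(control.periods, rhythmic)
    if comp.testable and comp.p < rules.p_threshold \
            and abs(comp.delta) >= rules.min_delta_h:
        labels.append("Short" if comp.delta < 0 else "Long")

    if is_rd:
        amp_ratio = float(rhythmic["amplitude"].median()) / control.median_amp_fit
        notes.append("amplitude ratio from fitted window-start amplitude (RD)")
    else:
        kd_amp = (rhythmic["amp_day3to5"] if "amp_day3to5" in rhythmic
                  else rhythmic["amplitude"])
        amp_ratio = float(np.nanmedian(kd_amp.to_numpy(float))) \
            / control.median_amp_day3to5
    if np.isfinite(amp_ratio):
        if amp_ratio < rules.amp_low:
            labels.append("LA")
        elif amp_ratio > rules.amp_high:
            labels.append("HA")

    if not labels:
        labels = ["WT"]
    return PhenotypeCall(tuple(labels), delta_T=comp.delta,
                         amp_ratio=amp_ratio, damping_ratio=damping_ratio,
                         p_period=comp.p, fraction_rhythmic=frac,
                         notes="; ".join(notes))


def classify_fit_table(fits: pd.DataFrame,
                       rules: PhenotypeRules = PhenotypeRules(),
                       ) -> pd.DataFrame:
    """Classify every non-control perturbation in a per-well fit table.

    Control references are built per cell line from its NS wells. Returns
    one row per (cell_line, perturbation) with the call and its evidence;
    a table with only NS wells yields an empty frame with a warning.
    """
    out = []
    for cell_line, sub in fits.groupby("cell_line", sort=False):
        kd_all = sub[~sub["is_control"].astype(bool)]
        if len(kd_all) == 0:
            continue
        control = ControlReference.from_fit_table(sub)
        for pert, kd in kd_all.groupby("perturbation", sort=False):
            try:
                call = classify(kd, control, rules)
                out.append({"cell_line": cell_line, "perturbation": pert,
                            "label": call.label, "delta_T_h": call.delta_T,
                            "amp_ratio": call.amp_ratio,
                            "damping_ratio": call.damping_ratio,
                            "p_period": call.p_period,
                            "fraction_rhythmic": call.fraction_rhythmic,
                            "n_wells": len(kd), "notes": call.notes})
            except Exception as exc:
                out.append({"cell_line": cell_line, "perturbation": pert,
                            "label": "", "delta_T_h": np.nan,
                            "amp_ratio": np.nan, "damping_ratio": np.nan,
                            "p_period": np.nan, "fraction_rhythmic": np.nan,
                            "n_wells": len(kd), "notes": f"failed: {exc}"})
    if not out:
        warnings.warn("no knockdown conditions found (only NS wells?)",
                      stacklevel=2)
        return pd.DataFrame(columns=["cell_line", "perturbation", "label"])
    return pd.DataFrame(out)


def phenotype_plate(record, detrend_cfg: DetrendConfig = DetrendConfig(),
                    fit_cfg: FitConfig = FitConfig(),
                    rules: PhenotypeRules = PhenotypeRules(),
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end plate phenotyping: fit every well, then classify.

    Returns ``(calls, fits)``.
    """
    fits = fit_plate(record, detrend_cfg, fit_cfg, with_amplitude=True)
    return classify_fit_table(fits, rules), fits


def phenotype_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Pivot phenotype calls into a perturbation x cell-line label matrix."""
    return calls.pivot_table(index="perturbation", columns="cell_line",
                             values="label", aggfunc="first")
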