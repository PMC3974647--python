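"""Synthetic bioluminescence data with known ground truth.

Generative model for one trace (hours on the x axis, counts/s on the y)::

    y(t) = b0 + b1*t
         + transient_amp * exp(-t / transient_tau)
         + A * exp(-t / (24 * tau)) * cos(2*pi*(t - phi) / T)
         + eps(t)

``tau`` is the amplitude damping constant in days, so the damping rate
``1/tau`` is per day. ``phi`` is the time of the first cosine peak, in
hours. The transient term emulates the high luminescence burst that
follows a medium change and is the reason the first recorded cycle is
excluded from rhythm analysis downstream. Noise is Gaussian with
SD(t) = sigma_rel * A * exp(-t/(24*tau)) + sigma_abs, a high-count
approximation of photon-counting noise; a Poisson option is available.

Cell-line presets (period means/SDs taken from the published per-line
statistics; amplitude/damping/noise are package choices) and the
knockdown-effect library (period shifts, amplitude factors, damping
factors, arrhythmic flags encoding the screen's phenotype vocabulary)
are shipped in ``data/presets.yaml`` and are user-overridable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InvalidParameterError
from .io_plate import PlateMap, PlateRecord, WellInfo
from .trace import TimeSeriesTrace

__all__ = [
    "TraceModelParams", "CellLinePreset", "KnockdownEffect", "PlateCondition",
    "PlateSimConfig", "NULL_EFFECT", "load_presets", "load_effects",
    "get_preset", "get_effect", "apply_effect", "model_signal",
    "simulate_trace", "simulate_plate", "simulate_single_cell_ensemble",
    "simulate_qpcr",
]


@dataclass(frozen=True)
class TraceModelParams:
    """Parameters of the generative damped-cosine trace model."""

    b0: float = 200.0          # baseline intercept, counts/s
    b1: float = -0.3           # baseline slope, counts/s per h
    A: float = 100.0           # initial rhythm amplitude, counts/s
    T: float = 24.0            # period, h
    phi: float = 4.0           # first cosine peak time, h in [0, T)
    tau: float = 3.0           # damping constant, days
    transient_amp: float = 300.0
    transient_tau: float = 6.0  # h
    sigma_rel: float = 0.05    # noise SD as fraction of instantaneous amplitude
    sigma_abs: float = 1.0     # additive noise SD, counts/s

    def validate(self) -> None:
        vals = [self.b0, self.b1, self.A, self.T, self.phi, self.tau,
                self.transient_amp, self.transient_tau,
                self.sigma_rel, self.sigma_abs]
        if not all(np.isfinite(v) for v in vals):
            raise InvalidParameterError("non-finite trace model parameter")
        if self.A < 0:
            raise InvalidParameterError(f"A must be >= 0, got {self.A}")
        if not (16.0 <= self.T <= 40.0):
            raise InvalidParameterError(
                f"period T={self.T} h outside the circadian band [16, 40]")
        if self.tau <= 0:
            raise InvalidParameterError(f"tau must be > 0 d, got {self.tau}")
        if not (0.0 <= self.phi < self.T):
            raise InvalidParameterError(
                f"phi={self.phi} h must lie in [0, T={self.T})")
        if self.sigma_rel < 0 or self.sigma_abs < 0:
            raise InvalidParameterError("noise SDs must be >= 0")
        if self.transient_tau <= 0:
            raise InvalidParameterError("transient_tau must be > 0 h")


@dataclass(frozen=True)
class CellLinePreset:
    """A reporter cell line: base trace model + between-replicate dispersion."""

    name: str
    cell_line: str
    reporter: str
    base: TraceModelParams
    well_period_sd: float          # between-well period SD, h
    cell_period_sd: float | None = None  # between-cell period SD, h (imaging)


@dataclass(frozen=True)
class KnockdownEffect:
    """Simulation-side description of a perturbation.

    ``damping_factor`` multiplies the damping *rate* 1/tau, so a factor of 3
    turns a 3-day damping constant into 1 day. ``arrhythmic`` forces the
    rhythm amplitude to zero regardless of ``amp_factor``.
    """

    gene: str = "NS"
    shrna_id: str = "NS"
    delta_T: float = 0.0           # signed period shift, h
    amp_factor: float = 1.0        # multiplicative amplitude effect
    damping_factor: float = 1.0    # multiplicative effect on 1/tau
    kd_efficiency: float = 0.0     # fraction of endogenous mRNA removed
    arrhythmic: bool = False
    label: str = "WT"              # phenotype the effect encodes (ground truth)

    def validate(self) -> None:
        if self.amp_factor < 0 or self.damping_factor <= 0:
            raise InvalidParameterError("effect factors out of range")
        if not (0.0 <= self.kd_efficiency < 1.0):
            raise InvalidParameterError("kd_efficiency must be in [0, 1)")

    @property
    def is_null(self) -> bool:
        return (self.delta_T == 0 and self.amp_factor == 1
                and self.damping_factor == 1 and not self.arrhythmic)


NULL_EFFECT = KnockdownEffect()


def apply_effect(params: TraceModelParams, effect: KnockdownEffect,
                 ) -> TraceModelParams:
    """Return preset parameters with a knockdown effect applied."""
    effect.validate()
    amp = 0.0 if effect.arrhythmic else params.A * effect.amp_factor
    return replace(
        params,
        T=params.T + effect.delta_T,
        A=amp,
        tau=params.tau / effect.damping_factor,
    )


# ---------------------------------------------------------------------------
# preset / effect registry

def _params_from_dict(d: dict) -> TraceModelParams:
    return TraceModelParams(**{k: float(v) for k, v in d.items()})


def load_presets(path: str | Path | None = None) -> dict[str, CellLinePreset]:
    """Load cell-line presets from YAML (package defaults if no path given)."""
    raw = _load_yaml(path)
    presets = {}
    for name, spec in raw["presets"].items():
        presets[name] = CellLinePreset(
            name=name,
            cell_line=str(spec["cell_line"]),
            reporter=str(spec["reporter"]),
            base=_params_from_dict(spec["base"]),
            well_period_sd=float(spec["well_period_sd"]),
            cell_period_sd=(float(spec["cell_period_sd"])
                            if "cell_period_sd" in spec else None),
        )
    return presets


def load_effects(path: str | Path | None = None,
                 ) -> dict[str, dict[str, KnockdownEffect]]:
    """Load the knockdown-effect library: gene -> cell line -> effect."""
    raw = _load_yaml(path)
    lib: dict[str, dict[str, KnockdownEffect]] = {}
    for gene, spec in raw.get("effects", {}).items():
        per_line = {}
        for cell_line, eff in spec["by_cell_line"].items():
            per_line[cell_line] = KnockdownEffect(
                gene=gene,
                shrna_id=str(spec.get("shrna_id", "sh?")),
                delta_T=float(eff.get("delta_T", 0.0)),
                amp_factor=float(eff.get("amp_factor", 1.0)),
                damping_factor=float(eff.get("damping_factor", 1.0)),
                kd_efficiency=float(spec.get("kd_efficiency", 0.0)),
                arrhythmic=bool(eff.get("arrhythmic", False)),
                label=str(eff.get("label", "WT")),
            )
        lib[gene] = per_line
    return lib


def _load_yaml(path: str | Path | None) -> dict:
    if path is None:
        ref = importlib.resources.files("circaluc.data") / "presets.yaml"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


def get_preset(name: str, path: str | Path | None = None) -> CellLinePreset:
    presets = load_presets(path)
    if name not in presets:
        raise ConfigError(
            f"unknown preset {name!r}; valid presets: {sorted(presets)}")
    return presets[name]


def get_effect(gene: str, cell_line: str,
               path: str | Path | None = None) -> KnockdownEffect:
    lib = load_effects(path)
    if gene not in lib:
        raise ConfigError(f"unknown gene {gene!r}; known: {sorted(lib)}")
    if cell_line not in lib[gene]:
        raise ConfigError(
            f"no {gene} effect for cell line {cell_line!r}; "
            f"known: {sorted(lib[gene])}")
    return lib[gene][cell_line]


# ---------------------------------------------------------------------------
# trace simulation

def model_signal(params: TraceModelParams, t: np.ndarray) -> np.ndarray:
    """Noiseless closed-form evaluation of the trace model."""
    t = np.asarray(t, float)
    env = params.A * np.exp(-t / (24.0 * params.tau))
    return (params.b0 + params.b1 * t
            + params.transient_amp * np.exp(-t / params.transient_tau)
            + env * np.cos(2.0 * np.pi * (t - params.phi) / params.T))


def simulate_trace(params: TraceModelParams, duration: float, dt: float,
                   seed: int | np.random.Generator,
                   noise: str = "gaussian") -> TimeSeriesTrace:
    """Simulate one luminescence trace on the grid t = 0, dt, ..., duration.

    With ``sigma_rel = sigma_abs = 0`` (Gaussian noise) the output equals the
    closed-form model exactly; the same seed always yields the same trace.
    ``noise="poisson"`` instead draws each sample from a Poisson law with the
    model value as mean (counts/s treated as counts per sampling bin).
    """
    params.validate()
    if duration < 48.0:
        raise InvalidParameterError(
            f"duration must be >= 48 h for rhythm analysis, got {duration}")
    if dt <= 0:
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    rng = _as_rng(seed)
    n = int(np.floor(duration / dt)) + 1
    t = np.arange(n) * dt
    clean = model_signal(params, t)
    if noise == "gaussian":
        sd = (params.sigma_rel * params.A * np.exp(-t / (24.0 * params.tau))
              + params.sigma_abs)
        y = clean + rng.normal(0.0, 1.0, size=n) * sd
    elif noise == "poisson":
        y = rng.poisson(np.clip(clean, 0.0, None)).astype(float)
    else:
        raise InvalidParameterError(f"unknown noise model {noise!r}")
    return TimeSeriesTrace(t, y, meta={"true_params": params})


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# plate simulation

@dataclass
class PlateCondition:
    """One experimental condition on a plate: a preset plus a perturbation."""

    preset: CellLinePreset
    effect: KnockdownEffect = NULL_EFFECT
    n_wells: int = 4
    wells: Sequence[str] | None = None   # explicit ids; auto-assigned if None

    @property
    def name(self) -> str:
        return f"{self.preset.name}:{self.effect.gene}"


@dataclass
class PlateSimConfig:
    conditions: list[PlateCondition]
    duration: float = 120.0   # h
    dt: float = 1.0 / 6.0     # h (10-min sampling)
    seed: int = 0

    def validate(self) -> None:
        if not self.conditions:
            raise ConfigError("plate config lists no conditions")
        if self.duration <= 0 or self.dt <= 0:
            raise ConfigError("duration and dt must be positive")
        for cond in self.conditions:
            eff_T = cond.preset.base.T + cond.effect.delta_T
            # >= 3 full periods must remain after first-cycle exclusion
            if self.duration - 24.0 < 3.0 * eff_T:
                raise ConfigError(
                    f"duration {self.duration} h leaves fewer than 3 periods "
                    f"of {cond.name} after first-cycle exclusion")
        assigned: set[str] = set()
        for cond in self.conditions:
            if cond.wells is not None:
                overlap = assigned & set(cond.wells)
                if overlap:
                    raise ConfigError(f"overlapping well assignment: {overlap}")
                assigned |= set(cond.wells)


def _auto_wells(n_total: int) -> list[str]:
    rows = "ABCDEFGH"
    ids = [f"{r}{c:02d}" for r in rows for c in range(1, 13)]
    if n_total > len(ids):
        ids = [f"W{i:03d}" for i in range(1, n_total + 1)]
    return ids[:n_total]


def simulate_plate(config: PlateSimConfig) -> PlateRecord:
    """Simulate a plate of traces with hidden per-well ground truth.

    The period of each well is drawn ``N(T_preset + delta_T,
    well_period_sd^2)`` (clipped to the circadian band); all other
    parameters follow the preset with the effect applied. True per-well
    parameters are stored in ``record.ground_truth``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_total = sum(c.n_wells if c.wells is None else len(c.wells)
                  for c in config.conditions)
    auto = iter(_auto_wells(n_total))

    traces: dict[str, TimeSeriesTrace] = {}
    wells_info: dict[str, WellInfo] = {}
    truth: dict[str, dict] = {}
    for cond in config.conditions:
        well_ids = (list(cond.wells) if cond.wells is not None
                    else [next(auto) for _ in range(cond.n_wells)])
        base = apply_effect(cond.preset.base, cond.effect)
        for well in well_ids:
            T_i = float(np.clip(
                rng.normal(base.T, cond.preset.well_period_sd), 16.0, 40.0))
            params = replace(base, T=T_i, phi=base.phi % T_i)
            tr = simulate_trace(params, config.duration, config.dt, rng)
            tr.meta.update(
                well=well,
                cell_line=cond.preset.cell_line,
                reporter=cond.preset.reporter,
                perturbation=cond.effect.gene,
                is_control=(cond.effect.gene == "NS"),
                condition=cond.name,
            )
            traces[well] = tr
            wells_info[well] = WellInfo(
                cell_line=cond.preset.cell_line,
                reporter=cond.preset.reporter,
                perturbation=tr.meta["perturbation"],
                is_control=(cond.effect.gene == "NS"),
            )
            truth[well] = {
                "params": params,
                "preset": cond.preset.name,
                "effect": cond.effect,
            }
    return PlateRecord(traces, PlateMap(wells_info), dt=config.dt,
                       ground_truth=truth)


# ---------------------------------------------------------------------------
# single-cell ensembles

def simulate_single_cell_ensemble(preset: CellLinePreset, n_cells: int,
                                  duration: float = 144.0, dt: float = 0.5,
                                  seed: int = 0,
                                  ) -> list[TimeSeriesTrace]:
    """Simulate an ensemble of single-cell traces.

    Per-cell periods are drawn ``N(preset mean, cell_period_sd^2)``;
    per-cell peak times get a few hours of jitter (dissociated cells are
    not phase-locked). Noise follows the preset, which for the neuron
    presets is substantially higher than plate wells.
    """
    if n_cells < 1:
        raise InvalidParameterError("n_cells must be >= 1")
    cell_sd = preset.cell_period_sd
    if cell_sd is None:
        cell_sd = preset.well_period_sd
    rng = np.random.default_rng(seed)
    cells = []
    for i in range(n_cells):
        T_i = float(np.clip(rng.normal(preset.base.T, cell_sd), 16.0, 40.0))
        phi_i = float((preset.base.phi + rng.normal(0.0, 2.0)) % T_i)
        params = replace(preset.base, T=T_i, phi=phi_i)
        tr = simulate_trace(params, duration, dt, rng)
        tr.meta.update(cell=f"cell{i:04d}", cell_line=preset.cell_line,
                       reporter=preset.reporter)
        if n_cells == 1:
            tr.meta["sem_defined"] = False
        cells.append(tr)
    return cells


# ---------------------------------------------------------------------------
# full knockdown screen

# reporter line used for phenotyping in each cellular model
SCREEN_PRESETS = {"3T3": "fib_bmal1", "3T3-L1": "adip_per2",
                  "MMH-D3": "hep_per2"}


def screen_configs(n_kd: int = 4, n_ns: int = 8, duration: float = 120.0,
                   dt: float = 1.0 / 6.0, seed: int = 0,
                   genes: Sequence[str] | None = None,
                   ) -> dict[str, PlateSimConfig]:
    """Build one plate config per cellular model for the full knockdown screen.

    Each plate carries ``n_ns`` NS control wells plus ``n_kd`` wells per gene
    in the effect library, using the reporter line that was used for
    phenotyping in that model (Bmal1-dLuc for 3T3 fibroblasts, Per2-dLuc for
    3T3-L1 adipocytes and MMH-D3 hepatocytes). Per-plate seeds derive from
    ``seed``.
    """
    presets = load_presets()
    effects = load_effects()
    genes = list(genes) if genes is not None else sorted(effects)
    configs = {}
    for i, (cell_line, preset_name) in enumerate(sorted(SCREEN_PRESETS.items())):
        preset = presets[preset_name]
        conds = [PlateCondition(preset, NULL_EFFECT, n_wells=n_ns)]
        for gene in genes:
            conds.append(PlateCondition(
                preset, effects[gene][cell_line], n_wells=n_kd))
        configs[cell_line] = PlateSimConfig(
            conditions=conds, duration=duration, dt=dt,
            seed=(seed * 7 + i) % 2**31)
    return configs


def expected_screen_labels(genes: Sequence[str] | None = None,
                           ) -> pd.DataFrame:
    """Ground-truth phenotype labels encoded by the effect library."""
    effects = load_effects()
    genes = list(genes) if genes is not None else sorted(effects)
    rows = [{"cell_line": cl, "perturbation": g, "label": effects[g][cl].label}
            for g in genes for cl in sorted(SCREEN_PRESETS)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR tables

def simulate_qpcr(kd_efficiency: float, ct_ns_target: float = 22.0,
                  ct_ref: float = 16.0, noise_sd: float = 0.0,
                  seed: int = 0, gene: str = "target",
                  reference_gene: str = "Gapdh",
                  n_replicates: int = 2) -> pd.DataFrame:
    """Simulate a Ct table for one knockdown vs its non-specific control.

    A knockdown removing a fraction ``e`` of target mRNA delays the target
    amplification by ``-log2(1 - e)`` cycles; the reference gene is
    unaffected in expectation. Returns the long-format Ct table consumed by
    :func:`circaluc.qpcr.percent_of_control`.
    """
    if not (0.0 <= kd_efficiency < 1.0):
        raise InvalidParameterError(
            f"kd_efficiency must be in [0, 1); {kd_efficiency} would imply "
            "an infinite Ct")
    rng = np.random.default_rng(seed)
    shift = -np.log2(1.0 - kd_efficiency)
    rows = []
    for condition, tgt_ct in (("NS", ct_ns_target), ("KD", ct_ns_target + shift)):
        for rep in range(1, n_replicates + 1):
            rows.append({"sample": f"{condition}_{rep}", "condition": condition,
                         "gene": gene, "replicate": rep,
                         "ct": tgt_ct + rng.normal(0.0, noise_sd)})
            rows.append({"sample": f"{condition}_{rep}", "condition": condition,
                         "gene": reference_gene, "replicate": rep,
                         "ct": ct_ref + rng.normal(0.0, noise_sd)})
    return pd.DataFrame(rows)
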