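"""Plate-level I/O: wide/long CSV readers, plate maps, result tables.

Canonical exchange formats (plate-reader exports are vendor-specific, so the
package defines its own documented dialects):

* **Wide plate CSV** — first column ``time_h`` (hours) or ``time_min``
  (minutes), one column per well. Example::

      time_h,A01,A02,A03
      0.0,312.1,298.7,305.2
      0.1667,310.9,297.5,304.1

* **Plate-map CSV** — columns ``well,cell_line,reporter,perturbation,
  is_control`` (``is_control`` parsed as boolean).

* **Long trace CSV** — columns ``cell_id,t_h,signal`` (used for single-cell
  ROI traces; any id column name accepted via ``id_col``).

* **Results CSV** — one row per well/cell with fitted parameters, plus a
  JSON sidecar recording the configuration and package version so every
  output is regenerable from its sidecar plus the inputs.

Gap policy on ingestion: rows where every well is missing are dropped;
runs of up to 3 consecutive missing values within a well are linearly
interpolated; longer runs are rejected with an error naming the well.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, SchemaError
from .trace import TimeSeriesTrace

_MAX_GAP_RUN = 3

PLATEMAP_COLUMNS = ["well", "cell_line", "reporter", "perturbation", "is_control"]
VALID_REPORTERS = {"Per2-dLuc", "Bmal1-dLuc", "mPer2Luc"}


@dataclass
class WellInfo:
    cell_line: str
    reporter: str
    perturbation: str
    is_control: bool


@dataclass
class PlateMap:
    """Mapping of well id to (cell line, reporter, perturbation, control flag)."""

    wells: dict[str, WellInfo]

    def __post_init__(self) -> None:
        if not self.wells:
            raise SchemaError("plate map is empty")

    def __contains__(self, well: str) -> bool:
        return well in self.wells

    def __getitem__(self, well: str) -> WellInfo:
        return self.wells[well]

    @property
    def control_wells(self) -> list[str]:
        return [w for w, info in self.wells.items() if info.is_control]

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlateMap":
        df = pd.read_csv(path)
        missing = [c for c in PLATEMAP_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"plate map {path} lacks columns: {missing}")
        if df["well"].duplicated().any():
            dups = df.loc[df["well"].duplicated(), "well"].tolist()
            raise SchemaError(f"duplicate plate-map wells: {dups}")
        wells = {}
        for row in df.itertuples(index=False):
            wells[str(row.well)] = WellInfo(
                cell_line=str(row.cell_line),
                reporter=str(row.reporter),
                perturbation=str(row.perturbation),
                is_control=_parse_bool(row.is_control),
            )
        return cls(wells)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {
                "well": w,
                "cell_line": i.cell_line,
                "reporter": i.reporter,
                "perturbation": i.perturbation,
                "is_control": i.is_control,
            }
            for w, i in self.wells.items()
        ]
        pd.DataFrame(rows, columns=PLATEMAP_COLUMNS).to_csv(path, index=False)


def _parse_bool(v: Any) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in {"true", "1", "yes", "y"}:
        return True
    if s in {"false", "0", "no", "n"}:
        return False
    raise SchemaError(f"cannot parse boolean plate-map value {v!r}")


@dataclass
class PlateRecord:
    """A plate of traces joined to its plate map; all traces share one grid."""

    traces: dict[str, TimeSeriesTrace]
    map: PlateMap
    dt: float
    ground_truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.traces:
            raise SchemaError("plate record holds no traces")
        grids = [tr.t for tr in self.traces.values()]
        ref = grids[0]
        for g in grids[1:]:
            if len(g) != len(ref) or not np.allclose(g, ref):
                raise SchemaError("all plate traces must share one time grid")

    @property
    def wells(self) -> list[str]:
        return list(self.traces)

    def condition_of(self, well: str) -> WellInfo:
        return self.map[well]


def read_plate_csv(path: str | Path, platemap_path: str | Path) -> PlateRecord:
    """Read a wide plate CSV joined to a plate map.

    The first column must be named ``time_h`` or ``time_min``; no silent
    unit inference. Unmapped data columns raise a schema error naming the
    offenders; non-monotone time raises a format error.
    """
    plate_map = PlateMap.from_csv(platemap_path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: plate CSV needs a time column and wells")
    time_col = df.columns[0]
    if time_col == "time_h":
        t = df[time_col].to_numpy(float)
    elif time_col == "time_min":
        t = df[time_col].to_numpy(float) / 60.0
    else:
        raise SchemaError(
            f"{path}: first column must be 'time_h' or 'time_min', got {time_col!r}"
        )
    well_cols = [c for c in df.columns[1:]]
    unmapped = [c for c in well_cols if c not in plate_map]
    if unmapped:
        raise SchemaError(f"{path}: wells missing from plate map: {unmapped}")

    signal = df[well_cols]
    keep = ~signal.isna().all(axis=1)
    t, signal = t[keep.to_numpy()], signal.loc[keep]
    if len(t) < 2:
        raise InsufficientDataError(f"{path}: fewer than 2 usable rows")
    if not np.all(np.diff(t) > 0):
        raise FormatError(f"{path}: time column is not strictly increasing")

    traces = {}
    for well in well_cols:
        y = signal[well].to_numpy(float)
        y = _fill_gaps(t, y, well)
        info = plate_map[well]
        traces[well] = TimeSeriesTrace(
            t,
            y,
            meta={
                "well": well,
                "cell_line": info.cell_line,
                "reporter": info.reporter,
                "perturbation": info.perturbation,
                "is_control": info.is_control,
            },
        )
    return PlateRecord(traces, plate_map, dt=float(np.median(np.diff(t))))


def _fill_gaps(t: np.ndarray, y: np.ndarray, well: str) -> np.ndarray:
    """Interpolate missing runs of <= 3 samples; reject longer runs."""
    missing = ~np.isfinite(y)
    if not missing.any():
        return y
    # locate runs of consecutive missing samples
    idx = np.flatnonzero(missing)
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        if len(run) > _MAX_GAP_RUN:
            raise SchemaError(
                f"well {well}: {len(run)} consecutive missing values "
                f"(gap policy allows at most {_MAX_GAP_RUN})"
            )
        if run[0] == 0 or run[-1] == len(y) - 1:
            raise SchemaError(f"well {well}: missing values at trace boundary")
    out = y.copy()
    out[missing] = np.interp(t[missing], t[~missing], y[~missing])
    return out


def write_plate_csv(record: PlateRecord, path: str | Path,
                    platemap_path: str | Path | None = None) -> None:
    """Write a PlateRecord as a wide plate CSV (+ optional plate-map CSV)."""
    wells = record.wells
    t = record.traces[wells[0]].t
    df = pd.DataFrame({"time_h": t})
    for w in wells:
        df[w] = record.traces[w].y
    df.to_csv(path, index=False, float_format="%.10g")
    if platemap_path is not None:
        record.map.to_csv(platemap_path)


def read_long_csv(path: str | Path, id_col: str = "cell_id",
                  t_col: str = "t_h", y_col: str = "signal",
                  ) -> dict[str, TimeSeriesTrace]:
    """Read long-format per-cell (or per-well) traces."""
    df = pd.read_csv(path)
    for c in (id_col, t_col, y_col):
        if c not in df.columns:
            raise SchemaError(f"{path}: missing column {c!r}")
    traces: dict[str, TimeSeriesTrace] = {}
    for cid, sub in df.groupby(id_col, sort=False):
        sub = sub.sort_values(t_col)
        t = sub[t_col].to_numpy(float)
        y = sub[y_col].to_numpy(float)
        keep = np.isfinite(y)
        traces[str(cid)] = TimeSeriesTrace(t[keep], y[keep], meta={"cell": str(cid)})
    return traces


def write_long_csv(traces: Mapping[str, TimeSeriesTrace], path: str | Path,
                   id_col: str = "cell_id") -> None:
    frames = [
        pd.DataFrame({id_col: cid, "t_h": tr.t, "signal": tr.y})
        for cid, tr in traces.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.10g")


def write_results(table: pd.DataFrame, path: str | Path,
                  config: Mapping[str, Any] | None = None) -> None:
    """Write a results table as CSV plus a JSON provenance sidecar.

    The sidecar (``<path>.meta.json``) records the configuration used, the
    package version, and a timestamp; the CSV itself is deterministic.
    """
    if table is None or len(table) == 0:
        raise InsufficientDataError("refusing to write an empty results table")
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.10g")
    from . import __version__

    sidecar = {
        "software": "circaluc",
        "version": __version__,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "n_rows": int(len(table)),
        "config": dict(config) if config else {},
    }
    with open(path.with_name(path.name + ".meta.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
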