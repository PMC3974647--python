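"""Knockdown-efficiency quantification by the ddCt method.

Target-gene Ct values are normalized to a reference gene (Gapdh) within
each sample (dCt = Ct_target - Ct_reference) and expressed relative to the
non-specific-control condition: relative expression = 2^-(dCt_KD -
mean dCt_NS), reported as a percentage of NS control expression.
Amplification efficiency is fixed at 2 per cycle (the classic ddCt
assumption); NS replicates are averaged on the dCt scale before
exponentiation, so the NS condition evaluates to 100% by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError

__all__ = ["CT_COLUMNS", "validate_ct_table", "read_ct_csv",
           "percent_of_control", "PercentOfControl"]

CT_COLUMNS = ["sample", "condition", "gene", "replicate", "ct"]
_CT_RANGE = (0.0, 45.0)


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"Ct table lacks columns: {missing}")
    ct = table["ct"].to_numpy(float)
    bad = ~((ct > _CT_RANGE[0]) & (ct < _CT_RANGE[1]))
    if bad.any():
        raise SchemaError(
            f"{bad.sum()} Ct values outside ({_CT_RANGE[0]}, {_CT_RANGE[1]}) cycles")
    conditions = set(table["condition"].unique())
    if not conditions <= {"KD", "NS"}:
        raise SchemaError(
            f"condition must be 'KD' or 'NS', got {sorted(conditions)}")
    return table


def read_ct_csv(path) -> pd.DataFrame:
    return validate_ct_table(pd.read_csv(path))


@dataclass
class PercentOfControl:
    """Relative expression of a knockdown as percent of NS control."""

    gene: str
    percent_mean: float
    percent_sd: float            # NaN with a single KD replicate
    n_replicates: int
    ns_percent: float = 100.0    # by construction

    @property
    def kd_efficiency(self) -> float:
        """Implied fraction of endogenous mRNA removed."""
        return 1.0 - self.percent_mean / 100.0


def percent_of_control(table: pd.DataFrame, target_gene: str,
                       reference_gene: str = "Gapdh") -> PercentOfControl:
    """Percent-of-control expression of ``target_gene`` via ddCt.

    Every (sample, condition) must carry a Ct for both the target and the
    reference gene. Within each sample dCt = Ct_target - Ct_reference;
    the NS baseline is the mean NS dCt; each KD replicate contributes
    ``100 * 2**-(dCt - baseline)`` and the mean and SD over KD replicates
    are reported (SD is NaN with a single replicate).
    """
    validate_ct_table(table)
    dct = {}
    for cond in ("NS", "KD"):
        sub = table[table["condition"] == cond]
        tgt = sub[sub["gene"] == target_gene].set_index("sample")["ct"]
        ref = sub[sub["gene"] == reference_gene].set_index("sample")["ct"]
        if len(tgt) == 0:
            raise SchemaError(f"no {cond} measurements for gene {target_gene!r}")
        if not set(tgt.index) <= set(ref.index):
            orphans = sorted(set(tgt.index) - set(ref.index))
            raise SchemaError(
                f"samples missing reference gene {reference_gene!r}: {orphans}")
        dct[cond] = (tgt - ref.loc[tgt.index]).to_numpy(float)

    baseline = dct["NS"].mean()
    percents = 100.0 * np.power(2.0, -(dct["KD"] - baseline))
    n = len(percents)
    return PercentOfControl(
        gene=target_gene,
        percent_mean=float(percents.mean()),
        percent_sd=float(percents.std(ddof=1)) if n > 1 else float("nan"),
        n_replicates=n,
    )
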