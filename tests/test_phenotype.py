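"""Classifier: period tests, label cascade, invariances, control self-test."""

import numpy as np
import pandas as pd
import pytest

from circaluc.errors import InsufficientDataError, InvalidParameterError
from circaluc.phenotype import (ControlReference, PhenotypeCall,
                                PhenotypeRules, classify, classify_fit_table,
                                compare_periods, phenotype_matrix,
                                phenotype_plate)
from circaluc.synthetic import (KnockdownEffect, PlateCondition,
                                PlateSimConfig, get_preset, simulate_plate)


def _with_stats(base, mean, sd):
    """Array with exactly the requested mean and sample SD."""
    base = np.asarray(base, float)
    z = (base - base.mean()) / base.std(ddof=1)
    return mean + sd * z


def make_fit_table(periods, amps=None, rates=None, late_gofs=None,
                   rhythmic=None, is_control=False, perturbation="KD",
                   cell_line="3T3"):
    n = len(periods)
    amps = np.full(n, 50.0) if amps is None else np.asarray(amps, float)
    rates = np.full(n, 1 / 3) if rates is None else np.asarray(rates, float)
    late = np.full(n, 95.0) if late_gofs is None else np.asarray(late_gofs, float)
    ry = np.full(n, True) if rhythmic is None else np.asarray(rhythmic, bool)
    return pd.DataFrame({
        "well": [f"W{i}" for i in range(n)],
        "cell_line": cell_line, "perturbation": perturbation,
        "is_control": is_control, "period_h": periods, "amplitude": amps,
        "amp_day3to5": amps, "damping_rate_per_d": rates,
        "late_gof_pct": late, "gof_pct": np.where(ry, 95.0, 20.0),
        "rhythmic": ry,
    })


CONTROL = make_fit_table(_with_stats([-1.5, -0.5, 0.5, 1.5, -1, 0, 1, 2],
                                     24.5, 0.2),
                         is_control=True, perturbation="NS")
REF = ControlReference.from_fit_table(CONTROL)


class TestComparePeriods:
    def test_identical_groups(self):
        c = compare_periods([24.0, 25.0, 26.0], [24.0, 25.0, 26.0])
        assert c.delta == 0.0 and c.p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        a = _with_stats([-1.5, -0.5, 0.5, 1.5], 24.5, 0.2)
        b = _with_stats([-1.5, -0.5, 0.5, 1.5], 22.5, 0.2)
        c = compare_periods(a, b)
        assert c.delta == pytest.approx(-2.0)
        assert c.p < 0.001

    def test_insufficient_group_not_testable(self):
        c = compare_periods([24.0], [24.0, 25.0, 26.0])
        assert not c.testable and np.isnan(c.p)


class TestClassify:
    def test_period_shortening_called_short(self):
        kd = make_fit_table(_with_stats([-1, 0, 1, 2], 23.0, 0.2))
        call = classify(kd, REF)
        assert call.label == "Short"
        assert call.delta_T == pytest.approx(-1.5)

    def test_arrhythmic_wells_called_ar(self):
        kd = make_fit_table([24, 24, 24, 24], rhythmic=[False, False, False, True])
        call = classify(kd, REF)
        assert call.label == "AR"

    def test_null_effect_called_wt(self):
        kd = make_fit_table(_with_stats([-1, 0, 1, 2], 24.5, 0.2))
        assert classify(kd, REF).label == "WT"

    def test_low_and_high_amplitude(self):
        kd = make_fit_table(_with_stats([-1, 0, 1, 2], 24.5, 0.2),
                            amps=[15, 14, 16, 15])
        assert classify(kd, REF).label == "LA"
        kd = make_fit_table(_with_stats([-1, 0, 1, 2], 24.5, 0.2),
                            amps=[90, 110, 100, 95])
        assert classify(kd, REF).label == "HA"

    def test_rapid_damping_requires_late_rhythm_loss(self):
        fast = make_fit_table(_with_stats([-1, 0, 1, 2], 24.5, 0.2),
                              rates=[1.0, 1.1, 0.9, 1.0],
                              late_gofs=[40, 35, 50, 45])
        assert classify(fast, REF).label == "RD"
        # fast damping but still rhythmic at the end -> not RD
        persistent = make_fit_table(_with_stats([-1, 0, 1, 2], 24.5, 0.2),
                                    rates=[1.0, 1.1, 0.9, 1.0],
                                    late_gofs=[90, 92, 88, 91])
        assert classify(persistent, REF).label == "WT"

    def test_combined_short_and_rd(self):
        kd = make_fit_table(_with_stats([-1, 0, 1, 2], 23.0, 0.2),
                            rates=[1.0, 1.0, 1.0, 1.0],
                            late_gofs=[40, 35, 50, 45])
        assert classify(kd, REF).label == "Short, RD"

    def test_empty_set_rejected(self):
        with pytest.raises(InsufficientDataError):
            classify(CONTROL.iloc[:0], REF)

    def test_well_order_never_changes_the_call(self):
        kd = make_fit_table(_with_stats([-1, 0, 1, 2], 23.0, 0.2),
                            amps=[15, 40, 14, 16])
        base = classify(kd, REF).label
        for seed in range(5):
            shuffled = kd.sample(frac=1, random_state=seed)
            assert classify(shuffled, REF).label == base

    def test_larger_shifts_never_revert_to_wt(self):
        labels = []
        for delta in [0.6, 1.0, 1.5, 2.5, 4.0]:
            kd = make_fit_table(_with_stats([-1, 0, 1, 2], 24.5 - delta, 0.2))
            labels.append(classify(kd, REF).label)
        assert labels == ["Short"] * 5


class TestPhenotypeCallInvariants:
    @pytest.mark.parametrize("labels", [
        (), ("Short", "Long"), ("LA", "HA"), ("AR", "LA"), ("WT", "Short")])
    def test_invalid_label_sets_rejected(self, labels):
        with pytest.raises(InvalidParameterError):
            PhenotypeCall(labels)

    def test_canonical_order(self):
        assert PhenotypeCall(("LA", "RD")).label == "RD, LA"
        assert PhenotypeCall(("RD", "Short")).label == "Short, RD"
        assert PhenotypeCall(("HA", "Long")).label == "Long, HA"


class TestControlSelfConsistency:
    def test_split_half_controls_classify_as_wt(self, fib_plate_fits):
        fits = fib_plate_fits.copy()
        n_wt = 0
        n_splits = 100
        for seed in range(n_splits):
            rng = np.random.default_rng(seed)
            idx = rng.permutation(len(fits))
            ctrl = fits.iloc[idx[:12]]
            half = fits.iloc[idx[12:]].copy()
            half["is_control"] = False
            ref = ControlReference.from_fit_table(ctrl)
            n_wt += classify(half, ref).label == "WT"
        assert n_wt >= 0.95 * n_splits


class TestPhenotypePlate:
    def test_double_knockdown_arrhythmic(self):
        # composed Per1+Per2 effect: rhythm amplitude collapses entirely
        preset = get_preset("hep_per2")
        double = KnockdownEffect(gene="Per1+Per2", arrhythmic=True)
        cfg = PlateSimConfig([
            PlateCondition(preset, n_wells=6),
            PlateCondition(preset, double, n_wells=4),
        ], seed=3)
        calls, fits = phenotype_plate(simulate_plate(cfg))
        row = calls[calls["perturbation"] == "Per1+Per2"].iloc[0]
        assert row["label"] == "AR"

    def test_only_controls_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="NS"):
            out = classify_fit_table(CONTROL)
        assert len(out) == 0

    def test_matrix_shape(self):
        calls = pd.DataFrame({
            "cell_line": ["3T3", "MMH-D3", "3T3"],
            "perturbation": ["Per3", "Per3", "Cry2"],
            "label": ["Short", "Short", "Long"]})
        m = phenotype_matrix(calls)
        assert m.loc["Per3", "3T3"] == "Short"
        assert m.shape == (2, 2)
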