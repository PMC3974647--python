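"""Generator: closed-form values, determinism, ensemble structure."""

import numpy as np
import pytest
from scipy import stats

from circaluc import synthetic
from circaluc.errors import ConfigError, InvalidParameterError
from circaluc.synthetic import (NULL_EFFECT, KnockdownEffect, PlateCondition,
                                PlateSimConfig, TraceModelParams, apply_effect,
                                simulate_plate, simulate_qpcr,
                                simulate_single_cell_ensemble, simulate_trace)

from conftest import noiseless_params


class TestSimulateTrace:
    def test_closed_form_peak_and_trough(self):
        p = noiseless_params(b0=10, A=100, T=24, phi=0, tau=3)
        tr = simulate_trace(p, 120, 1 / 6, seed=0)
        assert tr.y[0] == pytest.approx(110.0)
        i12 = np.argmin(np.abs(tr.t - 12.0))
        assert tr.y[i12] == pytest.approx(10 - 100 * np.exp(-12 / 72.0))

    def test_peak_times_follow_phase_convention(self):
        # negligible damping so the envelope does not pull peaks earlier
        p = noiseless_params(T=24, phi=6, tau=1e5)
        tr = simulate_trace(p, 72, 0.01, seed=0)
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(tr.y)
        peak_times = tr.t[peaks]
        assert np.allclose(peak_times, [6.0, 30.0, 54.0], atol=0.05)

    def test_mean_over_whole_periods_is_baseline(self):
        # numeric-integration oracle: the damped cosine nearly averages out
        p = noiseless_params(b0=50.0, T=24, tau=1e5)
        tr = simulate_trace(p, 96 - 1e-9, 0.01, seed=0)
        assert np.mean(tr.y) == pytest.approx(50.0, abs=0.05)

    @pytest.mark.parametrize("bad", [
        dict(T=50.0), dict(T=10.0), dict(tau=-1.0), dict(phi=30.0),
        dict(sigma_rel=-0.1), dict(A=-5.0), dict(b0=np.nan),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(InvalidParameterError):
            simulate_trace(noiseless_params(**bad), 120, 1 / 6, seed=0)

    def test_short_duration_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_trace(noiseless_params(), 24, 1 / 6, seed=0)

    def test_seed_determinism(self):
        p = noiseless_params(sigma_rel=0.05, sigma_abs=1.0)
        a = simulate_trace(p, 120, 1 / 6, seed=7)
        b = simulate_trace(p, 120, 1 / 6, seed=7)
        assert np.array_equal(a.y, b.y)
        c = simulate_trace(p, 120, 1 / 6, seed=8)
        assert not np.array_equal(a.y, c.y)

    def test_poisson_noise_option(self):
        p = noiseless_params(b0=500.0)
        tr = simulate_trace(p, 120, 1 / 6, seed=3, noise="poisson")
        assert np.all(tr.y >= 0) and np.all(tr.y == np.round(tr.y))


class TestSimulatePlate:
    def test_ground_truth_period_dispersion(self, fib_preset, fib_plate):
        true_T = np.array([gt["params"].T
                           for gt in fib_plate.ground_truth.values()])
        assert len(true_T) == 24
        sd = true_T.std(ddof=1)
        # chi-square-ish band around the preset's between-well SD
        assert 0.5 * fib_preset.well_period_sd < sd < 1.6 * fib_preset.well_period_sd

    def test_arrhythmic_effect_zeroes_amplitude(self, fib_preset):
        eff = KnockdownEffect(gene="Bmal1", arrhythmic=True)
        cfg = PlateSimConfig([PlateCondition(fib_preset, eff, n_wells=4)],
                             seed=1)
        rec = simulate_plate(cfg)
        assert all(gt["params"].A == 0.0 for gt in rec.ground_truth.values())

    def test_same_seed_identical_plates(self, fib_preset):
        cfg = PlateSimConfig([PlateCondition(fib_preset, n_wells=6)], seed=5)
        a, b = simulate_plate(cfg), simulate_plate(cfg)
        assert a.wells == b.wells
        for w in a.wells:
            assert np.array_equal(a.traces[w].y, b.traces[w].y)

    def test_overlapping_wells_rejected(self, fib_preset):
        conds = [
            PlateCondition(fib_preset, wells=["A01", "A02"]),
            PlateCondition(fib_preset, wells=["A02", "A03"]),
        ]
        with pytest.raises(ConfigError):
            PlateSimConfig(conds, seed=0).validate()

    def test_too_short_duration_rejected(self, fib_preset):
        cfg = PlateSimConfig([PlateCondition(fib_preset, n_wells=2)],
                             duration=72.0, seed=0)
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_null_effect_reproduces_preset(self, fib_preset):
        assert NULL_EFFECT.is_null
        p = apply_effect(fib_preset.base, NULL_EFFECT)
        assert p == fib_preset.base


class TestSingleCellEnsemble:
    def test_sem_matches_definition(self):
        pre = synthetic.get_preset("scn_neuron_wt")
        cells = simulate_single_cell_ensemble(pre, 106, 96, 1.0, seed=2)
        true_T = np.array([c.meta["true_params"].T for c in cells])
        sem = true_T.std(ddof=1) / np.sqrt(106)
        assert sem == pytest.approx(pre.cell_period_sd / np.sqrt(106), rel=0.35)

    def test_single_cell_flagged(self):
        pre = synthetic.get_preset("scn_neuron_wt")
        cells = simulate_single_cell_ensemble(pre, 1, 96, 1.0, seed=2)
        assert len(cells) == 1 and cells[0].meta["sem_defined"] is False

    def test_separated_presets_distinguishable(self):
        wt = synthetic.get_preset("scn_neuron_wt")       # 27.23 h
        ko = synthetic.get_preset("scn_neuron_per3ko")   # 25.58 h
        a = simulate_single_cell_ensemble(wt, 400, 48, 2.0, seed=3)
        b = simulate_single_cell_ensemble(ko, 400, 48, 2.0, seed=4)
        Ta = [c.meta["true_params"].T for c in a]
        Tb = [c.meta["true_params"].T for c in b]
        _, p = stats.ttest_ind(Ta, Tb, equal_var=False)
        assert p < 1e-6

    def test_mean_converges_to_preset(self):
        # sampling-consistency check at n = 1000
        pre = synthetic.get_preset("scn_neuron_wt")
        cells = simulate_single_cell_ensemble(pre, 1000, 48, 2.0, seed=11)
        true_T = np.array([c.meta["true_params"].T for c in cells])
        sem = true_T.std(ddof=1) / np.sqrt(len(true_T))
        assert abs(true_T.mean() - pre.base.T) < 3 * sem


class TestAntiphase:
    def test_paired_reporters_anticorrelate_at_half_period(self):
        presets = synthetic.load_presets()
        per2 = noiseless_params(**{
            k: getattr(presets["fib_per2"].base, k)
            for k in ("T", "phi")}, tau=50.0)
        bmal = noiseless_params(**{
            k: getattr(presets["fib_bmal1"].base, k)
            for k in ("T", "phi")}, tau=50.0)
        dt = 0.1
        a = simulate_trace(per2, 72, dt, 0).y
        b = simulate_trace(bmal, 72, dt, 0).y
        T = presets["fib_per2"].base.T
        lags = np.arange(0, int(T / dt))
        n = len(a) - int(T / dt)
        corr = np.array([np.corrcoef(a[:n], b[k:k + n])[0, 1] for k in lags])
        # anti-phasic reporters: strongly anticorrelated as recorded,
        # best aligned when one is shifted by about half a period
        assert corr[0] < -0.8
        lag_max = lags[int(np.argmax(corr))] * dt
        assert 0.35 * T < lag_max < 0.65 * T

    def test_paired_presets_have_similar_periods(self):
        presets = synthetic.load_presets()
        for a, b in [("fib_per2", "fib_bmal1"), ("adip_per2", "adip_bmal1"),
                     ("hep_per2", "hep_bmal1")]:
            assert abs(presets[a].base.T - presets[b].base.T) < 1.5


class TestSimulateQpcr:
    def test_known_efficiency_shifts_ct(self):
        tbl = simulate_qpcr(0.75, ct_ns_target=22.0, noise_sd=0.0, seed=0)
        tgt = tbl[tbl["gene"] == "target"]
        ns = tgt[tgt["condition"] == "NS"]["ct"].mean()
        kd = tgt[tgt["condition"] == "KD"]["ct"].mean()
        assert kd - ns == pytest.approx(2.0)   # -log2(0.25)

    def test_zero_efficiency_identical(self):
        tbl = simulate_qpcr(0.0, noise_sd=0.0, seed=0)
        by_cond = tbl.groupby(["gene", "condition"])["ct"].mean().unstack()
        assert np.allclose(by_cond["KD"], by_cond["NS"])

    def test_complete_knockdown_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_qpcr(1.0)

    def test_determinism(self):
        a = simulate_qpcr(0.5, noise_sd=0.3, seed=9)
        b = simulate_qpcr(0.5, noise_sd=0.3, seed=9)
        assert a.equals(b)


def test_effect_library_covers_screen():
    effects = synthetic.load_effects()
    assert len(effects) == 13
    for gene, per_line in effects.items():
        assert set(per_line) == {"3T3", "3T3-L1", "MMH-D3"}
        for eff in per_line.values():
            eff.validate()
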