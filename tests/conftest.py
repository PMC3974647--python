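import numpy as np
import pytest
from hypothesis import settings

from circaluc import (DetrendConfig, PlateCondition, PlateSimConfig,
                      TraceModelParams, fit_plate, get_preset, simulate_plate,
                      simulate_trace)
from circaluc import preprocess

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


def noiseless_params(**overrides) -> TraceModelParams:
    """Transient-free, noise-free model parameters for closed-form checks."""
    base = dict(b0=0.0, b1=0.0, A=100.0, T=25.62, phi=4.0, tau=3.0,
                transient_amp=0.0, transient_tau=6.0,
                sigma_rel=0.0, sigma_abs=0.0)
    base.update(overrides)
    return TraceModelParams(**base)


def detrended_noiseless(params: TraceModelParams, duration=120.0, dt=1 / 6):
    tr = simulate_trace(params, duration, dt, seed=0)
    return preprocess.detrend(tr, DetrendConfig())


@pytest.fixture(scope="session")
def fib_preset():
    return get_preset("fib_per2")


@pytest.fixture(scope="session")
def fib_plate(fib_preset):
    """24-well 3T3 Per2-dLuc plate at default noise, fixed seed."""
    cfg = PlateSimConfig([PlateCondition(fib_preset, n_wells=24)], seed=42)
    return simulate_plate(cfg)


@pytest.fixture(scope="session")
def fib_plate_fits(fib_plate):
    """Full exclude -> detrend -> fit results for the shared plate."""
    return fit_plate(fib_plate)


def grid_search_rss(trace, period_bounds=(16.0, 40.0), n_T=161, n_phi=24,
                    tau_grid=(0.5, 1.0, 2.0, 3.0, 5.0, 10.0)) -> float:
    """Independent brute-force oracle for the damped-sine fit.

    Dense grid over (T, phi) with a coarse damping grid; for each gridpoint
    the model is linear in (c0, c1, A) and solved exactly by least squares.
    Returns the best residual sum of squares found.
    """
    t, y = trace.t, trace.y
    best = np.inf
    for T in np.linspace(*period_bounds, n_T):
        for tau in tau_grid:
            env = np.exp(-(t - t[0]) / (24.0 * tau))
            for phi in np.linspace(0.0, T, n_phi, endpoint=False):
                X = np.column_stack(
                    [np.ones_like(t), t,
                     env * np.cos(2 * np.pi * (t - phi) / T)])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                r = y - X @ beta
                best = min(best, float(r @ r))
    return best
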