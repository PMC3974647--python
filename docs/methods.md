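# Methods

## Generative trace model

Each luminescence recording is modelled as

```
y(t) = b0 + b1·t
     + transient_amp · exp(−t / transient_tau)
     + A · exp(−t / (24·τ)) · cos(2π (t − φ) / T)
     + ε(t)
```

with `t` in hours and `y` in counts/s.

| symbol | meaning | unit | default |
| --- | --- | --- | --- |
| `b0`, `b1` | baseline intercept and drift | counts/s, counts/s/h | 200, −0.3 |
| `A` | initial rhythm amplitude | counts/s | 100 (wells), 30 (neurons) |
| `T` | period | h | per preset (24.4–27.23) |
| `φ` | time of the first cosine peak | h in [0, T) | 4 (Per2), ≈ φ+T/2 (Bmal1) |
| `τ` | damping constant | days | 3 (wells), 2.5 (neurons), 4 (explants) |
| `transient_amp`, `transient_tau` | medium-change burst | counts/s, h | 300, 6 |
| `sigma_rel` | noise SD as fraction of instantaneous amplitude | – | 0.05 (wells), 0.15 (cells) |
| `sigma_abs` | additive noise SD | counts/s | 1.0 (wells), 1.5 (cells) |

Design notes:

* **Damping in days.** τ is parameterized so that the conventional identity
  *damping rate = 1/damping constant* comes out in units of 1/day, the
  standard way these rates are reported.
* **Phase as peak time.** φ is the hour of the first cosine peak rather than
  a radian phase, the convention of single-cell imaging studies; a radian
  conversion is provided (`DampedSineFit.phi_rad`). Note that the peak of
  the *product* envelope × cosine sits slightly earlier than φ; the offset
  is `atan(T / (2π·24·τ)) · T / (2π)` ≈ 0.2 h at default damping.
* **Noise.** Gaussian with SD `sigma_rel·A·exp(−t/(24τ)) + sigma_abs`,
  a high-count approximation to photon-counting statistics where the
  variance tracks the signal. A Poisson option (`noise="poisson"`) draws
  counts directly from the model mean.
* **Transient.** The post-medium-change burst is a single decaying
  exponential. Real transients are messier (they can be non-monotone), but
  since the first 24 h are excluded from analysis only the residual tail
  matters, and by 24 h the default transient has decayed to ~2% of its
  initial value.

### Presets and the effect library

Per-line period means and between-replicate SDs are the published per-line
statistics (microplate lines: mean ± SD over n = 24 clonal wells; SCN
neurons/explants: mean ± SEM converted to SD via `SEM·√n`). No raw
amplitudes, damping constants, baselines or noise magnitudes were ever
published for these lines, so those preset values are package choices
picked once to look like typical reporter recordings (peak signal a few
hundred counts/s, rhythms damping over ~3 days, >95% GOF for persistent
lines).

Knockdown effects are phenomenological: a signed period shift, an
amplitude factor, a factor on the damping *rate*, and an arrhythmic flag.
The shipped library encodes the knockdown-screen phenotype vocabulary with
fixed magnitudes — ±1.5 h for period labels, ×0.3 / ×2.0 for low/high
amplitude, ×3 on the damping rate for rapid damping (τ: 3 d → 1 d), zero
amplitude for arrhythmic. These magnitudes are *labels made quantitative*,
not measured effect sizes.

What the generator deliberately does not emulate: mechanistic clock-gene
dynamics (no ODE network — knockdown effects are imposed, not emergent),
phase drift/desynchronization within a well, non-stationary periods,
plate-edge effects, and instrument artifacts (cosmic-ray spikes, gain
steps). Passing tests therefore demonstrate that the *analysis* is correct
and well-calibrated under the stated statistical structure, not that real
recordings satisfy that structure.

## Fitting

Pipeline per trace: drop samples with `t < 24 h` (configurable), fit an
OLS polynomial baseline (order 1 by default) on the remaining window, and
fit the damped sinusoid to the residuals with bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective, analytic
Jacobian). The fitted model retains a residual linear term `c0 + c1·t` to
absorb imperfect detrending; it is dropped when the input is declared
pre-detrended (`FitConfig(include_trend=False)`).

Numerical choices:

* **Initialization.** Candidate periods are the top 3 local maxima of a
  Lomb–Scargle periodogram restricted to the period bounds (default
  16–40 h, the circadian band), with exact power ties resolved toward the
  shorter period. The amplitude guess is the 95th percentile of |y| over
  the first candidate period; the phase guess is the first smoothed peak;
  the damping guess is a log-linear fit of cycle-peak heights, floored at
  0.5 day.
* **Multistart.** Every candidate period × four phase offsets
  (0, T/4, T/2, 3T/4). Best residual sum of squares wins; near-ties
  (≤ 1e−9 relative) are broken by smaller |c1|, then smaller damping rate —
  an arbitrary but documented rule that makes the fit deterministic.
  On small fixtures the multistart optimum was verified against a dense
  brute-force (T, φ) grid with exact per-gridpoint linear solves.
* **Amplitude referencing.** `A` is the envelope value at the start of the
  fitted window (`t_ref`), so amplitudes from different windows are
  comparable via `amplitude_at(t)`.
* **GOF.** `100·(1 − RSS/TSS)` with TSS the variance of the detrended
  input about its mean, clipped to [0, 100]. The 80% rhythmicity cutoff is
  the conventional threshold for persistent reporter rhythms; at default
  noise, persistent wells sit near 99% and pure-noise traces below 5%.
* **Degenerate inputs.** Flat traces raise a no-signal error at
  initialization; total non-convergence returns a flagged failure object
  rather than raising, so plate and ensemble loops never abort.
* **Amplitude protocol.** The reported screen amplitude is from the
  day-3-to-5 window: raw trace restricted to [48 h, 120 h) (days 1-indexed
  from recording start — the only reading that yields a 3-day window
  containing days 3, 4 and 5), linearly detrended within the window, then
  fitted; the amplitude is referenced to 48 h.

## Phenotype classification

Controls are the rhythmic NS wells of the same cell line. The cascade:

1. **AR** if fewer than 50% of knockdown wells are rhythmic.
2. **RD** if the median damping rate exceeds 2.5× the control mean *and*
   the median GOF of the existing fit evaluated on the final 48 h falls
   below the rhythmicity threshold ("only transiently rhythmic"). RD does
   not terminate the cascade.
3. **Short/Long** if the Welch test against control periods gives
   p < 0.01 and the shift magnitude is ≥ 0.5 h.
4. **LA/HA** if the median amplitude ratio to control is < 0.5 / > 1.5.
   For non-RD calls the ratio uses day-3-to-5 amplitudes. For RD calls it
   uses the fitted window-start amplitude instead: rapid damping
   mechanically collapses the day-3-to-5 amplitude, and using it would
   attach a spurious LA to every RD call.
5. **WT** otherwise.

Period, RD and amplitude labels combine (canonical order: period, RD,
amplitude — e.g. "Short, RD", "RD, LA"); AR and WT are standalone. All
cutoffs live in `PhenotypeRules`; historical screens assigned these labels
by expert judgment, so the defaults are deliberate, conservative artifact
choices rather than community standards. No multiple-testing correction is
applied across a screen (per-comparison testing, matching single-panel
practice).

## Single cells

Identical pipeline with a relaxed 70% GOF threshold (dimmer, noisier
traces). Ensemble statistics (mean, SD, SEM of period) cover rhythmic
cells only — the field convention — and `n` reports that count. Welch
comparisons use raw per-cell periods when available and the closed form
from (mean, SEM, n) otherwise. For the reference genotype comparison the
closed form from the printed summaries gives t ≈ 6.15, p ≈ 6×10⁻⁹; the
package reports the computed p rather than forcing any smaller printed
bound (which is only reachable from raw per-cell data).

## qPCR

Classic ΔΔCt with amplification efficiency fixed at 2 per cycle:
ΔCt = Ct_target − Ct_Gapdh per sample, NS replicates averaged on the ΔCt
scale (geometric-mean convention, making NS ≡ 100% by construction), KD
replicates exponentiated individually and summarized as mean ± SD percent
of control. Single-replicate SD is reported as not available. No standard
curves or multi-reference normalization.

## Problem sizes

The shipped validation runs use: 24-well plates at 10-min sampling over
120 h for the microplate presets; 50 wells for the GOF benchmark; the full
13-gene × 3-model screen at 4 knockdown + 8 control wells per condition;
106/157-cell neuron ensembles at 30-min sampling over 144 h; 5 explants at
10-min sampling over 144 h; 200 traces per line for parameter-recovery
statistics; 25 small fixtures for the brute-force oracle comparison. These
sizes mirror the reference experiments where sizes were stated and are
otherwise chosen to give stable Monte-Carlo estimates.

## Known limitations

* The damped cosine assumes a single stationary period; period lability or
  multi-component rhythms (common in weakly coupled cells) bias τ.
* GOF-based rhythmicity is not a significance test; for formal rhythm
  detection a permutation or harmonic-regression test would be needed.
* The classifier inherits the noise model's optimism: with heavier-tailed
  real noise the Welch test's nominal p-values are approximate.
* ΔΔCt assumes perfect doubling per cycle; primer efficiencies below 2
  inflate apparent knockdown.
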