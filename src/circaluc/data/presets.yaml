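# Cell-line presets and knockdown-effect library for the synthetic generator.
#
# Human-editable. Schema:
#   presets: name -> {cell_line, reporter, well_period_sd, [cell_period_sd], base}
#     base holds the generative trace model:
#       b0   baseline intercept, counts/s
#       b1   baseline slope, counts/s per h
#       A    initial rhythm amplitude, counts/s
#       T    period, h (circadian band 16-40 h)
#       phi  time of first cosine peak, h in [0, T)
#       tau  amplitude damping constant, days (envelope exp(-t/(24*tau)))
#       transient_amp / transient_tau  medium-change transient, counts/s and h
#       sigma_rel  noise SD as a fraction of instantaneous rhythm amplitude
#       sigma_abs  additive noise SD, counts/s
#   effects: gene -> {shrna_id, kd_efficiency, by_cell_line}
#     by_cell_line: cell line -> {label, delta_T, amp_factor, damping_factor,
#                                 arrhythmic}; omitted fields default to the
#     null effect (delta_T 0, amp_factor 1, damping_factor 1, arrhythmic false).
#     `label` is the phenotype the effect encodes, used as simulation ground
#     truth when benchmarking the classifier.
#
# Period means/SDs are the published per-line statistics (n = 24 microplate
# wells per clonal line; SCN explants and dissociated neurons reported as
# mean +/- SEM with n = 5 / 106 / 157 — SDs here are SEM*sqrt(n)).
# Amplitudes, damping constants, baselines and noise levels are package
# choices: no raw amplitude or damping values were published for any line.

presets:
  fib_per2:
    cell_line: "3T3"
    reporter: "Per2-dLuc"
    well_period_sd: 0.21
    base: {b0: 200.0, b1: -0.3, A: 100.0, T: 25.62, phi: 4.0, tau: 3.0,
           transient_amp: 300.0, transient_tau: 6.0,
           sigma_rel: 0.05, sigma_abs: 1.0}
  fib_bmal1:
    cell_line: "3T3"
    reporter: "Bmal1-dLuc"
    well_period_sd: 0.31
    base: {b0: 200.0, b1: -0.3, A: 100.0, T: 26.72, phi: 17.36, tau: 3.0,
           transient_amp: 300.0, transient_tau: 6.0,
           sigma_rel: 0.05, sigma_abs: 1.0}
  adip_per2:
    cell_line: "3T3-L1"
    reporter: "Per2-dLuc"
    well_period_sd: 0.32
    base: {b0: 200.0, b1: -0.3, A: 100.0, T: 24.60, phi: 4.0, tau: 3.0,
           transient_amp: 300.0, transient_tau: 6.0,
           sigma_rel: 0.05, sigma_abs: 1.0}
  adip_bmal1:
    cell_line: "3T3-L1"
    reporter: "Bmal1-dLuc"
    well_period_sd: 0.19
    base: {b0: 200.0, b1: -0.3, A: 100.0, T: 25.01, phi: 16.50, tau: 3.0,
           transient_amp: 300.0, transient_tau: 6.0,
           sigma_rel: 0.05, sigma_abs: 1.0}
  hep_per2:
    cell_line: "MMH-D3"
    reporter: "Per2-dLuc"
    well_period_sd: 0.18
    base: {b0: 200.0, b1: -0.3, A: 100.0, T: 24.49, phi: 4.0, tau: 3.0,
           transient_amp: 300.0, transient_tau: 6.0,
           sigma_rel: 0.05, sigma_abs: 1.0}
  hep_bmal1:
    cell_line: "MMH-D3"
    reporter: "Bmal1-dLuc"
    well_period_sd: 0.13
    base: {b0: 200.0, b1: -0.3, A: 100.0, T: 25.33, phi: 16.67, tau: 3.0,
           transient_amp: 300.0, transient_tau: 6.0,
           sigma_rel: 0.05, sigma_abs: 1.0}

  # SCN explants: slow-damping tissue-level rhythms, plate-like noise.
  scn_explant_wt:
    cell_line: "SCN-explant"
    reporter: "mPer2Luc"
    well_period_sd: 0.3801   # 0.17 SEM * sqrt(5)
    base: {b0: 150.0, b1: -0.2, A: 100.0, T: 24.40, phi: 4.0, tau: 4.0,
           transient_amp: 200.0, transient_tau: 6.0,
           sigma_rel: 0.05, sigma_abs: 1.0}
  scn_explant_per3ko:
    cell_line: "SCN-explant"
    reporter: "mPer2Luc"
    well_period_sd: 0.4025   # 0.18 SEM * sqrt(5)
    base: {b0: 150.0, b1: -0.2, A: 100.0, T: 23.78, phi: 4.0, tau: 4.0,
           transient_amp: 200.0, transient_tau: 6.0,
           sigma_rel: 0.05, sigma_abs: 1.0}

  # Dissociated SCN neurons: dim single-cell signals, broad period
  # dispersion between cells, noticeably noisier than plate wells.
  scn_neuron_wt:
    cell_line: "SCN-neuron"
    reporter: "mPer2Luc"
    well_period_sd: 2.4708
    cell_period_sd: 2.4708   # 0.24 SEM * sqrt(106)
    base: {b0: 30.0, b1: -0.05, A: 30.0, T: 27.23, phi: 4.0, tau: 2.5,
           transient_amp: 60.0, transient_tau: 6.0,
           sigma_rel: 0.15, sigma_abs: 1.5}
  scn_neuron_per3ko:
    cell_line: "SCN-neuron"
    reporter: "mPer2Luc"
    well_period_sd: 1.5036
    cell_period_sd: 1.5036   # 0.12 SEM * sqrt(157)
    base: {b0: 30.0, b1: -0.05, A: 30.0, T: 25.58, phi: 4.0, tau: 2.5,
           transient_amp: 60.0, transient_tau: 6.0,
           sigma_rel: 0.15, sigma_abs: 1.5}

# Knockdown-effect library. One entry per clock gene, one sub-entry per
# cellular model; labels use the screen vocabulary
# (WT / Short / Long / LA / HA / RD / AR, combinable).
# Magnitudes encode the vocabulary, not measured values: period labels are
# +/-1.5 h shifts, LA/HA are x0.3 / x2.0 amplitude, RD triples the damping
# rate (tau 3 d -> 1 d), AR zeroes the rhythm.
effects:
  Bmal1:
    shrna_id: sh15
    kd_efficiency: 0.85
    by_cell_line:
      "3T3":    {label: "AR", arrhythmic: true}
      "3T3-L1": {label: "RD", damping_factor: 3.0}
      "MMH-D3": {label: "AR", arrhythmic: true}
  Bmal2:
    shrna_id: sh21
    kd_efficiency: 0.80
    by_cell_line:
      "3T3":    {label: "WT"}
      "3T3-L1": {label: "WT"}
      "MMH-D3": {label: "WT"}
  Clock:
    shrna_id: sh33
    kd_efficiency: 0.80
    by_cell_line:
      "3T3":    {label: "AR", arrhythmic: true}
      "3T3-L1": {label: "RD", damping_factor: 3.0}
      "MMH-D3": {label: "AR", arrhythmic: true}
  Npas2:
    shrna_id: sh41
    kd_efficiency: 0.80
    by_cell_line:
      "3T3":    {label: "WT"}
      "3T3-L1": {label: "WT"}
      "MMH-D3": {label: "WT"}
  Cry1:
    shrna_id: sh52
    kd_efficiency: 0.85
    by_cell_line:
      "3T3":    {label: "RD", damping_factor: 3.0}
      "3T3-L1": {label: "RD", damping_factor: 3.0}
      "MMH-D3": {label: "LA", amp_factor: 0.3}
  Cry2:
    shrna_id: sh58
    kd_efficiency: 0.85
    by_cell_line:
      "3T3":    {label: "Long", delta_T: 1.5}
      "3T3-L1": {label: "Long", delta_T: 1.5}
      "MMH-D3": {label: "Long, HA", delta_T: 1.5, amp_factor: 2.0}
  Per1:
    shrna_id: sh62
    kd_efficiency: 0.80
    by_cell_line:
      "3T3":    {label: "WT"}
      "3T3-L1": {label: "WT"}
      "MMH-D3": {label: "Short, LA", delta_T: -1.5, amp_factor: 0.3}
  Per2:
    shrna_id: sh67
    kd_efficiency: 0.80
    by_cell_line:
      "3T3":    {label: "Short", delta_T: -1.5}
      "3T3-L1": {label: "WT"}
      "MMH-D3": {label: "Short, LA", delta_T: -1.5, amp_factor: 0.3}
  Per3:
    shrna_id: sh74
    kd_efficiency: 0.85
    by_cell_line:
      "3T3":    {label: "Short", delta_T: -1.5}
      "3T3-L1": {label: "Short", delta_T: -1.5}
      "MMH-D3": {label: "Short", delta_T: -1.5}
  Fbxl3:
    shrna_id: sh81
    kd_efficiency: 0.80
    by_cell_line:
      "3T3":    {label: "Long, LA", delta_T: 1.5, amp_factor: 0.3}
      "3T3-L1": {label: "Long", delta_T: 1.5}
      "MMH-D3": {label: "RD, LA", damping_factor: 3.0, amp_factor: 0.3}
  Nr1d1:
    shrna_id: sh92
    kd_efficiency: 0.80
    by_cell_line:
      "3T3":    {label: "WT"}
      "3T3-L1": {label: "WT"}
      "MMH-D3": {label: "WT"}
  Nr1d2:
    shrna_id: sh96
    kd_efficiency: 0.80
    by_cell_line:
      "3T3":    {label: "LA", amp_factor: 0.3}
      "3T3-L1": {label: "Short", delta_T: -1.5}
      "MMH-D3": {label: "Short", delta_T: -1.5}
  E4bp4:
    shrna_id: sh99
    kd_efficiency: 0.80
    by_cell_line:
      "3T3":    {label: "Short, RD", delta_T: -1.5, damping_factor: 3.0}
      "3T3-L1": {label: "LA", amp_factor: 0.3}
      "MMH-D3": {label: "Short", delta_T: -1.5}
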