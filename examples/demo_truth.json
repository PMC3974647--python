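{
 "A01": {
  "preset": "hep_per2",
  "gene": "NS",
  "params": {
   "b0": 200.0,
   "b1": -0.3,
   "A": 100.0,
   "T": 24.488771179624205,
   "phi": 4.0,
   "tau": 3.0,
   "transient_amp": 300.0,
   "transient_tau": 6.0,
   "sigma_rel": 0.05,
   "sigma_abs": 1.0
  }
 },
 "A02": {
  "preset": "hep_per2",
  "gene": "NS",
  "params": {
   "b0": 200.0,
   "b1": -0.3,
   "A": 100.0,
   "T": 24.38539023157747,
   "phi": 4.0,
   "tau": 3.0,
   "transient_amp": 300.0,
   "transient_tau": 6.0,
   "sigma_rel": 0.05,
   "sigma_abs": 1.0
  }
 },
 "A03": {
  "preset": "hep_per2",
  "gene": "NS",
  "params": {
   "b0": 200.0,
   "b1": -0.3,
   "A": 100.0,
   "T": 24.59524062864262,
   "phi": 4.0,
   "tau": 3.0,
   "transient_amp": 300.0,
   "transient_tau": 6.0,
   "sigma_rel": 0.05,
   "sigma_abs": 1.0
  }
 },
 "A04": {
  "preset": "hep_per2",
  "gene": "Per3",
  "params": {
   "b0": 200.0,
   "b1": -0.3,
   "A": 100.0,
   "T": 22.92350061208406,
   "phi": 4.0,
   "tau": 3.0,
   "transient_amp": 300.0,
   "transient_tau": 6.0,
   "sigma_rel": 0.05,
   "sigma_abs": 1.0
  }
 },
 "A05": {
  "preset": "hep_per2",
  "gene": "Per3",
  "params": {
   "b0": 200.0,
   "b1": -0.3,
   "A": 100.0,
   "T": 22.829771157865448,
   "phi": 4.0,
   "tau": 3.0,
   "transient_amp": 300.0,
   "transient_tau": 6.0,
   "sigma_rel": 0.05,
   "sigma_abs": 1.0
  }
 },
 "A06": {
  "preset": "hep_per2",
  "gene": "Per3",
  "params": {
   "b0": 200.0,
   "b1": -0.3,
   "A": 100.0,
   "T": 22.954461990609637,
   "phi": 4.0,
   "tau": 3.0,
   "transient_amp": 300.0,
   "transient_tau": 6.0,
   "sigma_rel": 0.05,
   "sigma_abs": 1.0
  }
 }
}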