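# A six-group synthetic twin study: zygosity (MZ/DZ) x sex twin pairs plus
# general-population (GP) cohorts. Parameters express the usual pattern:
# twins face less frequent / smaller extrinsic challenges than the general
# population, MZ more so than DZ, and women less than men; intrinsic
# parameters are nearly shared. Group sizes are desk-scale; raise n_pairs/n
# (and bootstrap B) for smoother results.
seed: 42
truncation_age: 10
interval_width: 1
max_age: 120
dt: 0.05

groups:
  MZ-M: {r: 0.0130, s: 0.0126, lam: 0.0470, beta: 0.370, n_pairs: 1000, paired: true}
  MZ-F: {r: 0.0133, s: 0.0126, lam: 0.0380, beta: 0.380, n_pairs: 1000, paired: true}
  DZ-M: {r: 0.0135, s: 0.0126, lam: 0.0450, beta: 0.385, n_pairs: 1800, paired: true}
  DZ-F: {r: 0.0134, s: 0.0126, lam: 0.0400, beta: 0.390, n_pairs: 1800, paired: true}
  GP-M: {r: 0.0135, s: 0.0126, lam: 0.0449, beta: 0.400, n: 5000}
  GP-F: {r: 0.0134, s: 0.0126, lam: 0.0400, beta: 0.398, n: 5000}

fit:
  bias_correction: simulate
  B: 50
  n_cal: 2000

bootstrap:
  fraction: 0.75
  B: 1000          # --fast caps this at 50
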