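# AML maintenance-chemotherapy case study, evaluated under the null
# hypothesis (log_hazard_ratio = 0: both arms share the control hazard).
# Selection bias eta = 0.2*|ln 0.4003| = 0.1831 acts through the
# convergence guessing strategy; the improving logarithmic time trend
# theta = 0.125*ln(0.4003) = -0.1144 reflects expected progress in
# induction therapy. Time unit: weeks.
design:
  n: 64
  accrual_length: 18
  total_length: 52
  alpha: 0.05
  dropout_rate: 0.0077
  baseline_hazard: 0.0431
  log_hazard_ratio: 0.0
bias:
  eta: 0.1831
  theta: -0.1144
  trend: logarithmic
procedures:
  - CR
  - EBC(2/3)
  - PBR(4)
  - PBR(8)
  - PBR(16)
  - RAR
  - MP(3)
  - MP(7)
  - MP(11)
  - BSD(3)
  - BSD(7)
  - BSD(11)
  - CHEN(3, 2/3)
  - CHEN(7, 2/3)
  - CHEN(11, 2/3)
monte_carlo:
  sequences: 7500
  seed: 1
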