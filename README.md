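# ranbias

Evaluation of randomization procedures for two-arm survival trials in the
presence of **selection bias** and **chronological bias**.

When blinding is imperfect, an investigator who knows past allocations can
guess upcoming ones and preferentially enroll healthier or sicker patients
(selection bias); independently, outcomes may drift over enrollment order
through learning curves or criteria amendments (chronological bias). How much
these distortions inflate the type I error of the log-rank test depends on the
randomization procedure: designs that force balance are predictable and
selection-prone, while very random designs tolerate imbalance and are
trend-prone. `ranbias` quantifies this trade-off so that trial statisticians
can choose a procedure for the study at hand.

## Model

Patient `i` under randomization sequence `z ∈ {0,1}^n` (0 = control,
1 = experimental) has hazard

```
h_i(t, z) = h_C(t) · exp( z_i ln(HR) + η_i(z) + θ_i )
```

with `η_i(z) = η · sgn(N_E(i−1) − N_C(i−1))` the selection-bias shift under
the Blackwell–Hodges convergence guessing strategy, and `θ_i` a stepwise,
linear or logarithmic trend in enrollment order. Conditionally on `z`, the
log-rank statistic is asymptotically `N(E_bias(z), 1)` with

```
E_bias(z) = √n · ∫ (φ − π) V dt / sqrt( ∫ π(1 − π) V dt ),
```

where `π(t,z)` and `φ(t,z)` are the survival- and density-weighted expected
control fractions at risk and `V(t,z)` is the density of observed event times
under uniform accrual over `[0, A]`, study end at `F`, and exponential
dropout. The per-sequence type I error of the two-sided level-α test is
`1 − Φ(q_{α/2} − E_bias) + Φ(−q_{α/2} − E_bias)`; a randomization procedure is
summarized by the mean and SD of this quantity over a Monte-Carlo sample of
its sequences.

Seven procedure families are supported — `CR`, `EBC(p)`, `RAR`, `PBR(k)`,
`MP(b)` (exactly uniform via path-count sampling), `BSD(b)` and
`CHEN(b, p)` — with exact per-sequence probabilities for small-n validation,
plus a patient-level trial simulator with the exact log-rank statistic as a
brute-force cross-check of the approximation.

## Worked example

Score one permuted-block sequence under the AML case study (n = 64, accrual
18 weeks, study length 52 weeks, control hazard 0.0431/week, dropout
0.0077/week, null treatment effect; selection bias η = 0.1831, logarithmic
trend θ = −0.1144):

```python
import numpy as np
from ranbias import (BiasSpec, StudyDesign, expected_bias, generate_sequence,
                     parse_procedure, rejection_probability, total_offsets,
                     empirical_rejection_rate)

design = StudyDesign(n=64, accrual_length=18, total_length=52, alpha=0.05,
                     dropout_rate=0.0077, baseline_hazard=0.0431,
                     log_hazard_ratio=0.0)
bias = BiasSpec(eta=0.1831, theta=-0.1144, trend="logarithmic")

rng = np.random.default_rng(42)
z = generate_sequence(parse_procedure("PBR(4)"), design.n, rng)
effects = total_offsets(z, design, bias)
e = expected_bias(z, effects, design)
print(f"E_bias = {e:.3f}, type I error = {rejection_probability(e, design.alpha):.3f}")
print(f"simulated rejection rate = {empirical_rejection_rate(z, effects, design, 10_000, rng):.3f}")
```

prints

```
E_bias = 0.413, type I error = 0.070
simulated rejection rate = 0.071
```

The bias model shifts the mean of this sequence's log-rank statistic by 0.41
standard deviations, inflating the nominal 5% level to 7.0%; the
patient-level simulator confirms the asymptotic value.

The full procedure comparison runs from the command line:

```sh
ranbias run --config examples/aml_case_study.yaml --out aml_table.csv
```

```
    procedure  n_sequences  mean_type1  sd_type1  excluded  seed
           CR         7500       0.052     0.002         0     1
     EBC(2/3)         7500       0.062     0.007         0     1
       PBR(4)         7500       0.081     0.005         0     1
       PBR(8)         7500       0.070     0.005         0     1
      PBR(16)         7500       0.062     0.005         0     1
          RAR         7500       0.054     0.004         0     1
        MP(3)         7500       0.063     0.005         0     1
        MP(7)         7500       0.055     0.004         0     1
       MP(11)         7500       0.054     0.004         0     1
       BSD(3)         7500       0.055     0.003         0     1
       BSD(7)         7500       0.052     0.002         0     1
      BSD(11)         7500       0.052     0.002         0     1
 CHEN(3, 2/3)         7500       0.065     0.006         0     1
 CHEN(7, 2/3)         7500       0.062     0.006         0     1
CHEN(11, 2/3)         7500       0.062     0.007         0     1
```

Mean type I error is the column to rank procedures by: under this bias
scenario small permuted blocks are the most inflated (8.1%), while complete
randomization and big stick designs with a generous imbalance cap stay near
the nominal 5%. `ranbias oracle-check --config <file>` validates the
approximation against simulated trials.

## Layout

- `src/ranbias/design.py` — trial configuration and validation
- `src/ranbias/procedures.py` — sequence generation and exact probabilities
- `src/ranbias/bias.py` — selection-bias and time-trend offsets
- `src/ranbias/survival.py` — survival, density and censoring functions
- `src/ranbias/approximation.py` — `E_bias` and rejection probabilities
- `src/ranbias/oracle.py` — trial simulator and exact log-rank statistic
- `src/ranbias/evaluate.py` — Monte-Carlo comparison pipeline
- `src/ranbias/cli.py` — `ranbias run` / `ranbias oracle-check`
- `docs/methods.md` — modeling assumptions and numerical choices
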