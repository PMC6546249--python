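# Methods

## Bias model

The package models a randomized, two-arm, 1:1 parallel-group survival trial.
Patients enter sequentially, uniformly over an accrual period `[0, A]`, are
treated immediately, and are followed until event, random dropout, or the end
of the study at calendar time `F > A`. Conditional on the realized allocation
sequence `z ∈ {0,1}^n`, patient `i`'s hazard is

    h_i(t, z) = h_C(t) · exp( z_i · ln(HR) + η_i(z) + θ_i ),

a proportional-hazards perturbation of the control hazard. The two bias terms
act additively on the log-hazard scale:

- **Selection bias.** All past allocations are assumed unblinded. The
  investigator guesses the next allocation with the convergence strategy —
  predict the currently under-represented arm — and preferentially enrolls
  accordingly, shifting patient `i`'s log-hazard by
  `η_i(z) = η · sgn(N_E(i−1) − N_C(i−1))`. The first patient is never
  biased. With `η > 0` the shift points in the direction that inflates the
  type I error for balance-targeting procedures.
- **Chronological bias.** An unobserved trend in enrollment order `i` (not
  calendar time): stepwise `θ·1{i > k}`, linear `θ·(i−1)/(n−1)`, or
  logarithmic `θ·ln(i)/ln(n)`. Negative `θ` means outcomes improve over the
  course of the trial.

Both effects can be given absolutely or as fractions of the anticipated
`|ln HR|` (the bundled AML example uses 0.2 and 0.125). Type I error is
evaluated under the null by setting `ln HR = 0` while keeping the baseline
hazard; the bias terms are parameterized separately and persist.

## Asymptotic distribution of the log-rank statistic

Conditionally on `z`, and for bias effects of the same `O(n^{-1/2})` order as
a local alternative, the log-rank statistic is asymptotically normal with
variance 1 and mean

    E_bias(z) = √n · I₁ / √I₂,
    I₁ = ∫₀^F (φ(t,z) − π(t,z)) V(t,z) dt,
    I₂ = ∫₀^F π(t,z)(1 − π(t,z)) V(t,z) dt,

where, with `S_i` and `f_i` the per-patient survival and density functions,

    π(t,z) = Σ(1−z_i) S_i(t) / Σ S_i(t),
    φ(t,z) = Σ(1−z_i) f_i(t) / Σ f_i(t),
    V(t,z) = (1/n) Σ f_i(t) · S_cen(t) · S_uni(t).

`S_cen(t) = exp(−λ_cen t)` is random-dropout survival and `S_uni` the
survival function of the administrative censoring time induced by uniform
accrual (1 before `F−A`, linear to 0 at `F`). `V` vanishes beyond `F`, so the
integrals run over `[0, F]`. The two-sided rejection probability at level α
is `1 − Φ(q − E) + Φ(−q − E)` with `q = Φ⁻¹(1 − α/2)`; it equals α exactly at
`E = 0`, which makes the null calibration of the whole pipeline testable to
numerical precision. A one-sided variant is available behind a flag.

The baseline is exponential (`S_i(t) = exp(−λ_C m_i t)` with
`m_i = exp(offset_i)`), matching both bundled study settings; the formulas
above are semi-parametric, but only the exponential baseline is exercised by
the tests.

## Randomization procedures

`CR`, `EBC(p)`, `RAR`, `PBR(k)`, `MP(b)`, `BSD(b)` and `CHEN(b, p)` are
implemented as samplers plus exact probability mass functions over `{0,1}^n`.
Design choices worth noting:

- **MP(b)** is the final-balance variant: uniform over balanced sequences
  whose running imbalance never exceeds `b`. Sampling is by sequential path
  counts — a dynamic program over (position, imbalance) with exact integer
  arithmetic gives the number of admissible completions, and the next
  assignment is drawn with probability proportional to the completions it
  leaves. This is exactly uniform, unlike rejection sampling, and costs
  `O(n·b)` per sequence after a cached `O(n·b)` table build.
- **EBC/CHEN** use probability `p` for the under-represented arm and a fair
  coin at zero imbalance; at a forced CHEN/BSD step the imbalance is `±b ≠ 0`
  so no tie-handling is needed.
- **PBR(k)** with `n` not a multiple of `k` closes with a random allocation
  rule on the remainder (standard practice; never triggered in the bundled
  examples).
- Probabilities are exact `Fraction`s (with `p` held as a rational), so
  small-`n` enumeration tests compare empirical frequencies against exact
  masses with no floating-point slack.

## Monte-Carlo evaluation

A procedure is summarized by the mean and sample SD (`M−1` denominator) of
the per-sequence rejection probability over `M` freshly drawn sequences. The
sample size can be fixed (the bundled case study uses 7,500) or derived from
a 500-sequence pilot via the precision rule
`M = ⌈(z_{(1+c)/2} · sd / ε)²⌉` with default `ε = 2·10⁻⁴` and `c = 0.995`.
Degenerate single-arm sequences — possible only under complete randomization,
with probability `2^{1−n}` — leave the log-rank test undefined; they are
excluded from the summary and counted in the `excluded` column.

Each procedure draws from its own random stream seeded by the master seed
together with the bytes of the canonical procedure label, so results are
invariant to adding, removing or reordering procedures in a configuration.

## Patient-level simulator

The oracle module draws complete trials from the same model — exponential
event times with per-patient rates `λ_C·m_i`, exponential dropout,
administrative censoring at `F − entry` — and computes the log-rank statistic
with `e_j(1−e_j)` variance terms per distinct event time (the form whose
square is compared in tests against an independent implementation via the
optional hypergeometric variant). It serves as the brute-force check of the
asymptotic approximation: across random case-study sequences the mean
absolute deviation between approximate and empirical (10⁴-replicate)
rejection probabilities is below 0.01.

What the simulator emulates: uniform staggered entry, proportional per-patient
bias effects constant over each patient's follow-up, independent exponential
dropout. What it does not: covariates, non-proportional or within-patient
time-varying bias, interim looks, ties (the continuous model makes them
measure-zero; the statistic still groups tied times for rounded file input).
Passing tests therefore validate the asymptotics under this generative model,
not robustness to model misspecification in real data.

## Numerical choices

- **Quadrature.** `E_bias` integrands are smooth except for a kink at
  `t = F − A` where administrative censoring sets in. The default rule is
  Gauss–Legendre with 64 nodes on each of `[0, F−A]` and `[F−A, F]`; on the
  bundled settings it agrees with adaptive Gauss–Kronrod quadrature
  (tolerance 1e−9) to machine precision, and doubling the node count moves
  results by far less than 1e−6. A batched implementation evaluates thousands
  of sequences at once in chunks of 256 to bound memory.
- **Degenerate inputs.** Single-arm sequences raise or are flagged `nan`
  depending on the entry point; `I₂ = 0` cannot otherwise occur because `π`
  is strictly interior on a positive-measure set for any two-arm sequence.
- **Determinism.** All randomness flows from `numpy` `Generator` objects;
  a single integer seed reproduces sequences, simulations and summary tables
  byte-for-byte.

## Problem sizes in the test suite

The acceptance-level tests use 2,000 sequences per procedure for the
case-study means (Monte-Carlo SE of each mean ≤ 1.6·10⁻⁴, comfortably inside
the ±0.003 comparison band), 1,000 for ordering checks, 10⁵ draws at `n = 8`
for goodness of fit against exact sequence probabilities, and 50 sequences ×
10⁴ replicates for the approximation-vs-simulation check. The acceptance
script uses the full 7,500 sequences per procedure.

## Known limitations

- The guessing model is the convergence strategy only; strategies that use a
  procedure's true conditional allocation probabilities are not implemented.
- Allocation ratios other than 1:1, urn and covariate-adaptive designs, and
  power under the alternative as a selection metric are out of scope.
- The asymptotic approximation degrades at very small `n`; the bundled
  cross-checks exercise `n = 64` and above.
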