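import math

import numpy as np
import pytest

from ranbias import (
    BiasSpec,
    DegenerateSequenceError,
    RandomizationSequence,
    StudyDesign,
    evaluate_sequence,
    expected_bias,
    expected_bias_batch,
    mixture_density,
    phi_fn,
    pi_fn,
    rejection_probability,
    simulate_statistics,
    total_offsets,
)
from ranbias.bias import PatientEffects


def make_effects(offsets):
    offsets = np.asarray(offsets, dtype=float)
    return PatientEffects(
        selection=np.zeros_like(offsets), trend=np.zeros_like(offsets), total_offset=offsets
    )


def tiny_design(n=2, baseline=1.0):
    return StudyDesign(
        n=n,
        accrual_length=0.0,
        total_length=1000.0,
        alpha=0.05,
        dropout_rate=0.0,
        baseline_hazard=baseline,
        log_hazard_ratio=0.0,
    )


def seq(*bits):
    return RandomizationSequence(np.array(bits, dtype=np.int8))


# --- pi and phi -------------------------------------------------------------


def test_pi_equals_control_fraction_when_offsets_equal(case_study_design):
    z = seq(*([0] * 40 + [1] * 24))
    eff = make_effects(np.full(64, 0.37))
    t = np.linspace(0, 50, 7)
    np.testing.assert_allclose(pi_fn(t, z, eff, case_study_design), 40 / 64)
    np.testing.assert_allclose(phi_fn(t, z, eff, case_study_design), 40 / 64)


def test_pi_at_zero_is_control_fraction(case_study_design):
    z = seq(*([0, 1] * 32))
    eff = make_effects(np.linspace(-0.3, 0.3, 64))
    assert pi_fn(0.0, z, eff, case_study_design) == pytest.approx(0.5)


def test_pi_two_patient_closed_form():
    # control offset 0, experimental offset ln 2, unit baseline hazard, t = 1
    value = pi_fn(1.0, seq(0, 1), make_effects([0.0, math.log(2)]), tiny_design())
    assert value == pytest.approx(math.exp(-1) / (math.exp(-1) + math.exp(-2)))


def test_phi_at_zero_weights_by_hazards():
    value = phi_fn(0.0, seq(0, 1), make_effects([0.0, math.log(2)]), tiny_design())
    assert value == pytest.approx(1 / 3)


def test_phi_exceeds_pi_when_control_hazard_larger():
    """Two-group closed form: higher-hazard controls die earlier, so the
    density-weighted control share dominates the survival-weighted one."""
    design = tiny_design(n=4, baseline=0.05)
    z = seq(0, 0, 1, 1)
    eff = make_effects([0.4, 0.4, 0.0, 0.0])
    t = np.linspace(0.5, 60, 25)
    assert np.all(phi_fn(t, z, eff, design) > pi_fn(t, z, eff, design))


# --- mixture density --------------------------------------------------------


def test_mixture_density_vanishes_after_study_end(case_study_design):
    z = seq(*([0, 1] * 32))
    eff = make_effects(np.zeros(64))
    assert mixture_density(52.0, z, eff, case_study_design) == 0.0
    assert mixture_density(80.0, z, eff, case_study_design) == 0.0


def test_mixture_density_integrates_to_one_without_censoring():
    design = tiny_design(n=2, baseline=0.05)
    z = seq(0, 1)
    eff = make_effects([0.0, 0.2])
    t = np.linspace(0, 1000, 20001)
    total = np.trapezoid(mixture_density(t, z, eff, design), t)
    assert total == pytest.approx(1.0, abs=1e-6)


def test_mixture_integral_matches_observed_event_fraction(
    case_study_design, case_study_bias, rng
):
    """int V equals the expected fraction of patients with observed events."""
    z = seq(*rng.permutation([0] * 32 + [1] * 32))
    eff = total_offsets(z, case_study_design, case_study_bias)
    t = np.linspace(0, 52, 5001)
    expected_fraction = np.trapezoid(mixture_density(t, z, eff, case_study_design), t)
    from ranbias import simulate_trial

    reps = 4000
    fractions = np.empty(reps)
    for r in range(reps):
        trial = simulate_trial(z, eff, case_study_design, rng)
        fractions[r] = trial.n_events / case_study_design.n
    se = fractions.std(ddof=1) / math.sqrt(reps)
    assert abs(fractions.mean() - expected_fraction) < 4 * se + 1e-3


# --- expected bias ----------------------------------------------------------


def test_expected_bias_zero_without_bias(case_study_design):
    z = seq(*([0, 1] * 32))
    eff = total_offsets(z, case_study_design, BiasSpec())
    assert abs(expected_bias(z, eff, case_study_design)) < 1e-12


def test_degenerate_sequence_is_flagged(case_study_design):
    z = seq(*([1] * 64))
    eff = total_offsets(z, case_study_design, BiasSpec())
    with pytest.raises(DegenerateSequenceError):
        expected_bias(z, eff, case_study_design)
    evaluation = evaluate_sequence(z, eff, case_study_design)
    assert evaluation.degenerate and math.isnan(evaluation.e_bias)


def test_fixed_rule_agrees_with_adaptive_quadrature(
    case_study_design, case_study_bias, rng
):
    for _ in range(5):
        z = seq(*rng.integers(0, 2, 64))
        if z.degenerate:
            continue
        eff = total_offsets(z, case_study_design, case_study_bias)
        fixed = expected_bias(z, eff, case_study_design)
        adaptive = expected_bias(z, eff, case_study_design, adaptive=True)
        assert fixed == pytest.approx(adaptive, abs=1e-9)


def test_quadrature_is_converged(case_study_design, case_study_bias, rng):
    z = seq(*rng.permutation([0] * 32 + [1] * 32))
    eff = total_offsets(z, case_study_design, case_study_bias)
    coarse = expected_bias(z, eff, case_study_design, nodes=64)
    fine = expected_bias(z, eff, case_study_design, nodes=128)
    assert abs(coarse - fine) < 1e-6


def test_selection_bias_effect_is_monotone_in_eta(case_study_design):
    z = seq(*([0, 1] * 32))  # balance-targeting alternating sequence
    values = []
    for eta in [0.0, 0.05, 0.1, 0.2, 0.4]:
        eff = total_offsets(z, case_study_design, BiasSpec(eta=eta))
        values.append(abs(expected_bias(z, eff, case_study_design)))
    assert np.all(np.diff(values) >= -1e-12)


def test_batch_matches_scalar_path(case_study_design, case_study_bias, rng):
    Z = rng.integers(0, 2, size=(8, 64)).astype(np.int8)
    offsets = np.empty((8, 64))
    singles = np.empty(8)
    for i in range(8):
        z = RandomizationSequence(Z[i])
        eff = total_offsets(z, case_study_design, case_study_bias)
        offsets[i] = eff.total_offset
        singles[i] = (
            np.nan if z.degenerate else expected_bias(z, eff, case_study_design)
        )
    batch = expected_bias_batch(Z, offsets, case_study_design)
    np.testing.assert_allclose(batch, singles, rtol=1e-12, equal_nan=True)


def test_arm_effect_sign_matches_simulated_logrank_mean(rng):
    """Balanced sequence, pure treatment effect: the asymptotic mean has the
    sign of -ln(HR) and matches the simulated mean log-rank statistic."""
    design = StudyDesign(
        n=200,
        accrual_length=30.0,
        total_length=90.0,
        alpha=0.05,
        dropout_rate=0.02,
        baseline_hazard=0.06,
        log_hazard_ratio=-0.25,
    )
    z = seq(*([0, 1] * 100))
    eff = total_offsets(z, design, BiasSpec())
    e = expected_bias(z, eff, design)
    assert e > 0  # hazard-lowering treatment shifts the statistic upward
    lr = simulate_statistics(z, eff, design, 10_000, rng)
    lr = lr[~np.isnan(lr)]
    se = lr.std(ddof=1) / math.sqrt(lr.size)
    assert abs(lr.mean() - e) < 3 * se + 0.05


def test_selection_bias_sign_matters_alongside_a_trend(case_study_design):
    """With a concurrent time trend the two-sided rejection probability is
    not symmetric in the sign of the selection-bias effect."""
    z = seq(*([0, 1] * 32))
    pos = total_offsets(z, case_study_design, BiasSpec(eta=0.1831, theta=-0.1144, trend="logarithmic"))
    neg = total_offsets(z, case_study_design, BiasSpec(eta=-0.1831, theta=-0.1144, trend="logarithmic"))
    r_pos = evaluate_sequence(z, pos, case_study_design).rejection_probability
    r_neg = evaluate_sequence(z, neg, case_study_design).rejection_probability
    assert r_pos != pytest.approx(r_neg, abs=1e-4)
    assert r_pos > 0.05  # the inflating direction used in the case study


# --- rejection probability --------------------------------------------------


def test_rejection_probability_calibrates_at_zero():
    assert rejection_probability(0.0, 0.05) == pytest.approx(0.05, abs=1e-15)


def test_rejection_probability_is_symmetric_and_increasing():
    es = np.linspace(0, 3, 13)
    up = rejection_probability(es, 0.05)
    down = rejection_probability(-es, 0.05)
    np.testing.assert_allclose(up, down)
    assert np.all(np.diff(up) > 0)


def test_rejection_probability_at_unit_shift():
    assert rejection_probability(1.0, 0.05) == pytest.approx(0.17007504575308752)


def test_one_sided_option():
    assert rejection_probability(0.0, 0.05, two_sided=False) == pytest.approx(0.05)
    assert rejection_probability(1.0, 0.05, two_sided=False) > rejection_probability(
        1.0, 0.05
    )


def test_invalid_alpha_rejected():
    with pytest.raises(ValueError):
        rejection_probability(0.5, 0.0)
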