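"""Patient-level trial simulation and the exact log-rank statistic.

This module is the brute-force counterpart of :mod:`ranbias.approximation`:
it draws complete trials from the bias model (exponential event times
with per-patient hazards ``lambda_C * exp(b_i)``, exponential random
dropout, administrative censoring at ``F - entry`` with entries uniform
on ``[0, A]``) and computes the log-rank statistic

    LR = sum_j (O_j - e_j) / sqrt(sum_j e_j (1 - e_j)),

with ``O_j`` the observed and ``e_j`` the expected number of control-arm
events at the ``j``-th distinct event time, both computed from the
at-risk sets. Under a continuous model event times are almost surely
distinct; tied times (e.g. rounded file input) are grouped, with the
variance term either in the form above or optionally the hypergeometric
form ``d_j p_j (1-p_j) (N_j - d_j)/(N_j - 1)``.

Follow-up time is measured from randomization; calendar entry times are
latent and affect the statistic only through administrative censoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bias import PatientEffects
from .design import StudyDesign
from .procedures import RandomizationSequence

__all__ = [
    "SimulatedTrial",
    "LogRankResult",
    "simulate_trial",
    "logrank_statistic",
    "empirical_rejection_rate",
    "simulate_statistics",
]


@dataclass(frozen=True)
class SimulatedTrial:
    """One realized trial: entries, observed times, event flags, groups."""

    entry_times: np.ndarray
    observed_times: np.ndarray
    event_flags: np.ndarray
    groups: np.ndarray

    @property
    def n_events(self) -> int:
        return int(self.event_flags.sum())

    def to_frame(self) -> pd.DataFrame:
        """Tabular export (columns: patient_index, group, entry_time,
        observed_time, event_flag)."""
        return pd.DataFrame(
            {
                "patient_index": np.arange(1, self.groups.size + 1),
                "group": self.groups.astype(int),
                "entry_time": self.entry_times,
                "observed_time": self.observed_times,
                "event_flag": self.event_flags.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SimulatedTrial":
        frame = frame.sort_values("patient_index")
        return cls(
            entry_times=frame["entry_time"].to_numpy(dtype=float),
            observed_times=frame["observed_time"].to_numpy(dtype=float),
            event_flags=frame["event_flag"].to_numpy(dtype=bool),
            groups=frame["group"].to_numpy(dtype=np.int8),
        )


@dataclass(frozen=True)
class LogRankResult:
    """Log-rank statistic with its per-event-time decomposition."""

    statistic: float
    observed: np.ndarray
    expected: np.ndarray
    variance_terms: np.ndarray
    valid: bool = True


def simulate_trial(
    z: RandomizationSequence,
    effects: PatientEffects,
    design: StudyDesign,
    rng: np.random.Generator,
) -> SimulatedTrial:
    """Draw one trial under the bias model."""
    n = design.n
    if z.n != n:
        raise ValueError(f"sequence length {z.n} does not match design n={n}")
    rates = design.baseline_hazard * effects.multipliers
    entry = rng.uniform(0.0, design.accrual_length, size=n) if design.accrual_length > 0 else np.zeros(n)
    event = rng.exponential(1.0 / rates)
    if design.dropout_rate > 0:
        dropout = rng.exponential(1.0 / design.dropout_rate, size=n)
    else:
        dropout = np.full(n, np.inf)
    admin = design.total_length - entry
    censor = np.minimum(dropout, admin)
    observed = np.minimum(event, censor)
    return SimulatedTrial(
        entry_times=entry,
        observed_times=observed,
        event_flags=event <= censor,
        groups=z.z.copy(),
    )


def logrank_statistic(
    trial: SimulatedTrial, *, variance: str = "binomial"
) -> LogRankResult:
    """Exact log-rank statistic with control-arm observed/expected counts.

    ``variance='binomial'`` uses ``e_j (1 - e_j)`` per distinct event
    time; ``variance='hypergeometric'`` uses the finite-population form
    (the two coincide for untied data). Trials with no events or a
    single arm yield an invalid result (``nan`` statistic).
    """
    if variance not in ("binomial", "hypergeometric"):
        raise ValueError(f"unknown variance form {variance!r}")
    y, flags, ctrl = trial.observed_times, trial.event_flags, 1 - trial.groups
    if not flags.any() or len(set(trial.groups.tolist())) < 2:
        empty = np.empty(0)
        return LogRankResult(float("nan"), empty, empty, empty, valid=False)
    taus = np.unique(y[flags.astype(bool)])
    O = np.empty(taus.size)
    E = np.empty(taus.size)
    Vt = np.empty(taus.size)
    for j, tau in enumerate(taus):
        at_risk = y >= tau
        n_risk = int(at_risk.sum())
        n_ctrl = int(ctrl[at_risk].sum())
        here = (y == tau) & flags.astype(bool)
        d = int(here.sum())
        O[j] = int(ctrl[here].sum())
        p = n_ctrl / n_risk
        E[j] = d * p
        if variance == "binomial":
            Vt[j] = E[j] * (1.0 - E[j])
        else:
            corr = (n_risk - d) / (n_risk - 1) if n_risk > 1 else 0.0
            Vt[j] = d * p * (1.0 - p) * corr
    denom = Vt.sum()
    if denom <= 0:
        return LogRankResult(float("nan"), O, E, Vt, valid=False)
    stat = float((O - E).sum() / np.sqrt(denom))
    return LogRankResult(stat, O, E, Vt, valid=True)


def simulate_statistics(
    z: RandomizationSequence,
    effects: PatientEffects,
    design: StudyDesign,
    replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Log-rank statistics from ``replicates`` simulated trials (vectorized).

    Exploits the continuity of the model (no ties almost surely): each
    distinct event time carries exactly one event. Replicates with no
    events or a vanishing variance denominator yield ``nan``.
    """
    n = design.n
    rates = design.baseline_hazard * effects.multipliers
    shape = (replicates, n)
    entry = (
        rng.uniform(0.0, design.accrual_length, size=shape)
        if design.accrual_length > 0
        else np.zeros(shape)
    )
    event = rng.exponential(1.0, size=shape) / rates
    if design.dropout_rate > 0:
        dropout = rng.exponential(1.0 / design.dropout_rate, size=shape)
    else:
        dropout = np.full(shape, np.inf)
    censor = np.minimum(dropout, design.total_length - entry)
    y = np.minimum(event, censor)
    flags = (event <= censor).astype(float)

    order = np.argsort(y, axis=1)
    flags_s = np.take_along_axis(flags, order, axis=1)
    ctrl = np.broadcast_to((1 - z.z).astype(float), shape)
    ctrl_s = np.take_along_axis(ctrl, order, axis=1)
    at_risk = np.arange(n, 0, -1, dtype=float)[None, :]
    ctrl_at_risk = np.cumsum(ctrl_s[:, ::-1], axis=1)[:, ::-1]
    p = ctrl_at_risk / at_risk
    num = (flags_s * (ctrl_s - p)).sum(axis=1)
    den = (flags_s * p * (1.0 - p)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lr = np.where(den > 0, num / np.sqrt(den), np.nan)
    return lr


def empirical_rejection_rate(
    z: RandomizationSequence,
    effects: PatientEffects,
    design: StudyDesign,
    replicates: int,
    rng: np.random.Generator,
    *,
    two_sided: bool = True,
) -> float:
    """Fraction of simulated trials on which the log-rank test rejects.

    Invalid replicates (no events, degenerate variance) are excluded
    from the denominator.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    lr = simulate_statistics(z, effects, design, replicates, rng)
    valid = ~np.isnan(lr)
    if not valid.any():
        raise RuntimeError("all replicates invalid (no usable events)")
    if two_sided:
        q = stats.norm.ppf(1 - design.alpha / 2)
        reject = np.abs(lr[valid]) > q
    else:
        q = stats.norm.ppf(1 - design.alpha)
        reject = lr[valid] > q
    return float(reject.mean())
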