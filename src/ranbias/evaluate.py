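"""Monte-Carlo comparison of randomization procedures.

For each procedure, a Monte-Carlo sample of ``M`` randomization
sequences is drawn, the per-sequence type I error probability of the
log-rank test under the configured bias model is computed with the
asymptotic approximation, and the sample is summarized by its mean and
standard deviation (``M - 1`` denominator). Degenerate single-arm
sequences (possible under complete randomization with probability
``2^(1-n)``) are excluded from the summary and counted.

Each procedure receives its own random stream derived from the master
seed keyed by the procedure label, so adding or reordering procedures
does not perturb the others' results.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .approximation import expected_bias_batch, rejection_probability
from .bias import BiasSpec, selection_effects, trend_effects
from .design import ConfigurationError, StudyDesign, load_design
from .procedures import ProcedureSpec, generate_sequence, parse_procedure

__all__ = [
    "ProcedureSummary",
    "evaluate_procedure",
    "per_sequence_rejections",
    "required_sequences",
    "load_bias",
    "run_study",
]

logger = logging.getLogger("ranbias")

#: Pilot sample size used to size the Monte-Carlo run when no explicit
#: sequence count is configured.
PILOT_SEQUENCES = 500
DEFAULT_PRECISION = 2e-4
DEFAULT_CERTAINTY = 0.995


@dataclass(frozen=True)
class ProcedureSummary:
    """Summary of per-sequence type I error probabilities for one procedure."""

    procedure: ProcedureSpec
    n_sequences: int
    mean_rejection: float
    sd_rejection: float
    excluded: int
    seed: int


def procedure_rng(master_seed: int, label: str) -> np.random.Generator:
    """Independent stream for one procedure, keyed by its label.

    The stream is seeded by the master seed together with the bytes of
    the canonical procedure label, so each procedure's draws are a
    deterministic function of ``(master_seed, label)`` alone.
    """
    entropy = [int(master_seed)] + list(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def per_sequence_rejections(
    spec: ProcedureSpec,
    design: StudyDesign,
    bias: BiasSpec,
    n_sequences: int,
    rng: np.random.Generator,
    *,
    two_sided: bool = True,
) -> np.ndarray:
    """Rejection probabilities for ``n_sequences`` fresh draws from ``spec``.

    Degenerate sequences yield ``nan`` entries.
    """
    n = design.n
    Z = np.empty((n_sequences, n), dtype=np.int8)
    for m in range(n_sequences):
        Z[m] = generate_sequence(spec, n, rng).z
    trend = trend_effects(n, bias)
    # selection effect from prefix imbalances, vectorized over sequences
    D = np.cumsum(2 * Z.astype(np.int64) - 1, axis=1)
    prev = np.concatenate([np.zeros((n_sequences, 1), dtype=np.int64), D[:, :-1]], axis=1)
    sel = bias.eta * np.sign(prev)
    offsets = Z * design.log_hazard_ratio + sel + trend[None, :]
    e = expected_bias_batch(Z, offsets, design)
    return np.asarray(rejection_probability(e, design.alpha, two_sided=two_sided))


def evaluate_procedure(
    spec: ProcedureSpec,
    design: StudyDesign,
    bias: BiasSpec,
    n_sequences: int,
    seed: int,
    *,
    two_sided: bool = True,
) -> ProcedureSummary:
    """Monte-Carlo summary of the type I error probability for one procedure."""
    if n_sequences < 2:
        raise ValueError("n_sequences must be >= 2")
    rng = procedure_rng(seed, spec.label)
    rejections = per_sequence_rejections(
        spec, design, bias, n_sequences, rng, two_sided=two_sided
    )
    valid = rejections[~np.isnan(rejections)]
    excluded = int(np.isnan(rejections).sum())
    if valid.size == 0:
        raise RuntimeError(f"all sequences degenerate for {spec.label}")
    if excluded:
        logger.info("%s: excluded %d degenerate sequence(s)", spec.label, excluded)
    return ProcedureSummary(
        procedure=spec,
        n_sequences=n_sequences,
        mean_rejection=float(valid.mean()),
        sd_rejection=float(valid.std(ddof=1)),
        excluded=excluded,
        seed=int(seed),
    )


def required_sequences(
    pilot_sd: float, precision: float = DEFAULT_PRECISION, certainty: float = DEFAULT_CERTAINTY
) -> int:
    """Smallest Monte-Carlo sample size meeting a precision requirement.

    Returns the smallest ``M`` with
    ``z_{(1+certainty)/2} * pilot_sd / sqrt(M) <= precision`` (at least 1).
    """
    if pilot_sd < 0 or precision <= 0:
        raise ValueError("pilot_sd must be >= 0 and precision > 0")
    if not 0 < certainty < 1:
        raise ValueError(f"certainty must lie in (0, 1), got {certainty}")
    if pilot_sd == 0:
        return 1
    q = stats.norm.ppf((1 + certainty) / 2)
    return max(1, math.ceil((q * pilot_sd / precision) ** 2))


def load_bias(config: Mapping[str, Any], design: Optional[StudyDesign] = None) -> BiasSpec:
    """Build a :class:`BiasSpec` from a config block.

    Accepts either absolute effects (``eta``, ``theta``) or relative
    ones (``eta_fraction``, ``theta_fraction`` of the design's
    ``|ln HR|`` / ``ln HR``), plus ``trend`` and ``step_index``.
    """
    trend = config.get("trend", "none")
    step_index = config.get("step_index")
    if "eta_fraction" in config or "theta_fraction" in config:
        if design is None:
            raise ConfigurationError(
                "relative bias parameterization requires a study design"
            )
        if "eta" in config or "theta" in config:
            raise ConfigurationError(
                "give either absolute (eta/theta) or relative "
                "(eta_fraction/theta_fraction) bias effects, not both"
            )
        return BiasSpec.from_fractions(
            design,
            eta_fraction=float(config.get("eta_fraction", 0.0)),
            theta_fraction=float(config.get("theta_fraction", 0.0)),
            trend=trend,
            step_index=step_index,
        )
    return BiasSpec(
        eta=float(config.get("eta", 0.0)),
        theta=float(config.get("theta", 0.0)),
        trend=trend,
        step_index=step_index,
    )


def run_study(
    config: Mapping[str, Any],
    *,
    seed: Optional[int] = None,
    n_sequences: Optional[int] = None,
) -> pd.DataFrame:
    """Evaluate every configured procedure and tabulate the summaries.

    The configuration document has blocks ``design`` (see
    :func:`ranbias.design.load_design`), ``bias`` (see :func:`load_bias`),
    ``procedures`` (list of strings such as ``"CHEN(3, 2/3)"``) and
    ``monte_carlo`` (keys ``sequences``, ``seed``, ``precision``,
    ``certainty``). When ``sequences`` is absent, each procedure's
    sample size is set from a pilot run via :func:`required_sequences`.

    Returns a DataFrame with columns ``procedure, n_sequences,
    mean_type1, sd_type1, excluded, seed`` in the configured procedure
    order; deterministic given the seed.
    """
    try:
        design = load_design(config["design"])
        proc_strings: Sequence[str] = config["procedures"]
    except KeyError as exc:
        raise ConfigurationError(f"missing config block: {exc}") from exc
    bias = load_bias(config.get("bias", {}), design)
    mc = config.get("monte_carlo", {})
    if seed is None:
        seed = int(mc.get("seed", 0))
    if n_sequences is None:
        n_sequences = mc.get("sequences")
    precision = float(mc.get("precision", DEFAULT_PRECISION))
    certainty = float(mc.get("certainty", DEFAULT_CERTAINTY))

    specs = [parse_procedure(s) for s in proc_strings]
    rows = []
    for spec in specs:
        if n_sequences is None:
            pilot = evaluate_procedure(spec, design, bias, PILOT_SEQUENCES, seed)
            m = max(
                required_sequences(pilot.sd_rejection, precision, certainty), 2
            )
        else:
            m = int(n_sequences)
        summary = evaluate_procedure(spec, design, bias, m, seed)
        rows.append(
            {
                "procedure": spec.label,
                "n_sequences": summary.n_sequences,
                "mean_type1": summary.mean_rejection,
                "sd_type1": summary.sd_rejection,
                "excluded": summary.excluded,
                "seed": summary.seed,
            }
        )
    return pd.DataFrame(rows)
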