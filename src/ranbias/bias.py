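"""Per-patient log-hazard offsets from selection bias and time trends.

The bias model acts multiplicatively on the hazard: patient ``i`` under
sequence ``z`` has hazard

    h_i(t, z) = h_C(t) * exp(z_i * ln(HR) + eta_i(z) + theta_i),

where ``eta_i(z)`` is the selection-bias shift induced by an unblinded
investigator guessing upcoming allocations with the Blackwell–Hodges
convergence strategy (predict the currently under-represented arm), and
``theta_i`` is an unobserved time trend over enrollment order.

Positive ``eta``/``theta`` raise the hazard (worsen outcomes when long
survival is desirable); both are expressed in log-hazard units. Trends
are indexed by enrollment order ``i``, not calendar time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .design import ConfigurationError, StudyDesign
from .procedures import RandomizationSequence

__all__ = [
    "BiasSpec",
    "PatientEffects",
    "TREND_SHAPES",
    "selection_effects",
    "trend_effects",
    "total_offsets",
]

TREND_SHAPES = ("none", "stepwise", "linear", "logarithmic")


@dataclass(frozen=True)
class BiasSpec:
    """Selection-bias effect ``eta``, trend shape and trend effect ``theta``.

    ``step_index`` is the change point of the stepwise trend (the trend
    applies to patients ``i > step_index``); it is required exactly when
    ``trend == 'stepwise'``.
    """

    eta: float = 0.0
    theta: float = 0.0
    trend: str = "none"
    step_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.trend not in TREND_SHAPES:
            raise ConfigurationError(
                f"trend must be one of {TREND_SHAPES}, got {self.trend!r}"
            )
        if self.trend == "stepwise" and self.step_index is None:
            raise ConfigurationError("stepwise trend requires step_index")

    @classmethod
    def from_fractions(
        cls,
        design: StudyDesign,
        eta_fraction: float = 0.0,
        theta_fraction: float = 0.0,
        trend: str = "none",
        step_index: Optional[int] = None,
    ) -> "BiasSpec":
        """Parameterize the effects relative to ``|ln(HR)|`` of the design.

        ``eta = eta_fraction * |ln HR|`` points in the hazard-raising
        direction; ``theta = theta_fraction * ln HR`` shares the sign of
        the anticipated treatment effect (an improving trend when the
        experimental treatment lowers the hazard).
        """
        lhr = design.log_hazard_ratio
        return cls(
            eta=eta_fraction * abs(lhr),
            theta=theta_fraction * lhr,
            trend=trend,
            step_index=step_index,
        )


@dataclass(frozen=True)
class PatientEffects:
    """Per-patient log-hazard components and their sum.

    ``total_offset[i-1] = z_i * ln(HR) + selection[i-1] + trend[i-1]``.
    """

    selection: np.ndarray
    trend: np.ndarray
    total_offset: np.ndarray

    @property
    def multipliers(self) -> np.ndarray:
        """Proportional-hazard multipliers ``m_i = exp(total_offset_i)``."""
        return np.exp(self.total_offset)


def selection_effects(z: RandomizationSequence, eta: float) -> np.ndarray:
    """Selection-bias shifts ``eta_i = eta * sgn(N_E_{i-1} - N_C_{i-1})``.

    The first patient's shift is always 0 (no allocation history).
    """
    return eta * np.sign(z.imbalance[:-1]).astype(float)


def trend_effects(n: int, spec: BiasSpec) -> np.ndarray:
    """Time-trend shifts ``theta_i`` for patients ``i = 1..n``.

    Shapes: ``stepwise`` jumps from 0 to ``theta`` after ``step_index``;
    ``linear`` is ``theta * (i-1)/(n-1)``; ``logarithmic`` is
    ``theta * ln(i)/ln(n)``. The first patient's shift is 0 for the
    linear and logarithmic shapes.
    """
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    i = np.arange(1, n + 1, dtype=float)
    if spec.trend == "none":
        return np.zeros(n)
    if spec.trend == "stepwise":
        if spec.step_index is None:
            raise ConfigurationError("stepwise trend requires step_index")
        return spec.theta * (i > spec.step_index).astype(float)
    if spec.trend == "linear":
        return spec.theta * (i - 1) / (n - 1)
    if spec.trend == "logarithmic":
        return spec.theta * np.log(i) / np.log(n)
    raise ConfigurationError(f"unknown trend {spec.trend!r}")  # pragma: no cover


def total_offsets(
    z: RandomizationSequence, design: StudyDesign, spec: BiasSpec
) -> PatientEffects:
    """Combine arm effect, selection bias and trend into per-patient offsets."""
    if z.n != design.n:
        raise ValueError(f"sequence length {z.n} does not match design n={design.n}")
    sel = selection_effects(z, spec.eta)
    trd = trend_effects(z.n, spec)
    total = z.z * design.log_hazard_ratio + sel + trd
    return PatientEffects(selection=sel, trend=trd, total_offset=total)
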