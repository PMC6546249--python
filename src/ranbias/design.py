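"""Trial design configuration shared by all other modules.

A :class:`StudyDesign` collects the timeline of a two-arm 1:1 survival
trial (uniform accrual over ``[0, A]``, total duration ``F``), the
exponential baseline hazard of the control arm, the exponential dropout
rate of the independent random-censoring mechanism, the anticipated log
hazard ratio of the experimental arm and the two-sided significance
level of the log-rank test.

All rates are per unit time in whatever unit the configuration uses
(weeks in the bundled examples); the package never converts units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Any, Mapping

__all__ = ["StudyDesign", "ConfigurationError", "load_design", "DESIGN_KEYS"]


class ConfigurationError(ValueError):
    """Raised when a configuration document is missing a field or violates an invariant."""


#: Exact keys of the flat design configuration document.
DESIGN_KEYS = (
    "n",
    "accrual_length",
    "total_length",
    "alpha",
    "dropout_rate",
    "baseline_hazard",
    "log_hazard_ratio",
)


@dataclass(frozen=True)
class StudyDesign:
    """Immutable trial configuration.

    Parameters
    ----------
    n:
        Number of patients; positive and even (1:1 allocation target).
    accrual_length:
        Length ``A >= 0`` of the accrual period. Patients enter the trial
        at calendar times uniform on ``[0, A]``.
    total_length:
        Total study duration ``F > A``; follow-up of a patient entering
        at calendar time ``a`` is administratively censored at ``F - a``.
    alpha:
        Two-sided significance level of the log-rank test, in ``(0, 1)``.
    dropout_rate:
        Rate ``lambda_cen >= 0`` of the exponential random-censoring
        distribution, independent of the survival times.
    baseline_hazard:
        Control-arm hazard ``lambda_C > 0`` (constant; exponential
        baseline survival).
    log_hazard_ratio:
        ``ln(HR)`` of the experimental arm; 0 encodes the null
        hypothesis used for type I error evaluation.
    """

    n: int
    accrual_length: float
    total_length: float
    alpha: float
    dropout_rate: float
    baseline_hazard: float
    log_hazard_ratio: float

    def __post_init__(self) -> None:
        if self.n < 2 or self.n % 2 != 0:
            raise ConfigurationError(f"n must be an even integer >= 2, got {self.n}")
        if self.accrual_length < 0:
            raise ConfigurationError(
                f"accrual_length must be >= 0, got {self.accrual_length}"
            )
        if not self.total_length > self.accrual_length:
            raise ConfigurationError(
                "total_length must exceed accrual_length, got "
                f"total_length={self.total_length}, accrual_length={self.accrual_length}"
            )
        if not 0 < self.alpha < 1:
            raise ConfigurationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.dropout_rate < 0:
            raise ConfigurationError(
                f"dropout_rate must be >= 0, got {self.dropout_rate}"
            )
        if not self.baseline_hazard > 0:
            raise ConfigurationError(
                f"baseline_hazard must be > 0, got {self.baseline_hazard}"
            )

    @property
    def hazard_ratio(self) -> float:
        """``HR = exp(log_hazard_ratio)``."""
        return math.exp(self.log_hazard_ratio)

    @property
    def experimental_hazard(self) -> float:
        """``lambda_E = lambda_C * HR``."""
        return self.baseline_hazard * self.hazard_ratio

    def under_null(self) -> "StudyDesign":
        """Copy of this design with ``log_hazard_ratio = 0``."""
        return StudyDesign(**{**asdict(self), "log_hazard_ratio": 0.0})

    def to_dict(self) -> dict[str, Any]:
        """Flat key-value document; round-trips through :func:`load_design`."""
        return asdict(self)


def load_design(config: Mapping[str, Any]) -> StudyDesign:
    """Validate a flat key-value document and build a :class:`StudyDesign`.

    Raises
    ------
    ConfigurationError
        If a required key is missing or an invariant is violated; the
        message names the offending field.
    """
    missing = [k for k in DESIGN_KEYS if k not in config]
    if missing:
        raise ConfigurationError(f"missing design field(s): {', '.join(missing)}")
    try:
        n = int(config["n"])
        values = {k: float(config[k]) for k in DESIGN_KEYS if k != "n"}
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"non-numeric design field: {exc}") from exc
    return StudyDesign(n=n, **values)
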