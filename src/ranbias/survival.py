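"""Per-patient survival model and the two censoring mechanisms.

Each patient's hazard is proportional to the baseline control hazard:
``h_i(t) = lambda_C * m_i`` with a per-patient multiplier
``m_i = exp(b_i)`` from the bias model, giving exponential survival
``S_i(t) = exp(-lambda_C * m_i * t)`` and density
``f_i(t) = lambda_C * m_i * S_i(t)``.

Censoring is the competition of two mechanisms: exponential random
dropout with survival ``S_cen(t) = exp(-lambda_cen * t)``, and
administrative censoring at end of study. With uniform accrual over
``[0, A]`` and total duration ``F``, a patient's maximal follow-up is
``F - entry`` and the administrative censoring time has survival

    S_uni(t) = 1                     for t <  F - A,
               1 - (t - (F - A))/A   for F - A <= t < F,
               0                     for t >= F.

Time is measured since randomization per patient; calendar time enters
only through ``S_uni``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "survival_fn",
    "density_fn",
    "hazard_fn",
    "admin_censoring_survival",
    "random_censoring_survival",
]


def _check_time(t: np.ndarray | float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    return t


def survival_fn(m, baseline_hazard: float, t) -> np.ndarray:
    """``S(t) = exp(-lambda_C * m * t)`` for multiplier(s) ``m``.

    Broadcasts over ``m`` and ``t``.
    """
    t = _check_time(t)
    return np.exp(-baseline_hazard * np.asarray(m, dtype=float) * t)


def density_fn(m, baseline_hazard: float, t) -> np.ndarray:
    """``f(t) = lambda_C * m * exp(-lambda_C * m * t)``."""
    m = np.asarray(m, dtype=float)
    return baseline_hazard * m * survival_fn(m, baseline_hazard, t)


def hazard_fn(m, baseline_hazard: float) -> np.ndarray:
    """Constant hazard ``lambda_C * m``."""
    return baseline_hazard * np.asarray(m, dtype=float)


def admin_censoring_survival(t, accrual_length: float, total_length: float) -> np.ndarray:
    """Survival function ``S_uni`` of the administrative censoring time.

    Piecewise linear: 1 before ``F - A``, linearly decreasing to 0 at
    ``F``, 0 thereafter; a step function at ``F`` when ``A = 0``.
    """
    if not total_length > accrual_length:
        raise ValueError("total_length must exceed accrual_length")
    t = _check_time(t)
    A, F = accrual_length, total_length
    if A == 0:
        return np.where(t < F, 1.0, 0.0)
    return np.clip((F - t) / A, 0.0, 1.0)


def random_censoring_survival(t, dropout_rate: float) -> np.ndarray:
    """Survival function ``exp(-lambda_cen * t)`` of random dropout."""
    t = _check_time(t)
    return np.exp(-dropout_rate * t)
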