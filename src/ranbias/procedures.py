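"""Randomization procedures for two-arm 1:1 trials.

Seven families are implemented, each defining a probability distribution
over allocation sequences ``z in {0,1}^n`` (``z_i = 0`` control,
``z_i = 1`` experimental):

``CR``
    Complete randomization — i.i.d. fair coin.
``EBC(p)``
    Efron's biased coin — coin biased with probability ``p`` toward the
    currently under-represented arm, fair at zero imbalance.
``RAR``
    Random allocation rule — uniform over the ``C(n, n/2)`` balanced
    sequences.
``PBR(k)``
    Permuted block randomization — independent random allocation rules
    within consecutive blocks of size ``k``.
``MP(b)``
    Maximal procedure with final balance — uniform over balanced
    sequences whose running imbalance never exceeds ``b`` in absolute
    value, sampled exactly via dynamic-programming path counts.
``BSD(b)``
    Big stick design — fair coin, deterministic assignment to the
    smaller arm once the imbalance reaches ``b``.
``CHEN(b, p)``
    Chen's design — Efron's coin with bias ``p``, deterministic
    assignment once the imbalance reaches ``b``.

Sequence probabilities are computed exactly (:class:`fractions.Fraction`)
to support small-``n`` enumeration tests.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np

from .design import ConfigurationError

__all__ = [
    "ProcedureSpec",
    "RandomizationSequence",
    "parse_procedure",
    "generate_sequence",
    "sequence_probability",
    "count_admissible_mp",
    "FAMILIES",
]

FAMILIES = ("CR", "EBC", "RAR", "PBR", "MP", "BSD", "CHEN")


def _as_fraction(p) -> Fraction:
    """Convert a probability given as Fraction, string ('2/3', '0.667') or float."""
    if isinstance(p, Fraction):
        return p
    if isinstance(p, str):
        return Fraction(p)
    if isinstance(p, int):
        return Fraction(p)
    # floats: recover the intended simple fraction (2/3 etc.) when obvious
    return Fraction(p).limit_denominator(10**9)


@dataclass(frozen=True)
class ProcedureSpec:
    """A randomization procedure family with its parameters.

    ``bias_probability`` (``p``) is required for EBC and CHEN and must be
    in ``[1/2, 1]``; ``block_size`` (``k``, even) for PBR;
    ``mti`` (``b``, the maximum tolerated imbalance) for MP, BSD and CHEN.
    """

    family: str
    bias_probability: Optional[Fraction] = None
    block_size: Optional[int] = None
    mti: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigurationError(
                f"unknown procedure family {self.family!r}; expected one of {FAMILIES}"
            )
        if self.bias_probability is not None:
            object.__setattr__(
                self, "bias_probability", _as_fraction(self.bias_probability)
            )
        if self.family in ("EBC", "CHEN"):
            p = self.bias_probability
            if p is None:
                raise ConfigurationError(f"{self.family} requires bias_probability p")
            if not Fraction(1, 2) <= p <= 1:
                raise ConfigurationError(f"bias_probability must be in [1/2, 1], got {p}")
        if self.family == "PBR":
            k = self.block_size
            if k is None:
                raise ConfigurationError("PBR requires block_size k")
            if k <= 0 or k % 2 != 0:
                raise ConfigurationError(f"block_size must be a positive even integer, got {k}")
        if self.family in ("MP", "BSD", "CHEN"):
            b = self.mti
            if b is None:
                raise ConfigurationError(f"{self.family} requires mti b")
            if b < 1:
                raise ConfigurationError(f"mti must be a positive integer, got {b}")

    @property
    def label(self) -> str:
        """Canonical display string, e.g. ``'CHEN(3, 2/3)'``."""
        if self.family == "CR" or self.family == "RAR":
            return self.family
        if self.family == "EBC":
            return f"EBC({self.bias_probability})"
        if self.family == "PBR":
            return f"PBR({self.block_size})"
        if self.family in ("MP", "BSD"):
            return f"{self.family}({self.mti})"
        return f"CHEN({self.mti}, {self.bias_probability})"


_PROC_RE = re.compile(r"^\s*([A-Za-z]+)\s*(?:\(\s*([^)]*?)\s*\))?\s*$")


def parse_procedure(text: str) -> ProcedureSpec:
    """Parse a procedure string as printed in configs, e.g. ``'CHEN(3, 2/3)'``.

    Accepts fractions and decimals for ``p`` and is whitespace-tolerant.
    """
    m = _PROC_RE.match(text)
    if m is None:
        raise ConfigurationError(f"unparseable procedure string: {text!r}")
    family = m.group(1).upper()
    args = [a.strip() for a in m.group(2).split(",")] if m.group(2) else []
    try:
        if family == "CR" or family == "RAR":
            if args:
                raise ConfigurationError(f"{family} takes no parameters: {text!r}")
            return ProcedureSpec(family)
        if family == "EBC":
            (p,) = args
            return ProcedureSpec(family, bias_probability=_as_fraction(p))
        if family == "PBR":
            (k,) = args
            return ProcedureSpec(family, block_size=int(k))
        if family in ("MP", "BSD"):
            (b,) = args
            return ProcedureSpec(family, mti=int(b))
        if family == "CHEN":
            b, p = args
            return ProcedureSpec(family, mti=int(b), bias_probability=_as_fraction(p))
    except (ValueError, ZeroDivisionError) as exc:
        raise ConfigurationError(f"bad parameters in procedure string {text!r}: {exc}") from exc
    raise ConfigurationError(f"unknown procedure family in {text!r}")


@dataclass(frozen=True)
class RandomizationSequence:
    """A realized allocation vector with its prefix imbalances.

    ``z[i-1]`` is the assignment of patient ``i``; ``imbalance[i]`` is
    ``D_i = N_E_i - N_C_i`` after the first ``i`` patients (``D_0 = 0``).
    """

    z: np.ndarray
    imbalance: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=np.int8)
        if z.ndim != 1 or not np.isin(z, (0, 1)).all():
            raise ValueError("z must be a 1-D vector over {0, 1}")
        object.__setattr__(self, "z", z)
        d = np.concatenate(([0], np.cumsum(2 * z.astype(np.int64) - 1)))
        object.__setattr__(self, "imbalance", d)

    @property
    def n(self) -> int:
        return self.z.size

    @property
    def n_experimental(self) -> np.ndarray:
        """Prefix counts ``N_E_i`` for ``i = 0..n``."""
        return np.concatenate(([0], np.cumsum(self.z.astype(np.int64))))

    @property
    def n_control(self) -> np.ndarray:
        """Prefix counts ``N_C_i`` for ``i = 0..n``."""
        return np.arange(self.n + 1) - self.n_experimental

    @property
    def degenerate(self) -> bool:
        """True if all patients landed in one arm."""
        s = int(self.z.sum())
        return s == 0 or s == self.n

    def key(self) -> str:
        return "".join(map(str, self.z.tolist()))


# ---------------------------------------------------------------------------
# Maximal-procedure path counts


@lru_cache(maxsize=None)
def _mp_completions(n: int, b: int) -> dict[tuple[int, int], int]:
    """Exact number of admissible completions from each (position, imbalance).

    ``counts[(i, d)]`` is the number of ways to extend a prefix of length
    ``i`` with imbalance ``d`` to a full sequence of length ``n`` with
    ``D_n = 0`` and ``|D_j| <= b`` throughout. Exact integer arithmetic.
    """
    counts: dict[tuple[int, int], int] = {(n, 0): 1}
    for i in range(n - 1, -1, -1):
        for d in range(-min(b, i), min(b, i) + 1):
            total = 0
            for step in (1, -1):
                nxt = d + step
                if abs(nxt) <= b:
                    total += counts.get((i + 1, nxt), 0)
            if total:
                counts[(i, d)] = total
    return counts


def count_admissible_mp(n: int, b: int) -> int:
    """Number of balanced length-``n`` sequences with ``max_i |D_i| <= b``."""
    if n % 2 != 0 or n < 2:
        raise ValueError(f"n must be a positive even integer, got {n}")
    if b < 1:
        raise ValueError(f"b must be >= 1, got {b}")
    return _mp_completions(n, min(b, n // 2))[(0, 0)]


# ---------------------------------------------------------------------------
# Sequence generation


def _draw_rar_block(size: int, rng: np.random.Generator) -> np.ndarray:
    block = np.zeros(size, dtype=np.int8)
    block[: size // 2] = 1
    rng.shuffle(block)
    return block


def generate_sequence(
    spec: ProcedureSpec, n: int, rng: np.random.Generator
) -> RandomizationSequence:
    """Draw one randomization sequence of length ``n`` from ``spec``.

    ``n`` must be even. The draw is reproducible given the generator
    state; each call consumes a family-dependent but deterministic
    portion of the stream.
    """
    if n < 2 or n % 2 != 0:
        raise ConfigurationError(f"n must be an even integer >= 2, got {n}")
    fam = spec.family

    if fam == "CR":
        return RandomizationSequence(rng.integers(0, 2, size=n).astype(np.int8))

    if fam == "RAR":
        return RandomizationSequence(_draw_rar_block(n, rng))

    if fam == "PBR":
        k = spec.block_size
        parts = [_draw_rar_block(k, rng) for _ in range(n // k)]
        rem = n % k
        if rem:
            parts.append(_draw_rar_block(rem, rng))
        return RandomizationSequence(np.concatenate(parts))

    if fam == "MP":
        b = min(spec.mti, n // 2)
        counts = _mp_completions(n, b)
        z = np.empty(n, dtype=np.int8)
        d = 0
        # uniformity: P(next = 1) = completions after stepping up / completions now
        for i in range(n):
            here = counts[(i, d)]
            up = counts.get((i + 1, d + 1), 0) if abs(d + 1) <= b else 0
            take_one = rng.random() < up / here
            z[i] = 1 if take_one else 0
            d += 1 if take_one else -1
        return RandomizationSequence(z)

    if fam == "BSD":
        b = spec.mti
        z = np.empty(n, dtype=np.int8)
        d = 0
        u = rng.random(n)
        for i in range(n):
            if d == b:
                z[i] = 0
            elif d == -b:
                z[i] = 1
            else:
                z[i] = 1 if u[i] < 0.5 else 0
            d += 1 if z[i] else -1
        return RandomizationSequence(z)

    if fam in ("EBC", "CHEN"):
        p = float(spec.bias_probability)
        b = spec.mti if fam == "CHEN" else None
        z = np.empty(n, dtype=np.int8)
        d = 0
        u = rng.random(n)
        for i in range(n):
            if b is not None and d == b:
                z[i] = 0
            elif b is not None and d == -b:
                z[i] = 1
            elif d == 0:
                z[i] = 1 if u[i] < 0.5 else 0
            elif d < 0:  # experimental under-represented
                z[i] = 1 if u[i] < p else 0
            else:
                z[i] = 0 if u[i] < p else 1
            d += 1 if z[i] else -1
        return RandomizationSequence(z)

    raise ConfigurationError(f"unknown family {fam!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Exact sequence probabilities


def sequence_probability(
    spec: ProcedureSpec, z: RandomizationSequence | Sequence[int]
) -> Fraction:
    """Exact probability of drawing ``z`` under ``spec``; 0 if inadmissible."""
    if not isinstance(z, RandomizationSequence):
        z = RandomizationSequence(np.asarray(z))
    n = z.n
    d = z.imbalance
    fam = spec.family

    if fam == "CR":
        return Fraction(1, 2**n)

    if fam == "RAR":
        if d[n] != 0:
            return Fraction(0)
        return Fraction(1, math.comb(n, n // 2))

    if fam == "PBR":
        k = spec.block_size
        prob = Fraction(1)
        start = 0
        while start < n:
            size = min(k, n - start)
            block = z.z[start : start + size]
            if int(block.sum()) * 2 != size:
                return Fraction(0)
            prob /= math.comb(size, size // 2)
            start += size
        return prob

    if fam == "MP":
        b = min(spec.mti, n // 2)
        if d[n] != 0 or np.abs(d).max() > b:
            return Fraction(0)
        return Fraction(1, count_admissible_mp(n, b))

    if fam == "BSD":
        b = spec.mti
        prob = Fraction(1)
        for i in range(n):
            if abs(d[i]) > b or abs(d[i + 1]) > b:
                return Fraction(0)
            if d[i] == b:
                if z.z[i] != 0:
                    return Fraction(0)
            elif d[i] == -b:
                if z.z[i] != 1:
                    return Fraction(0)
            else:
                prob /= 2
        return prob

    if fam in ("EBC", "CHEN"):
        p = spec.bias_probability
        b = spec.mti if fam == "CHEN" else None
        prob = Fraction(1)
        for i in range(n):
            if b is not None and abs(d[i + 1]) > b:
                return Fraction(0)
            if b is not None and d[i] == b:
                if z.z[i] != 0:
                    return Fraction(0)
            elif b is not None and d[i] == -b:
                if z.z[i] != 1:
                    return Fraction(0)
            elif d[i] == 0:
                prob /= 2
            elif d[i] < 0:
                prob *= p if z.z[i] == 1 else 1 - p
            else:
                prob *= p if z.z[i] == 0 else 1 - p
        return prob

    raise ConfigurationError(f"unknown family {fam!r}")  # pragma: no cover


def enumerate_sequences(n: int) -> Iterable[RandomizationSequence]:
    """All ``2^n`` sequences of length ``n`` (small-n test helper)."""
    for bits in range(2**n):
        yield RandomizationSequence(
            np.fromiter(((bits >> i) & 1 for i in range(n)), dtype=np.int8, count=n)
        )
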