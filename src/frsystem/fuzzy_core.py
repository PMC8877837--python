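"""Scalar fuzzy connectives: negations, implications, aggregations, pre-aggregations.

Every evaluator accepts floats or numpy arrays (broadcasting) and returns the
same shape; all values live on the unit interval.  Specs are small pydantic
models so they can be validated once and serialized to/from YAML fragments.
"""

from __future__ import annotations

from functools import reduce
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

__all__ = [
    "DomainError",
    "ParameterError",
    "ConfigurationError",
    "NegationSpec",
    "ImplicationSpec",
    "AggregatorSpec",
    "evaluate_negation",
    "evaluate_implication",
    "aggregate",
    "apply_binary",
]

ATOL = 1e-12  # absolute tolerance used by all unit-interval comparisons


class DomainError(ValueError):
    """An input fell outside the unit interval (inputs are validated, not clamped)."""


# direct Exception subclasses (not ValueError): pydantic re-wraps ValueError
# raised inside validators, and spec construction must surface these as-is
class ParameterError(Exception):
    """A spec parameter is outside its admissible range."""


class ConfigurationError(Exception):
    """Specs are inconsistent with each other or with the data they are applied to."""


def _check_unit(*values, what: str = "input") -> None:
    for v in values:
        arr = np.asarray(v, dtype=float)
        if np.any(arr < -ATOL) or np.any(arr > 1.0 + ATOL):
            raise DomainError(f"{what} must lie in [0, 1], got {v!r}")


# ---------------------------------------------------------------------------
# Negations
# ---------------------------------------------------------------------------

NegationKind = Literal["standard", "power", "strict_sq", "sugeno"]


class NegationSpec(BaseModel):
    """A fuzzy negation: non-increasing, N(0)=1, N(1)=0.

    ``standard`` and ``sugeno`` are strong (involutive); ``power`` is strong
    only for w=1; ``strict_sq`` (N(p)=1-p^2) is strict but not strong.
    """

    model_config = ConfigDict(frozen=True)

    kind: NegationKind = "standard"
    w: float = 1.0  # power family exponent, > 0
    lam: float = 0.0  # Sugeno family parameter, > -1

    @model_validator(mode="after")
    def _check_params(self) -> "NegationSpec":
        if self.kind == "power" and self.w <= 0:
            raise ParameterError(f"power negation requires w > 0, got w={self.w}")
        if self.kind == "sugeno" and self.lam <= -1:
            raise ParameterError(f"Sugeno negation requires lam > -1, got lam={self.lam}")
        return self


def evaluate_negation(spec: NegationSpec, p):
    """Evaluate the negation N(p) of the named family."""
    _check_unit(p)
    p = np.asarray(p, dtype=float)
    if spec.kind == "standard":
        out = 1.0 - p
    elif spec.kind == "power":
        out = (1.0 - np.clip(p, 0.0, 1.0) ** spec.w) ** (1.0 / spec.w)
    elif spec.kind == "strict_sq":
        out = 1.0 - p**2
    else:  # sugeno
        out = (1.0 - p) / (1.0 + spec.lam * p)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Implications
# ---------------------------------------------------------------------------

ImplicationKind = Literal["lukasiewicz", "fodor", "rescher", "reichenbach", "kleene_dienes"]


class ImplicationSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    kind: ImplicationKind


def evaluate_implication(spec: ImplicationSpec, p, q):
    """Evaluate the fuzzy implication I(p, q) of the named family."""
    _check_unit(p)
    _check_unit(q)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if spec.kind == "lukasiewicz":
        out = np.minimum(1.0, 1.0 - p + q)
    elif spec.kind == "fodor":
        out = np.where(p <= q, 1.0, np.maximum(1.0 - p, q))
    elif spec.kind == "rescher":
        out = np.where(p <= q, 1.0, 0.0)
    elif spec.kind == "reichenbach":
        out = 1.0 - p + p * q
    else:  # kleene_dienes
        out = np.maximum(1.0 - p, q)
    out = np.asarray(out)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Aggregations and pre-aggregations
# ---------------------------------------------------------------------------

AggregatorKind = Literal[
    "tm", "sm", "tp", "sp", "tl", "sl",  # t-norms / t-conorms (binary, associative)
    "amean", "gmean", "qmean",  # means (n-ary)
    "owa",  # ordered weighted averaging (n-ary, weighted)
    "pre_f", "lehmer",  # pre-aggregations (strictly binary)
]

# binary associative kinds extended to n arguments by left-fold
_FOLDABLE = {"tm", "sm", "tp", "sp", "tl", "sl"}
# only directionally monotone: never folded, arity 2 enforced
_BINARY_ONLY = {"pre_f", "lehmer"}


class AggregatorSpec(BaseModel):
    """An aggregation (or pre-aggregation) function on [0,1]^n.

    ``pre_f`` is F(p,q) = p - (max(0, p-q))^2, which is (0,1)-directionally
    increasing but not monotone; ``lehmer`` is the weighted Lehmer mean
    L_lam(p,q) = (lam*p^2 + (1-lam)*q^2) / (lam*p + (1-lam)*q) with 0/0 -> 0,
    which is (1-lam, lam)-increasing.  Both are pre-aggregations, not
    aggregation functions.
    """

    model_config = ConfigDict(frozen=True)

    kind: AggregatorKind
    weights: tuple[float, ...] | None = None  # owa only
    lam: float = 0.5  # lehmer only, in [0, 1]

    @model_validator(mode="after")
    def _check_params(self) -> "AggregatorSpec":
        if self.kind == "owa":
            if not self.weights:
                raise ParameterError("owa requires a weight vector")
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0) or np.any(w > 1):
                raise ParameterError("owa weights must lie in [0, 1]")
            if abs(float(w.sum()) - 1.0) > ATOL:
                raise ParameterError(f"owa weights must sum to 1, got {w.sum()!r}")
        elif self.weights is not None:
            raise ParameterError(f"weights are only meaningful for owa, not {self.kind}")
        if self.kind == "lehmer" and not (0.0 <= self.lam <= 1.0):
            raise ParameterError(f"lehmer requires lam in [0, 1], got {self.lam}")
        return self


def _binary(kind: str, p, q, lam: float = 0.5):
    if kind == "tm":
        return np.minimum(p, q)
    if kind == "sm":
        return np.maximum(p, q)
    if kind == "tp":
        return p * q
    if kind == "sp":
        return p + q - p * q
    if kind == "tl":
        return np.maximum(0.0, p + q - 1.0)
    if kind == "sl":
        return np.minimum(1.0, p + q)
    if kind == "pre_f":
        return p - np.maximum(0.0, p - q) ** 2
    if kind == "lehmer":
        num = lam * p**2 + (1.0 - lam) * q**2
        den = lam * p + (1.0 - lam) * q
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(np.asarray(den) > 0, num / np.where(np.asarray(den) > 0, den, 1.0), 0.0)
        return out
    raise ConfigurationError(f"{kind} is not a binary aggregator")


def apply_binary(spec: AggregatorSpec, p, q):
    """Apply a binary (or binary-capable) aggregator to a pair, with broadcasting."""
    _check_unit(p)
    _check_unit(q)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if spec.kind in _FOLDABLE or spec.kind in _BINARY_ONLY:
        out = np.asarray(_binary(spec.kind, p, q, spec.lam))
    elif spec.kind == "amean":
        out = (p + q) / 2.0
    elif spec.kind == "gmean":
        out = np.sqrt(p * q)
    elif spec.kind == "qmean":
        out = np.sqrt((p**2 + q**2) / 2.0)
    elif spec.kind == "owa":
        if spec.weights is None or len(spec.weights) != 2:
            raise ConfigurationError("binary owa application requires exactly 2 weights")
        hi = np.maximum(p, q)
        lo = np.minimum(p, q)
        out = np.asarray(spec.weights[0] * hi + spec.weights[1] * lo)
    else:
        raise ConfigurationError(f"{spec.kind} cannot be applied as a binary aggregator")
    out = np.asarray(np.clip(out, 0.0, 1.0))
    return out if out.ndim else float(out)


def aggregate(spec: AggregatorSpec, values: Sequence):
    """Aggregate a non-empty list of unit-interval values (or aligned arrays).

    Associative t-norms/t-conorms extend to n > 2 arguments by left-fold;
    ``pre_f`` and ``lehmer`` are strictly binary and raise for other arities.
    A single value passes through unchanged (after validation).
    """
    if len(values) == 0:
        raise ConfigurationError("cannot aggregate an empty list")
    for v in values:
        _check_unit(v)
    vals = [np.asarray(v, dtype=float) for v in values]
    n = len(vals)

    if spec.kind in _BINARY_ONLY:
        if n == 1:
            out = vals[0]
        elif n == 2:
            out = np.asarray(_binary(spec.kind, vals[0], vals[1], spec.lam))
        else:
            raise ConfigurationError(
                f"{spec.kind} is a strictly binary pre-aggregation (got {n} arguments)"
            )
    elif spec.kind in _FOLDABLE:
        out = np.asarray(reduce(lambda a, b: _binary(spec.kind, a, b), vals))
    elif spec.kind == "amean":
        out = np.mean(np.stack(np.broadcast_arrays(*vals)), axis=0) if n > 1 else vals[0]
    elif spec.kind == "gmean":
        stacked = np.stack(np.broadcast_arrays(*vals))
        out = np.prod(stacked, axis=0) ** (1.0 / n)
    elif spec.kind == "qmean":
        stacked = np.stack(np.broadcast_arrays(*vals))
        out = np.sqrt(np.mean(stacked**2, axis=0))
    elif spec.kind == "owa":
        if spec.weights is None or len(spec.weights) != n:
            raise ConfigurationError(
                f"owa weight vector length {0 if spec.weights is None else len(spec.weights)} "
                f"does not match {n} values"
            )
        stacked = np.stack(np.broadcast_arrays(*vals))
        # descending sort along the value axis; stable, permutation-invariant
        ordered = np.sort(stacked, axis=0)[::-1]
        w = np.asarray(spec.weights, dtype=float).reshape((n,) + (1,) * (ordered.ndim - 1))
        out = np.sum(w * ordered, axis=0)
    else:  # pragma: no cover - exhaustiveness guard
        raise ConfigurationError(f"unknown aggregator kind {spec.kind}")

    out = np.asarray(np.clip(out, 0.0, 1.0))
    return out if out.ndim else float(out)
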