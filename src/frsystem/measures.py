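"""Precedence indicators, knowledge measures, and the knowledge-augmented
premise combiner OR.

A *precedence indicator* Prec(p, q) grades how strongly membership degree p
"precedes" (is included in) q: it equals 1 exactly when p <= q, equals 0 only
at (1, 0), and is antitone in p / isotone in q (axioms P1-P3).  One is built
constructively from any aggregation A <= max and fuzzy negation N as

    Prec(p, q) = 1            if p <= q
                 A(N(p), q)   otherwise.

A *knowledge measure* K is the dual of fuzzy entropy: maximal exactly on
crisp degree vectors, minimal exactly on the all-0.5 vector, monotone under
sharpening, and complement-invariant (axioms K1-K4).  The precedence-based
construction compares each degree x with the two certain extremes:

    K = mean over x of |Prec(1,x) - Prec(x,0)| / (1 - min(Prec(1,x), Prec(x,0)))

which for the max-aggregator / standard-negation indicator has the closed
form |2x-1| / (1 - min(x, 1-x)).  Two literature measures are provided as
baselines: K_SLS = mean(2[x^2+(1-x)^2] - 1) and K_AK = log2(2*mean(x^2+(1-x)^2)).
"""

from __future__ import annotations

from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .fuzzy_core import (
    ATOL,
    AggregatorSpec,
    ConfigurationError,
    DomainError,
    NegationSpec,
    ParameterError,
    apply_binary,
    evaluate_negation,
)

__all__ = [
    "InvariantViolationError",
    "PrecedenceSpec",
    "KnowledgeSpec",
    "precedence",
    "knowledge",
    "operator_or",
]

_GRID = np.linspace(0.0, 1.0, 101)


class InvariantViolationError(RuntimeError):
    """A guarded mathematical invariant failed at run time."""


class PrecedenceSpec(BaseModel):
    """Constructive precedence indicator from (aggregator, negation).

    The aggregator must satisfy A(p,q) <= max(p,q) pointwise; this is checked
    empirically on a 101x101 grid at construction time because specs are
    user-composable (a symbolic proof per kind would not cover OWA weights
    etc.).
    """

    model_config = ConfigDict(frozen=True)

    aggregator: AggregatorSpec
    negation: NegationSpec = NegationSpec(kind="standard")

    @model_validator(mode="after")
    def _check_below_max(self) -> "PrecedenceSpec":
        p, q = np.meshgrid(_GRID, _GRID, indexing="ij")
        a = apply_binary(self.aggregator, p, q)
        if np.any(np.asarray(a) > np.maximum(p, q) + ATOL):
            raise ParameterError(
                f"aggregator {self.aggregator.kind} violates A <= max, cannot build "
                "a precedence indicator from it"
            )
        return self


def precedence(spec: PrecedenceSpec, p, q):
    """Evaluate Prec(p, q); accepts floats or broadcasting arrays."""
    pa = np.asarray(p, dtype=float)
    qa = np.asarray(q, dtype=float)
    if np.any(pa < -ATOL) or np.any(pa > 1 + ATOL) or np.any(qa < -ATOL) or np.any(qa > 1 + ATOL):
        raise DomainError("precedence arguments must lie in [0, 1]")
    body = apply_binary(spec.aggregator, evaluate_negation(spec.negation, pa), qa)
    out = np.asarray(np.where(pa <= qa, 1.0, body))
    return out if out.ndim else float(out)


KnowledgeKind = Literal["prec_based", "sls", "ak"]


class KnowledgeSpec(BaseModel):
    """A knowledge measure over a vector of membership degrees.

    ``prec_based`` requires a precedence indicator whose aggregator is
    symmetric and whose negation is strong with equilibrium 0.5 (otherwise
    axioms K2/K4 are not guaranteed); both requirements are verified on a
    grid at construction.  ``sls`` and ``ak`` are the quadratic literature
    baselines and take no parameters.
    """

    model_config = ConfigDict(frozen=True)

    kind: KnowledgeKind = "prec_based"
    precedence: Optional[PrecedenceSpec] = None

    @model_validator(mode="after")
    def _check_construction(self) -> "KnowledgeSpec":
        if self.kind != "prec_based":
            if self.precedence is not None:
                raise ConfigurationError(f"{self.kind} takes no precedence indicator")
            return self
        if self.precedence is None:
            raise ConfigurationError("prec_based knowledge measure requires a precedence spec")
        ps = self.precedence
        p, q = np.meshgrid(_GRID, _GRID, indexing="ij")
        a_pq = apply_binary(ps.aggregator, p, q)
        a_qp = apply_binary(ps.aggregator, q, p)
        if np.any(np.abs(np.asarray(a_pq) - np.asarray(a_qp)) > 1e-9):
            raise ParameterError(
                f"aggregator {ps.aggregator.kind} is not symmetric; the knowledge "
                "construction requires a symmetric aggregation"
            )
        n_n = evaluate_negation(ps.negation, evaluate_negation(ps.negation, _GRID))
        if np.any(np.abs(np.asarray(n_n) - _GRID) > 1e-9):
            raise ParameterError(f"negation {ps.negation.kind} is not strong (involutive)")
        if abs(evaluate_negation(ps.negation, 0.5) - 0.5) > 1e-9:
            raise ParameterError("negation must have equilibrium 0.5 (N(0.5) = 0.5)")
        return self


def knowledge(spec: KnowledgeSpec, degrees: Sequence):
    """Amount of knowledge (certainty) carried by a vector of degrees, in [0, 1].

    Accepts a non-empty list of floats, or of aligned arrays for a vectorised
    batch (the mean is then taken across the list axis, elementwise).
    """
    if len(degrees) == 0:
        raise ConfigurationError("knowledge of an empty degree vector is undefined")
    x = np.stack(np.broadcast_arrays(*[np.asarray(d, dtype=float) for d in degrees]))
    if np.any(x < -ATOL) or np.any(x > 1 + ATOL):
        raise DomainError("membership degrees must lie in [0, 1]")

    if spec.kind == "sls":
        out = np.mean(2.0 * (x**2 + (1.0 - x) ** 2) - 1.0, axis=0)
    elif spec.kind == "ak":
        out = np.log2(2.0 * np.mean(x**2 + (1.0 - x) ** 2, axis=0))
    else:
        ps = spec.precedence
        upper = precedence(ps, np.ones_like(x), x)  # Prec(1, x)
        lower = precedence(ps, x, np.zeros_like(x))  # Prec(x, 0)
        num = np.abs(np.asarray(upper) - np.asarray(lower))
        den = 1.0 - np.minimum(upper, lower)
        if np.any(den <= ATOL):
            raise InvariantViolationError(
                "degenerate denominator in the precedence-based knowledge term; "
                "the precedence spec does not satisfy the construction requirements"
            )
        out = np.mean(num / den, axis=0)

    out = np.asarray(np.clip(out, 0.0, 1.0))
    return out if out.ndim else float(out)


def operator_or(
    premises: Sequence,
    inner: AggregatorSpec,
    outer: AggregatorSpec,
    kspec: KnowledgeSpec,
):
    """Knowledge-augmented premise combination OR = B(A(premises), K(premises)).

    ``inner`` (A) aggregates the premise degrees of a rule, ``kspec`` measures
    how much certain knowledge those degrees carry, and the binary ``outer``
    (B) merges the two — so maximally fuzzy premises (all 0.5) are suppressed
    rather than propagated at half strength.
    """
    from .fuzzy_core import aggregate  # local import: avoids re-export confusion

    if len(premises) == 0:
        raise ConfigurationError("operator OR requires at least one premise")
    strength = aggregate(inner, list(premises))
    k = knowledge(kspec, list(premises))
    return aggregate(outer, [strength, k])
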