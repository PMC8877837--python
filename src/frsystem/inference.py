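"""Mamdani inference over the posture rule base, in two premise-combination
modes.

*classic* mode activates each rule by plainly aggregating its premise
membership degrees; *knowledge* mode uses the OR operator
B(A(premises), K(premises)), which discounts rules whose premises are
maximally uncertain.  Per pose class, rule activations are merged by
maximum; the class consequent curve is clipped at the class activation
(min by default); the three clipped sets are merged pointwise by maximum
into a single output set on the pose universe, defuzzified by centre of
gravity.  A frame is called lying (isLy) when the centroid falls below the
decision threshold (default 0.5, the crossover region between the isLy and
notLy consequent curves).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .fuzzy_core import (
    AggregatorSpec,
    ConfigurationError,
    NegationSpec,
    aggregate,
    apply_binary,
)
from .fuzzification import (
    FEATURES,
    POSE_LABELS,
    FeatureVector,
    LinguisticVariable,
    eval_mf,
    fuzzify,
)
from .measures import KnowledgeSpec, PrecedenceSpec, operator_or
from .rule_induction import Rule, RuleSet

__all__ = [
    "DiscreteFuzzySet",
    "InferenceConfig",
    "DefuzzificationError",
    "knowledge_presets",
    "rule_activation",
    "infer_output_set",
    "cog_defuzzify",
    "classify",
    "classify_batch",
    "gmp_compose",
    "relation_from_implication",
    "implication_from_aggregation",
]


class DefuzzificationError(RuntimeError):
    """The output set carries no mass, so its centroid is undefined."""


@dataclass(frozen=True)
class DiscreteFuzzySet:
    """Membership degrees sampled on a strictly increasing finite grid."""

    universe: np.ndarray
    degrees: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.universe, dtype=float)
        d = np.asarray(self.degrees, dtype=float)
        if u.ndim != 1 or d.shape != u.shape:
            raise ConfigurationError("universe and degrees must be aligned 1-D arrays")
        if np.any(np.diff(u) <= 0):
            raise ConfigurationError("the universe grid must be strictly increasing")
        if np.any(d < -1e-12) or np.any(d > 1 + 1e-12):
            raise ConfigurationError("degrees must lie in [0, 1]")
        object.__setattr__(self, "universe", u)
        object.__setattr__(self, "degrees", np.clip(d, 0.0, 1.0))


class InferenceConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    mode: Literal["classic", "knowledge"] = "classic"
    premise_aggregator: AggregatorSpec = AggregatorSpec(kind="amean")
    combiner: Optional[AggregatorSpec] = None  # B, binary; knowledge mode only
    kspec: Optional[KnowledgeSpec] = None  # knowledge mode only
    implication_clip: AggregatorSpec = AggregatorSpec(kind="tm")
    grid_points: int = 1001
    decision_threshold: float = 0.5

    @model_validator(mode="after")
    def _check(self) -> "InferenceConfig":
        if self.mode == "knowledge" and (self.combiner is None or self.kspec is None):
            raise ConfigurationError("knowledge mode requires both a combiner and a kspec")
        if self.grid_points < 101:
            raise ConfigurationError("grid_points must be at least 101")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ConfigurationError("decision_threshold must lie in (0, 1)")
        return self


def _prec(agg_kind: str) -> PrecedenceSpec:
    return PrecedenceSpec(
        aggregator=AggregatorSpec(kind=agg_kind), negation=NegationSpec(kind="standard")
    )


def knowledge_presets(grid_points: int = 1001) -> dict[str, InferenceConfig]:
    """The five studied knowledge-mode configurations K1–K5.

    Notation K(A, B, P): A aggregates the premises, B combines strength with
    knowledge, and P is the aggregator inside the precedence indicator the
    knowledge measure is built on (standard negation throughout).
    """

    def cfg(inner: str, outer: str, prec: str) -> InferenceConfig:
        return InferenceConfig(
            mode="knowledge",
            premise_aggregator=AggregatorSpec(kind=inner),
            combiner=AggregatorSpec(kind=outer),
            kspec=KnowledgeSpec(kind="prec_based", precedence=_prec(prec)),
            grid_points=grid_points,
        )

    return {
        "K1": cfg("qmean", "pre_f", "qmean"),
        "K2": cfg("qmean", "pre_f", "sm"),
        "K3": cfg("tm", "pre_f", "qmean"),
        "K4": cfg("amean", "pre_f", "amean"),
        "K5": cfg("amean", "tm", "sm"),
    }


def rule_activation(
    rule: Rule,
    degrees: Mapping[str, Mapping[str, float]],
    config: InferenceConfig,
):
    """Activation strength of one rule given fuzzified feature degrees.

    ``degrees`` maps feature -> label -> membership; values may be floats or
    aligned arrays (vectorised batches).
    """
    premises = []
    for feat, label in rule.antecedent:
        if feat not in degrees or label not in degrees[feat]:
            raise KeyError(f"no membership degree for condition {feat!r} = {label!r}")
        premises.append(degrees[feat][label])
    if config.mode == "classic":
        return aggregate(config.premise_aggregator, premises)
    return operator_or(premises, config.premise_aggregator, config.combiner, config.kspec)


@dataclass
class InferenceResult:
    class_sets: dict[str, DiscreteFuzzySet]
    activations: dict[str, float]
    output: DiscreteFuzzySet  # pointwise-maximum union of the class sets


def infer_output_set(
    rules: RuleSet,
    fv: FeatureVector,
    config: InferenceConfig,
    variables: Mapping[str, LinguisticVariable],
) -> InferenceResult:
    """Run the rule base on one frame and build the clipped pose output set."""
    if not rules:
        raise ConfigurationError("the rule set is empty")
    pose = variables["pose"]
    unknown = {r.consequent for r in rules} - set(pose.label_order)
    if unknown:
        raise ConfigurationError(f"rules reference unknown pose classes: {sorted(unknown)}")

    degrees = {f: fuzzify(variables[f], getattr(fv, f)) for f in FEATURES}
    activations = {c: 0.0 for c in pose.label_order}
    for rule in rules:
        act = float(rule_activation(rule, degrees, config))
        if act > activations[rule.consequent]:  # per-class max aggregation
            activations[rule.consequent] = act

    lo, hi = pose.universe
    grid = np.linspace(lo, hi, config.grid_points)
    class_sets: dict[str, DiscreteFuzzySet] = {}
    merged = np.zeros_like(grid)
    for c in pose.label_order:
        cons = eval_mf(pose.labels[c], grid)
        clipped = np.asarray(
            apply_binary(config.implication_clip, np.full_like(grid, activations[c]), cons)
        )
        class_sets[c] = DiscreteFuzzySet(universe=grid, degrees=clipped)
        merged = np.maximum(merged, clipped)
    return InferenceResult(
        class_sets=class_sets,
        activations=activations,
        output=DiscreteFuzzySet(universe=grid, degrees=merged),
    )


def cog_defuzzify(fs: DiscreteFuzzySet) -> float:
    """Centre of gravity: the membership-weighted mean of the grid."""
    mass = float(np.sum(fs.degrees))
    if mass <= 0.0:
        raise DefuzzificationError("all-zero output set: the centroid is undefined")
    return float(np.sum(fs.universe * fs.degrees) / mass)


@dataclass
class ClassificationResult:
    pose_label: str
    cog_score: Optional[float]
    class_activations: dict[str, float]


def classify(
    fv: FeatureVector,
    rules: RuleSet,
    config: InferenceConfig,
    variables: Mapping[str, LinguisticVariable],
) -> ClassificationResult:
    """Binary lying/not-lying decision for one frame.

    An all-zero output set (no rule fired at all) maps to notLy with a
    warning — absence of evidence for lying must not raise an alarm.
    """
    res = infer_output_set(rules, fv, config, variables)
    try:
        cog = cog_defuzzify(res.output)
    except DefuzzificationError:
        warnings.warn("no rule fired; defaulting to notLy", stacklevel=2)
        return ClassificationResult("notLy", None, res.activations)
    label = "isLy" if cog < config.decision_threshold else "notLy"
    return ClassificationResult(label, cog, res.activations)


# ---------------------------------------------------------------------------
# Vectorised batch path (identical semantics, one pass over a feature table)
# ---------------------------------------------------------------------------


def _batch_degrees(
    df: pd.DataFrame, variables: Mapping[str, LinguisticVariable]
) -> dict[str, dict[str, np.ndarray]]:
    out: dict[str, dict[str, np.ndarray]] = {}
    for f in FEATURES:
        var = variables[f]
        lo, hi = var.universe
        x = np.clip(df[f].to_numpy(dtype=float), lo, hi)
        out[f] = {label: np.asarray(eval_mf(mf, x)) for label, mf in var.labels.items()}
    return out


def classify_batch(
    df: pd.DataFrame,
    rules: RuleSet,
    config: InferenceConfig,
    variables: Mapping[str, LinguisticVariable],
) -> pd.DataFrame:
    """Classify every row of a feature table; returns the input columns plus
    ``cog``, ``pose_label`` and one activation column per pose class."""
    if not rules:
        raise ConfigurationError("the rule set is empty")
    if df.empty:
        out = df.copy()
        for c in ("cog", "pose_label"):
            out[c] = []
        return out
    pose = variables["pose"]
    n = len(df)
    degrees = _batch_degrees(df, variables)

    acts = {c: np.zeros(n) for c in pose.label_order}
    for rule in rules:
        act = np.asarray(rule_activation(rule, degrees, config))
        acts[rule.consequent] = np.maximum(acts[rule.consequent], act)

    lo, hi = pose.universe
    grid = np.linspace(lo, hi, config.grid_points)
    merged = np.zeros((n, grid.size))
    for c in pose.label_order:
        cons = np.asarray(eval_mf(pose.labels[c], grid))
        clipped = np.asarray(
            apply_binary(config.implication_clip, acts[c][:, None], cons[None, :])
        )
        merged = np.maximum(merged, clipped)

    mass = merged.sum(axis=1)
    fired = mass > 0
    cog = np.full(n, np.nan)
    cog[fired] = (merged[fired] @ grid) / mass[fired]
    labels = np.where(fired & (cog < config.decision_threshold), "isLy", "notLy")
    if not np.all(fired):
        warnings.warn(f"{int((~fired).sum())} frames fired no rule; defaulted to notLy",
                      stacklevel=2)

    out = df.copy()
    out["cog"] = cog
    out["pose_label"] = labels
    for c in pose.label_order:
        out[f"act_{c}"] = acts[c]
    return out


# ---------------------------------------------------------------------------
# Generalized modus ponens (aggregation-based composition)
# ---------------------------------------------------------------------------


def gmp_compose(
    input_degrees: Sequence[float] | np.ndarray,
    relation: np.ndarray,
    outer: AggregatorSpec,
    inner: AggregatorSpec,
) -> np.ndarray:
    """E'(q) = A_p B(D'(p), R(p, q)): compose a fact set with a fuzzy relation.

    ``outer`` (A) aggregates over the input universe P, ``inner`` (B) pairs
    the fact degree with the relation column.  Sup-min composition is
    outer=sm, inner=tm.
    """
    d = np.asarray(input_degrees, dtype=float)
    rel = np.asarray(relation, dtype=float)
    if rel.ndim != 2 or d.ndim != 1 or rel.shape[0] != d.size:
        raise ConfigurationError(
            f"dimension mismatch: fact has {d.size} points, relation is {rel.shape}"
        )
    paired = np.asarray(apply_binary(inner, d[:, None], rel))  # |P| x |Q|
    return np.asarray(aggregate(outer, list(paired)))


def relation_from_implication(
    antecedent_degrees: Sequence[float] | np.ndarray,
    consequent_degrees: Sequence[float] | np.ndarray,
    implication,
) -> np.ndarray:
    """R(p, q) = I(D(p), E(q)) for an implication spec."""
    from .fuzzy_core import evaluate_implication

    d = np.asarray(antecedent_degrees, dtype=float)
    e = np.asarray(consequent_degrees, dtype=float)
    return np.asarray(evaluate_implication(implication, d[:, None], e[None, :]))


def implication_from_aggregation(agg: AggregatorSpec):
    """Build I(p, q) = A(1 - p, q); requires A(1, 0) = A(0, 1) = 1."""
    if abs(float(apply_binary(agg, 1.0, 0.0)) - 1.0) > 1e-12 or abs(
        float(apply_binary(agg, 0.0, 1.0)) - 1.0
    ) > 1e-12:
        raise ConfigurationError(
            f"aggregator {agg.kind} does not satisfy A(1,0) = A(0,1) = 1; it cannot "
            "induce an implication"
        )

    def impl(p, q):
        return apply_binary(agg, 1.0 - np.asarray(p, dtype=float), q)

    return impl
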