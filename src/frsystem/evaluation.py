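"""Confusion metrics, synthetic posture-feature generation, and the
experiment driver comparing inference modes and rule sets.

The positive class throughout is isLy (lying): TP counts correctly detected
lying frames, TN correctly detected non-lying ones, so specificity is the
not-lying detection rate.  The synthetic generator draws feature vectors
around the full-membership cores of the linguistic profiles that
characterise each pose (lying: hw Lo, hmax Lo, sigma Lo∨Me, p40 Hi;
not-lying: hw Hi∨Me, hmax Hi∨Me, sigma Lo, p40 Lo), adds Gaussian noise
scaled to each curve's transition width, and flips a small fraction of class
labels to create overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .fuzzy_core import AggregatorSpec, ConfigurationError
from .fuzzification import (
    FEATURES,
    LinguisticVariable,
    load_default_config,
    mf_core,
    mf_width,
)
from .inference import InferenceConfig, classify_batch, knowledge_presets
from .rule_induction import (
    RuleSet,
    discretize,
    enumerate_knowledge_rules,
    induce_ruleset,
    rule_effectiveness,
)

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "metrics",
    "round3",
    "confusion_from_predictions",
    "SynthProfile",
    "default_profiles",
    "synth_generate",
    "run_experiment",
    "ExperimentReport",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ConfigurationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    """ACC, PRE, REC, SPE; a metric whose denominator is zero is None."""

    acc: Optional[float]
    pre: Optional[float]
    rec: Optional[float]
    spe: Optional[float]


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def metrics(c: ConfusionCounts) -> Metrics:
    """ACC=(TP+TN)/total, PRE=TP/(TP+FP), REC=TP/(TP+FN), SPE=TN/(TN+FP)."""
    return Metrics(
        acc=_ratio(c.tp + c.tn, c.total),
        pre=_ratio(c.tp, c.tp + c.fp),
        rec=_ratio(c.tp, c.tp + c.fn),
        spe=_ratio(c.tn, c.tn + c.fp),
    )


def round3(x: Optional[float]) -> Optional[float]:
    """Half-up rounding to 3 decimals, matching printed-table precision."""
    if x is None:
        return None
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def confusion_from_predictions(
    truth: Sequence[str], predicted: Sequence[str]
) -> ConfusionCounts:
    if len(truth) != len(predicted):
        raise ConfigurationError("truth and prediction vectors differ in length")
    counts = {"tp": 0, "tn": 0, "fp": 0, "fn": 0}
    for t, p in zip(truth, predicted):
        if t not in ("isLy", "notLy") or p not in ("isLy", "notLy"):
            raise ConfigurationError(f"labels must be isLy/notLy, got ({t!r}, {p!r})")
        if t == "isLy":
            counts["tp" if p == "isLy" else "fn"] += 1
        else:
            counts["tn" if p == "notLy" else "fp"] += 1
    return ConfusionCounts(**counts)


# ---------------------------------------------------------------------------
# Synthetic data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SynthProfile:
    """Target linguistic labels per feature for one pose class.

    A tuple of labels for a feature is a disjunction: the label is chosen
    uniformly per sample.  ``noise_scale`` multiplies each curve's transition
    width to give the Gaussian jitter; ``mislabel_rate`` is the fraction of
    samples whose class label is swapped to create class overlap.
    """

    class_label: str
    labels: Mapping[str, tuple[str, ...]]
    noise_scale: float = 0.15
    mislabel_rate: float = 0.02

    def __post_init__(self) -> None:
        if self.noise_scale <= 0:
            raise ConfigurationError("noise_scale must be positive")
        if not 0.0 <= self.mislabel_rate < 0.5:
            raise ConfigurationError("mislabel_rate must lie in [0, 0.5)")
        missing = [f for f in FEATURES if f not in self.labels or not self.labels[f]]
        if missing:
            raise ConfigurationError(f"profile lacks target labels for {missing}")


def default_profiles(
    noise_scale: float = 0.15, mislabel_rate: float = 0.02
) -> tuple[SynthProfile, SynthProfile]:
    """The two pose-class profiles derived from the most relevant attribute values."""
    is_ly = SynthProfile(
        class_label="isLy",
        labels={"hw": ("Lo",), "hmax": ("Lo",), "sigma": ("Lo", "Me"), "p40": ("Hi",)},
        noise_scale=noise_scale,
        mislabel_rate=mislabel_rate,
    )
    not_ly = SynthProfile(
        class_label="notLy",
        labels={"hw": ("Hi", "Me"), "hmax": ("Hi", "Me"), "sigma": ("Lo",), "p40": ("Lo",)},
        noise_scale=noise_scale,
        mislabel_rate=mislabel_rate,
    )
    return (is_ly, not_ly)


def synth_generate(
    n_per_class: int,
    profiles: Optional[Sequence[SynthProfile]] = None,
    seed: int = 0,
    variables: Optional[Mapping[str, LinguisticVariable]] = None,
) -> pd.DataFrame:
    """Draw a labelled feature table with ``n_per_class`` samples per profile.

    Per sample and feature: pick one target label from the profile's
    disjunction, draw uniformly inside that curve's full-membership core,
    then add N(0, noise_scale * transition_width) jitter, clamped to the
    universe.  A ``mislabel_rate`` fraction of each class swaps its label.
    Identical seeds give identical tables.
    """
    if n_per_class < 0:
        raise ConfigurationError("n_per_class must be non-negative")
    if profiles is None:
        profiles = default_profiles()
    if variables is None:
        variables = load_default_config()
    rng = np.random.default_rng(seed)
    other = {"isLy": "notLy", "notLy": "isLy"}

    rows: dict[str, list] = {f: [] for f in FEATURES}
    rows["label"] = []
    for profile in profiles:
        for f in FEATURES:
            var = variables[f]
            lo, hi = var.universe
            choices = profile.labels[f]
            picks = rng.integers(0, len(choices), size=n_per_class)
            vals = np.empty(n_per_class)
            for j, label in enumerate(choices):
                mask = picks == j
                k = int(mask.sum())
                if k == 0:
                    continue
                mf = var.labels[label]
                core_lo, core_hi = mf_core(mf, var.universe)
                base = rng.uniform(core_lo, core_hi, size=k)
                jitter = rng.normal(0.0, profile.noise_scale * mf_width(mf), size=k)
                vals[mask] = np.clip(base + jitter, lo, hi)
            rows[f].extend(vals.tolist())
        flips = rng.random(n_per_class) < profile.mislabel_rate
        rows["label"].extend(
            [other[profile.class_label] if fl else profile.class_label for fl in flips]
        )
    df = pd.DataFrame(rows)
    # p40 is a fraction by definition
    df["p40"] = df["p40"].clip(0.0, 1.0)
    return df


# ---------------------------------------------------------------------------
# Experiment driver
# ---------------------------------------------------------------------------


def _owa_linear_weights(n: int) -> tuple[float, ...]:
    # linearly decreasing weights favouring the strongest premises
    w = np.arange(n, 0, -1, dtype=float)
    return tuple(w / w.sum())


def classic_presets(grid_points: int = 1001) -> dict[str, InferenceConfig]:
    """Classic-mode premise aggregators studied alongside the knowledge modes.

    The binary-only pre-aggregation F is excluded here: classic mode feeds it
    rule antecedents of arbitrary arity and F does not extend beyond pairs.
    """
    kinds = {"Tm": "tm", "Tp": "tp", "Amean": "amean"}
    out = {
        name: InferenceConfig(
            mode="classic",
            premise_aggregator=AggregatorSpec(kind=kind),
            grid_points=grid_points,
        )
        for name, kind in kinds.items()
    }
    out["OWA"] = InferenceConfig(
        mode="classic",
        premise_aggregator=AggregatorSpec(kind="owa", weights=_owa_linear_weights(4)),
        grid_points=grid_points,
    )
    return out


def _activation_config_for_rule(config: InferenceConfig, n_conditions: int) -> InferenceConfig:
    # OWA weights must match the rule's arity; regenerate per arity
    if config.premise_aggregator.kind == "owa" and (
        config.premise_aggregator.weights is None
        or len(config.premise_aggregator.weights) != n_conditions
    ):
        return config.model_copy(
            update={
                "premise_aggregator": AggregatorSpec(
                    kind="owa", weights=_owa_linear_weights(n_conditions)
                )
            }
        )
    return config


@dataclass
class RuleRankEntry:
    rule_index: int
    consequent: str
    n_correct: int
    effectiveness_set: float
    effectiveness_class: float


@dataclass
class ExperimentReport:
    table: pd.DataFrame  # one row per (mode x config x rule source)
    rankings: dict[str, list[RuleRankEntry]] = field(default_factory=dict)

    def to_text(self) -> str:
        lines = [self.table.to_string(index=False)]
        return "\n".join(lines)


def _evaluate_config(
    name: str,
    config: InferenceConfig,
    rules: RuleSet,
    df: pd.DataFrame,
    variables: Mapping[str, LinguisticVariable],
) -> tuple[dict, list[RuleRankEntry]]:
    import warnings as _warnings

    from .inference import _batch_degrees, rule_activation

    n = len(df)
    degrees = _batch_degrees(df, variables)
    # per-rule activations (needed for both classification and ranking)
    act_matrix = np.zeros((len(rules), n))
    for i, rule in enumerate(rules):
        cfg_i = _activation_config_for_rule(config, len(rule.antecedent))
        act_matrix[i] = np.asarray(rule_activation(rule, degrees, cfg_i))

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        # classify_batch recomputes activations; acceptable at these sizes and
        # keeps one code path authoritative for the decision itself
        pred_df = _classify_with_matrix(df, rules, act_matrix, config, variables)
    truth = list(df["label"])
    pred = list(pred_df["pose_label"])
    counts = confusion_from_predictions(truth, pred)
    m = metrics(counts)

    # rule ranking: credit each object to its strongest rule (first on ties)
    winner = np.argmax(act_matrix, axis=0)
    correct = np.asarray([t == p for t, p in zip(truth, pred)])
    ranking: list[RuleRankEntry] = []
    for i, rule in enumerate(rules):
        won = winner == i
        n_correct = int(np.sum(won & correct))
        in_class = np.asarray([t == rule.consequent for t in truth])
        class_size = int(in_class.sum())
        n_correct_class = int(np.sum(won & correct & in_class))
        e_set, e_class = rule_effectiveness(n_correct, n, n_correct_class, class_size)
        ranking.append(RuleRankEntry(i, rule.consequent, n_correct, e_set, e_class))
    ranking.sort(key=lambda r: (-r.effectiveness_set, -r.effectiveness_class, r.rule_index))

    row = {
        "config": name,
        "mode": config.mode,
        "inner": config.premise_aggregator.kind,
        "outer": config.combiner.kind if config.combiner else "",
        "kmeasure": (
            config.kspec.precedence.aggregator.kind
            if config.kspec and config.kspec.precedence
            else (config.kspec.kind if config.kspec else "")
        ),
        "n_rules": len(rules),
        "tp": counts.tp,
        "tn": counts.tn,
        "fp": counts.fp,
        "fn": counts.fn,
        "acc": m.acc,
        "pre": m.pre,
        "rec": m.rec,
        "spe": m.spe,
    }
    return row, ranking


def _classify_with_matrix(df, rules, act_matrix, config, variables):
    """Finish classification from a precomputed per-rule activation matrix."""
    from .fuzzy_core import apply_binary
    from .fuzzification import eval_mf

    pose = variables["pose"]
    n = len(df)
    acts = {c: np.zeros(n) for c in pose.label_order}
    for i, rule in enumerate(rules):
        acts[rule.consequent] = np.maximum(acts[rule.consequent], act_matrix[i])
    lo, hi = pose.universe
    grid = np.linspace(lo, hi, config.grid_points)
    merged = np.zeros((n, grid.size))
    for c in pose.label_order:
        cons = np.asarray(eval_mf(pose.labels[c], grid))
        clipped = np.asarray(apply_binary(config.implication_clip, acts[c][:, None], cons[None, :]))
        merged = np.maximum(merged, clipped)
    mass = merged.sum(axis=1)
    fired = mass > 0
    cog = np.full(n, np.nan)
    cog[fired] = (merged[fired] @ grid) / mass[fired]
    out = df.copy()
    out["cog"] = cog
    out["pose_label"] = np.where(fired & (cog < config.decision_threshold), "isLy", "notLy")
    return out


def run_experiment(
    n_per_class: int = 500,
    seed: int = 42,
    modes: Sequence[str] = ("classic", "knowledge"),
    rule_sources: Sequence[str] = ("enumerated", "lem2"),
    noise_scale: float = 0.15,
    mislabel_rate: float = 0.02,
    variables: Optional[Mapping[str, LinguisticVariable]] = None,
    grid_points: int = 1001,
) -> ExperimentReport:
    """Generate synthetic data, build both rule sets, and score every
    (mode-configuration x rule source) combination.

    The LEM2 set is induced from the argmax-discretized synthetic table
    itself (train = test at this desk scale; the comparison of interest is
    full vs reduced rule set under identical conditions, not generalisation).
    """
    if variables is None:
        variables = load_default_config()
    df = synth_generate(
        n_per_class,
        default_profiles(noise_scale=noise_scale, mislabel_rate=mislabel_rate),
        seed=seed,
        variables=variables,
    )
    if df.empty:
        raise ConfigurationError("run_experiment needs a non-empty synthetic table")

    rulesets: dict[str, RuleSet] = {}
    if "enumerated" in rule_sources:
        rulesets["enumerated"] = enumerate_knowledge_rules()
    if "lem2" in rule_sources:
        table = discretize(df, variables)
        rulesets["lem2"] = induce_ruleset(table)

    configs: dict[str, InferenceConfig] = {}
    if "classic" in modes:
        configs.update(classic_presets(grid_points))
    if "knowledge" in modes:
        configs.update(knowledge_presets(grid_points))

    rows = []
    rankings: dict[str, list[RuleRankEntry]] = {}
    for cname, config in configs.items():
        for sname, rules in rulesets.items():
            row, ranking = _evaluate_config(cname, config, rules, df, variables)
            row["ruleset"] = sname
            rows.append(row)
            rankings[f"{cname}/{sname}"] = ranking
    cols = [
        "config", "mode", "inner", "outer", "kmeasure", "ruleset", "n_rules",
        "tp", "tn", "fp", "fn", "acc", "pre", "rec", "spe",
    ]
    return ExperimentReport(table=pd.DataFrame(rows)[cols], rankings=rankings)
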