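"""Rough-set rule machinery: decision tables, attribute-value blocks, LEM2
local coverings, and the combinatorial knowledge-approach rule set.

A decision table is an information system (U, A ∪ {d}, V, f) with discrete
attribute values.  LEM2 induces, per decision concept X, a *local covering*:
a minimal family of minimal complexes (irreducible conjunctions of
attribute-value pairs) whose blocks jointly cover X and each lie inside X.
The knowledge-approach set instead enumerates every Lo/Me/Hi conjunction over
the four posture features (3^4 = 81 rules) and maps each to a pose class.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .fuzzy_core import ConfigurationError
from .fuzzification import FEATURES, INPUT_LABELS, LinguisticVariable, fuzzify

__all__ = [
    "InconsistentTableError",
    "DecisionTable",
    "AttributeValuePair",
    "LocalCovering",
    "Rule",
    "RuleSet",
    "block",
    "lem2",
    "induce_ruleset",
    "discretize",
    "enumerate_knowledge_rules",
    "default_class_map",
    "rule_effectiveness",
    "rules_to_json",
    "rules_from_json",
]


class InconsistentTableError(ValueError):
    """The concept is not definable: identical attribute rows carry different decisions."""


@dataclass(frozen=True)
class AttributeValuePair:
    attribute: str
    value: str


@dataclass
class DecisionTable:
    """An information system over discrete labels; f must be total.

    ``value_domains`` fixes the declaration order of each attribute's values,
    which (together with attribute order) defines the canonical pair order
    used by LEM2's final tie-break.
    """

    objects: list
    attributes: list[str]
    decision: str
    values: dict  # (object_id, attribute_or_decision) -> label
    value_domains: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if self.decision in self.attributes:
            raise ConfigurationError("the decision attribute cannot also be a condition attribute")
        for x in self.objects:
            for a in list(self.attributes) + [self.decision]:
                if (x, a) not in self.values:
                    raise ConfigurationError(f"missing value f({x!r}, {a!r}); f must be total")
                v = self.values[(x, a)]
                if a in self.value_domains and v not in self.value_domains[a]:
                    raise ConfigurationError(f"value {v!r} not in the domain of {a!r}")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        decision: str,
        value_domains: Optional[Mapping[str, Sequence[str]]] = None,
    ) -> "DecisionTable":
        attributes = [c for c in df.columns if c != decision]
        if decision not in df.columns:
            raise ConfigurationError(f"decision column {decision!r} not present")
        domains: dict[str, tuple[str, ...]] = {}
        for c in df.columns:
            if value_domains is not None and c in value_domains:
                domains[c] = tuple(value_domains[c])
            else:  # first-appearance order keeps the table deterministic
                domains[c] = tuple(dict.fromkeys(df[c].astype(str)))
        values = {
            (idx, c): str(df.at[idx, c]) for idx in df.index for c in df.columns
        }
        return cls(
            objects=list(df.index),
            attributes=attributes,
            decision=decision,
            values=values,
            value_domains=domains,
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = self.attributes + [self.decision]
        return pd.DataFrame(
            {c: [self.values[(x, c)] for x in self.objects] for c in cols},
            index=self.objects,
        )

    def concept(self, label: str) -> frozenset:
        return frozenset(x for x in self.objects if self.values[(x, self.decision)] == label)

    def canonical_pairs(self) -> list[AttributeValuePair]:
        """All pairs, attributes in table order, values in domain order."""
        return [
            AttributeValuePair(a, v)
            for a in self.attributes
            for v in self.value_domains[a]
        ]


def lower_approximation(table: DecisionTable, concept_label: str) -> frozenset:
    """Objects certainly in the concept: indiscernibility classes wholly inside it.

    Rows are grouped by their full attribute signature; a class belongs to the
    lower approximation iff every object in it carries the concept's decision.
    The lower approximation is always definable, which makes LEM2 applicable
    to inconsistent tables (it then induces the certain rules).
    """
    X = table.concept(concept_label)
    signature: dict[tuple, list] = {}
    for x in table.objects:
        sig = tuple(table.values[(x, a)] for a in table.attributes)
        signature.setdefault(sig, []).append(x)
    out = set()
    for members in signature.values():
        if all(m in X for m in members):
            out.update(members)
    return frozenset(out)


def block(table: DecisionTable, pair: AttributeValuePair) -> frozenset:
    """[p]: the objects on which attribute(pair) takes value(pair)."""
    if pair.attribute not in table.attributes:
        raise KeyError(f"unknown attribute {pair.attribute!r}")
    if pair.value not in table.value_domains[pair.attribute]:
        raise KeyError(f"value {pair.value!r} not in domain of {pair.attribute!r}")
    return frozenset(x for x in table.objects if table.values[(x, pair.attribute)] == pair.value)


def _complex_block(table: DecisionTable, pairs: Iterable[AttributeValuePair]) -> frozenset:
    """[P]: intersection of the pair blocks; the empty conjunction covers U."""
    out = frozenset(table.objects)
    for p in pairs:
        out = out & block(table, p)
    return out


@dataclass
class LocalCovering:
    concept: str
    complexes: list[list[AttributeValuePair]] = field(default_factory=list)


def lem2(
    table: DecisionTable, concept_label: str, goal: Optional[frozenset] = None
) -> LocalCovering:
    """Induce a single local covering of the concept by the LEM2 strategy.

    Pair selection inside a growing complex: maximise |[p] ∩ G|; break ties
    by the smallest |[p]|; break remaining ties by the canonical pair order.
    Each complex is pruned pair-by-pair, and redundant complexes are dropped
    at the end.  Raises :class:`InconsistentTableError` when the goal set is
    not definable (objects inside and outside it share identical rows) —
    the literal goal-directed loop would otherwise never terminate; pass the
    concept's :func:`lower_approximation` as ``goal`` to induce certain rules
    from an inconsistent table instead.
    """
    X = table.concept(concept_label) if goal is None else frozenset(goal)
    pairs = table.canonical_pairs()
    blocks = {p: block(table, p) for p in pairs}

    covering = LocalCovering(concept=concept_label)
    G = set(X)
    while G:
        P: list[AttributeValuePair] = []
        local_G = set(G)
        while not P or not _complex_block(table, P) <= X:
            best = None
            best_key = None
            for p in pairs:
                if p in P:
                    continue
                inter = len(blocks[p] & local_G)
                if inter == 0:
                    continue
                key = (-inter, len(blocks[p]))  # max coverage, then smallest block, then first
                if best_key is None or key < best_key:
                    best, best_key = p, key
            if best is None:
                clashes = sorted(
                    (str(x) for x in local_G), key=str
                )
                raise InconsistentTableError(
                    f"concept {concept_label!r} is not definable: objects {clashes} share "
                    "their attribute values with objects outside the concept"
                )
            P.append(best)
            local_G &= blocks[best]
        # minimality: drop any pair whose removal keeps the block inside X
        for p in list(P):
            trial = [q for q in P if q != p]
            if trial and _complex_block(table, trial) <= X:
                P = trial
        covering.complexes.append(P)
        covered = set()
        for C in covering.complexes:
            covered |= _complex_block(table, C)
        G = set(X) - covered

    # drop complexes that are redundant for the covering
    for C in list(covering.complexes):
        rest = [D for D in covering.complexes if D is not C]
        union = set()
        for D in rest:
            union |= _complex_block(table, D)
        if union == set(X):
            covering.complexes = rest
    return covering


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Rule:
    """A conjunction of feature→label conditions implying a pose class."""

    antecedent: tuple[tuple[str, str], ...]  # ordered (feature, label) pairs
    consequent: str
    provenance: str = "knowledge"  # "knowledge" | "lem2"

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise ConfigurationError("a rule needs a non-empty antecedent")
        feats = [f for f, _ in self.antecedent]
        if len(set(feats)) != len(feats):
            raise ConfigurationError("at most one label per feature in an antecedent")

    @property
    def conditions(self) -> dict[str, str]:
        return dict(self.antecedent)


RuleSet = list[Rule]


def resolve_by_majority(table: DecisionTable) -> DecisionTable:
    """Make a table consistent by per-signature majority vote on the decision.

    Objects sharing a full attribute signature all receive the signature's
    most frequent decision label (ties break toward the earlier label in the
    decision domain order).  A consistent table passes through unchanged.
    """
    signature: dict[tuple, list] = {}
    for x in table.objects:
        sig = tuple(table.values[(x, a)] for a in table.attributes)
        signature.setdefault(sig, []).append(x)
    order = {lab: i for i, lab in enumerate(table.value_domains[table.decision])}
    values = dict(table.values)
    for members in signature.values():
        labels = [table.values[(x, table.decision)] for x in members]
        if len(set(labels)) > 1:
            winner = max(set(labels), key=lambda l: (labels.count(l), -order[l]))
            for x in members:
                values[(x, table.decision)] = winner
    return DecisionTable(
        objects=list(table.objects),
        attributes=list(table.attributes),
        decision=table.decision,
        values=values,
        value_domains=dict(table.value_domains),
    )


def induce_ruleset(
    table: DecisionTable,
    provenance: str = "lem2",
    inconsistency: str = "majority",
) -> RuleSet:
    """One LEM2 covering per decision label, flattened to rules.

    ``inconsistency`` controls what happens when identical attribute rows
    carry different decisions (LEM2 presupposes a consistent table):
    ``"majority"`` (default) relabels each clashing signature by majority
    vote first — appropriate when the clashes are label noise; ``"lower"``
    induces only the certain rules from each concept's lower approximation;
    ``"error"`` propagates :class:`InconsistentTableError`.  On a consistent
    table all three behave identically.
    """
    if inconsistency not in ("majority", "lower", "error"):
        raise ConfigurationError(f"unknown inconsistency policy {inconsistency!r}")
    if inconsistency == "majority":
        table = resolve_by_majority(table)
    rules: RuleSet = []
    for label in table.value_domains[table.decision]:
        goal = lower_approximation(table, label) if inconsistency == "lower" else None
        cov = lem2(table, label, goal=goal)
        for P in cov.complexes:
            rules.append(
                Rule(
                    antecedent=tuple((p.attribute, p.value) for p in P),
                    consequent=label,
                    provenance=provenance,
                )
            )
    return rules


def discretize(
    df: pd.DataFrame,
    variables: Mapping[str, LinguisticVariable],
    label_column: str = "label",
) -> DecisionTable:
    """Label each feature column by its argmax-membership linguistic label.

    Argmax ties break toward the lower-ordered label (Lo < Me < Hi).
    """
    if df.empty:
        raise ConfigurationError("cannot discretize an empty feature table")
    missing = [f for f in FEATURES if f not in variables]
    if missing:
        raise ConfigurationError(f"variables missing for features: {missing}")
    out = {}
    for feat in FEATURES:
        var = variables[feat]
        order = var.label_order
        labels = []
        for x in df[feat]:
            degrees = fuzzify(var, float(x))
            best = max(order, key=lambda lab: (degrees[lab], -order.index(lab)))
            labels.append(best)
        out[feat] = labels
    out[label_column] = [str(v) for v in df[label_column]]
    disc = pd.DataFrame(out, index=df.index)
    domains = {f: variables[f].label_order for f in FEATURES}
    domains[label_column] = tuple(dict.fromkeys(disc[label_column]))
    return DecisionTable.from_dataframe(disc, decision=label_column, value_domains=domains)


# --- knowledge-approach enumeration ----------------------------------------

# Prototype antecedents of clearly classifiable poses, in feature order
# (hw, hmax, sigma, p40): upright silhouettes are tall/narrow with low
# floor-point fraction; lying ones are wide/low with most points near the floor.
_NOTLY_PROTOTYPES = (
    ("Hi", "Hi", "Lo", "Lo"),
    ("Me", "Hi", "Lo", "Lo"),
    ("Me", "Me", "Lo", "Lo"),
)
_ISLY_PROTOTYPES = (
    ("Lo", "Lo", "Lo", "Hi"),
    ("Lo", "Lo", "Me", "Hi"),
)

_ORD = {lab: i for i, lab in enumerate(INPUT_LABELS)}


def _proto_distance(ante: tuple[str, ...], proto: tuple[str, ...]) -> int:
    return sum(abs(_ORD[a] - _ORD[p]) for a, p in zip(ante, proto))


def default_class_map() -> dict[tuple[str, ...], str]:
    """Heuristic pose class for every Lo/Me/Hi antecedent combination.

    Each antecedent is scored by ordinal distance to the prototype profiles of
    the two clearly classifiable poses; an antecedent within distance 1 of one
    class's prototypes (and strictly closer to it than to the other class) gets
    that class, everything else is mayLy.  The map is a documented heuristic
    and is user-replaceable via JSON.
    """
    out: dict[tuple[str, ...], str] = {}
    for ante in itertools.product(INPUT_LABELS, repeat=len(FEATURES)):
        d_not = min(_proto_distance(ante, p) for p in _NOTLY_PROTOTYPES)
        d_is = min(_proto_distance(ante, p) for p in _ISLY_PROTOTYPES)
        if d_not <= 1 and d_not < d_is:
            out[ante] = "notLy"
        elif d_is <= 1 and d_is < d_not:
            out[ante] = "isLy"
        else:
            out[ante] = "mayLy"
    return out


def enumerate_knowledge_rules(
    class_map: Optional[Mapping[tuple[str, ...], str]] = None,
) -> RuleSet:
    """All 3^4 = 81 feature-label conjunctions, each with its pose class."""
    if class_map is None:
        class_map = default_class_map()
    rules: RuleSet = []
    missing = []
    for ante in itertools.product(INPUT_LABELS, repeat=len(FEATURES)):
        if ante not in class_map:
            missing.append(ante)
            continue
        rules.append(
            Rule(
                antecedent=tuple(zip(FEATURES, ante)),
                consequent=class_map[ante],
                provenance="knowledge",
            )
        )
    if missing:
        raise ConfigurationError(
            f"class map is missing {len(missing)} antecedents, e.g. {missing[:5]}"
        )
    return rules


def rule_effectiveness(
    n_correct: int, set_size: int, n_correct_in_class: int, class_size: int
) -> tuple[float, float]:
    """(effectiveness in the whole set, effectiveness within the decision class).

    The first ratio is correct classifications of the rule over all objects;
    the second restricts both counts to the rule's decision class.  Rankings
    sort by the first ratio, then the second.
    """
    if set_size <= 0:
        raise ConfigurationError("set_size must be positive")
    if not 0 <= class_size <= set_size:
        raise ConfigurationError("class_size must lie in [0, set_size]")
    if not 0 <= n_correct <= set_size or not 0 <= n_correct_in_class <= max(class_size, 0):
        if class_size == 0 and n_correct_in_class > 0:
            raise InconsistentTableError("correct classifications in an empty decision class")
        raise ConfigurationError("correct counts cannot exceed the respective set sizes")
    e_set = n_correct / set_size
    e_class = (n_correct_in_class / class_size) if class_size > 0 else 0.0
    return (e_set, e_class)


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


def rules_to_json(rules: RuleSet) -> str:
    return json.dumps(
        [
            {"if": dict(r.antecedent), "then": r.consequent, "provenance": r.provenance}
            for r in rules
        ],
        indent=2,
    )


def rules_from_json(text: str) -> RuleSet:
    raw = json.loads(text)
    rules: RuleSet = []
    for item in raw:
        ante = tuple((str(k), str(v)) for k, v in item["if"].items())
        rules.append(
            Rule(antecedent=ante, consequent=str(item["then"]),
                 provenance=str(item.get("provenance", "knowledge")))
        )
    return rules
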