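# Methods

## Scope and model

`frsystem` implements single-frame lying-pose classification from four crisp
silhouette descriptors (`hw`, `hmax`, `sigma` [mm], `p40`). It deliberately
stops at the first stage of a two-stage fall detector: movement analysis over
time, alarm triggering, and depth-map feature extraction are out of scope —
the package consumes feature vectors, not images.

Inference is Mamdani with a configurable premise-combination step:

1. fuzzify each feature against its three labels (Lo/Me/Hi);
2. activate each rule, either classically (`A(premises)`) or with the
   knowledge-augmented operator `OR = B(A(premises), K(premises))`;
3. aggregate activations per pose class by maximum;
4. clip each pose consequent curve at its class activation (minimum by
   default; any shipped t-norm can be configured);
5. merge the three clipped sets pointwise by maximum and defuzzify by centre
   of gravity;
6. decide isLy when COG < threshold (default 0.5), else notLy.

The knowledge measure `K` is evaluated **on the rule's premise degrees** for
the current frame. The alternative reading — `K` over the rule's antecedent
membership functions on their universes — would be input-independent and
collapse `OR` to a per-rule constant rescaling, so it was rejected.

mayLy rules do not terminate a decision but participate fully in inference:
their clipped consequent contributes middle mass that pulls the centroid
toward 0.5, which is the intended effect of an uncertain rule.

## Membership parameters

The shipped configuration (`load_default_config`) is the expert-chosen
parameter set: Z-splines for Lo labels, S-splines for Hi, and two-sided
Gaussians (flat at 1 between the two centres) for Me. Interpretation choices:

- **Z/S triples (a, m, b).** The spline is anchored on the knots (a, b); the
  middle value m is the intended 0.5-crossover and is redundant with
  (a + b)/2 for 13 of the 15 curves. The two deviating curves
  (`hmax` Lo with m = 0.4 vs midpoint 0.425, and pose notLy with m = 0.63 vs
  0.635) construct with a warning rather than an error — rejecting the
  published parameter set would be self-defeating.
- **gauss2 quadruples.** Read as (c1, σ1, c2, σ2) — left centre/width, right
  centre/width — which is unambiguous from the magnitudes (e.g. widths 17/33
  around centre 310 mm for `sigma` Me). The `hw` Me entry contains an obvious
  decimal-comma typo and is read as (2, 0.5, 2, 0.4).
- **Universes.** Inputs: hw [0, 4], hmax [0, 1.2], sigma [200, 470] mm,
  p40 [0, 1]; each encloses every support with margin. The pose universe is
  never stated by the source parameters and is taken as [0, 1] (the pose
  knots span 0.22–0.77); it is configurable.
- **Out-of-range inputs are clamped** to the universe before evaluation.
- **Coverage.** The label families leave shallow dips between the shoulder
  curves and the narrow Gaussian middles: the pointwise maximum over a
  variable's labels falls to ≈ 0.35 in places (e.g. hw ≈ 1.37). This is a
  property of the published parameters, not of the implementation; the
  property test asserts a 0.3 floor on a 1000-point grid.

## Operators and their axioms

All connectives are validated at spec construction (inputs are checked, not
clamped; unit-interval comparisons use absolute tolerance 1e-12). Associative
t-norms/t-conorms extend to n arguments by left fold; the pre-aggregations
`pre_f` and `lehmer` are only directionally monotone, are kept strictly
binary, and raise for higher arity — they appear only as the outer combiner
`B` of the OR operator. OWA sorts descending with a stable sort (the result
is permutation-invariant regardless).

The constructive precedence indicator requires `A ≤ max` (checked on a
101×101 grid at construction). One mathematical caveat discovered while
testing: with `A = min` or the geometric mean, `A(N(p), 0) = 0` for *every*
p > 0, so axiom P1 (zero only at (1, 0)) fails, and the derived knowledge
measure loses the "minimum iff all degrees are 0.5" characterisation. The
full axiom suite therefore holds — and is asserted — for aggregators that
vanish only at (0, 0): arithmetic mean, quadratic mean, and max. The
min/gmean constructions are still available and are characterised by tests
showing exactly which axiom breaks; none of the shipped K1–K5 presets relies
on the broken property. Prec-based knowledge measures additionally require a
symmetric aggregator and a strong negation with equilibrium 0.5, both checked
empirically on a grid at construction because specs are user-composable.

## LEM2 and rule induction

The decision table is built by argmax-membership discretization of the
feature columns (ties break toward the lower-ordered label, Lo < Me < Hi; the
source never states its discretization, so this is the package's choice).
LEM2 follows the classic goal-directed strategy with the three-level
tie-break (max |[p] ∩ G|, then smallest |[p]|, then first pair in canonical
order: attributes in table order, values in domain order), per-complex pair
pruning, and final redundant-complex removal. The canonical order makes the
output deterministic across runs and platforms.

The literal algorithm never terminates when a concept is not definable, so
non-definability (no candidate pair remains) raises a diagnostic error naming
the clashing objects. `induce_ruleset` adds an inconsistency policy on top:

- `"majority"` (default): relabel each clashing attribute signature by
  majority vote before induction — the right model when inconsistency is
  label noise, as in the synthetic data;
- `"lower"`: induce certain rules from each concept's lower approximation;
- `"error"`: propagate the diagnostic.

On a consistent table all three behave identically.

The enumerated knowledge base contains all 3⁴ = 81 antecedents. The original
expert assignment of pose classes to the 81 antecedents is not publicly
reproducible, so the default class map is a documented heuristic: an
antecedent within ordinal distance 1 of one pose's prototype profiles
(notLy: (Hi,Hi,Lo,Lo), (Me,Hi,Lo,Lo), (Me,Me,Lo,Lo); isLy: (Lo,Lo,Lo,Hi),
(Lo,Lo,Me,Hi)) and strictly closer to it than to the other pose gets that
class; everything else is mayLy (yielding 13 notLy / 59 mayLy / 9 isLy). The
map is user-replaceable via JSON; no claim is made that it matches the
original expert table.

Rule effectiveness is reported as two ratios — correct classifications of
the rule over all objects, and over the rule's decision class — where a
rule is credited with the objects for which it attains the maximal
activation (first rule on ties). Rankings sort by the first ratio, then the
second.

## Synthetic data

`synth_generate` emulates the two-class structure of the real recordings:
per class and feature it picks a target label from the class profile
(lying: hw Lo, hmax Lo, sigma Lo∨Me, p40 Hi; not lying: hw Hi∨Me,
hmax Hi∨Me, sigma Lo, p40 Lo; disjunctions uniform per sample), draws
uniformly inside that curve's full-membership core, adds Gaussian jitter of
`noise_scale` × the curve's transition width, and clamps to the universe.
A `mislabel_rate` fraction of each class swaps labels to create overlap.
Defaults: `noise_scale = 0.15`, `mislabel_rate = 0.02`, 500 samples per
class — realistic frame-level separability for clearly lying vs clearly
upright postures, where label noise dominates feature noise.

What the generator does **not** emulate: temporal correlation between
consecutive frames, transitional poses (sitting down, kneeling) that occupy
the mayLy region in real recordings, sensor-specific depth noise, and
occlusions. Passing the synthetic study therefore demonstrates that the
pipeline is correct and that rule reduction preserves accuracy under the
stated class structure; it does not certify real-world detection rates.

## Numerical choices

- Pose output grid: 1001 points (COG shifts < 1e-3 when doubled).
- COG is the membership-weighted mean of the grid; an all-zero output set
  (no rule fired) maps to notLy with a warning — absence of evidence for
  lying must not raise an alarm.
- Half-up rounding to 3 decimals for table-style metric reporting; each
  metric with a zero denominator is reported as undefined, not an error.
- The batch classifier is a vectorised transcription of the scalar path and
  is tested to agree with it to 1e-12.
- OWA premise weights (never specified by the source studies) default to
  linearly decreasing, regenerated per rule arity in the experiment driver.
- Classic-mode presets cover Tm, Tp, Amean and OWA; the pre-aggregation F is
  excluded there because it is strictly binary while classic premise
  aggregation sees up to four conditions.

## Known limitations

- The synthetic study is desk-scale (1000 frames) and largely saturated: on
  well-separated data every aggregation choice reaches the same binary
  decisions, so configuration differences visible on real data do not
  discriminate here.
- LEM2 rule counts on the synthetic table are small (typically one or two
  complexes per class) because majority-cleaned synthetic signatures are
  separable by single attribute-value pairs; real recordings with richer
  overlap produce larger coverings.
- Interval-valued operators, other LERS-family algorithms (LEM1, MLEM2) and
  membership-function learning are out of scope.
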