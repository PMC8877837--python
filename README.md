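# frsystem

A hybrid fuzzy–rough inference system for **lying-posture classification** in
depth-camera fall detection, aimed at researchers in assistive sensing who want
an explainable, rule-based alternative to black-box classifiers.

Fall detectors built on depth maps (e.g. a ceiling- or wall-mounted Kinect)
typically decide in a first stage whether the silhouette in a single frame is
lying. Each frame is summarised by four silhouette descriptors:

| feature | meaning | unit |
|---|---|---|
| `hw` | H/W — bounding-box height/width ratio | – |
| `hmax` | H/Hmax — box height over the person's physical height | – |
| `sigma` | max(σx, σz) — maximal point-cloud spread from the centre of gravity | mm |
| `p40` | fraction of cloud points within 40 cm of the floor | – |

## The model

Each feature carries three linguistic labels (Lo/Me/Hi) defined by Z-spline,
two-sided-Gaussian and S-spline membership curves with an expert-chosen
parameter set shipped in `load_default_config()`. A rule base maps label
conjunctions to a pose class (isLy / mayLy / notLy); inference is Mamdani:
aggregate premises, clip the consequent curve, merge classes by maximum,
defuzzify by centre of gravity (COG) on the pose universe [0, 1], and call the
frame lying when COG < 0.5.

Two ingredients distinguish the system:

**Knowledge-augmented premise aggregation.** A *precedence indicator*
`Prec(p,q) = 1 if p ≤ q else A(N(p), q)` (aggregation `A ≤ max`, fuzzy negation
`N`) grades how much degree `p` is included in `q`. From it a *knowledge
measure* — the dual of fuzzy entropy — is built per rule over the premise
degrees `x_i`:

    K = mean_i |Prec(1, x_i) − Prec(x_i, 0)| / (1 − min(Prec(1, x_i), Prec(x_i, 0)))

which for the max/standard-negation indicator reduces to
`|2x−1| / (1 − min(x, 1−x))`. Rule activation then becomes
`OR = B(A(premises), K(premises))`: premises near 0.5 (maximal uncertainty)
are actively discounted instead of propagated at half strength. Five studied
configurations are shipped as `knowledge_presets()` (K1–K5; K2 =
quadratic-mean premises, pre-aggregation F combiner, max-based measure).

**Rough-set rule reduction.** The full knowledge rule base enumerates all
3⁴ = 81 label conjunctions. The LEM2 algorithm instead induces, per decision
concept, a minimal *local covering* of irreducible attribute-value
conjunctions from a discretized decision table, typically shrinking the rule
base by an order of magnitude while preserving accuracy.

## Worked example

```python
import frsystem as fr

variables = fr.load_default_config()          # shipped membership parameters
rules = fr.enumerate_knowledge_rules()        # the 81-rule knowledge base
config = fr.knowledge_presets()["K2"]         # knowledge-augmented inference

lying = fr.FeatureVector(hw=0.7, hmax=0.3, sigma=380.0, p40=0.6)
upright = fr.FeatureVector(hw=3.0, hmax=0.95, sigma=270.0, p40=0.2)
for fv in (lying, upright):
    r = fr.classify(fv, rules, config, variables)
    print(r.pose_label, round(r.cog_score, 4))
```

prints

```
isLy 0.4326
notLy 0.5771
```

The first frame (wide, low silhouette with most points near the floor)
defuzzifies to 0.4326 < 0.5 on the pose universe → lying; the second (tall,
narrow, elevated) lands at 0.5771 → not lying.

The same pipeline is scriptable from the shell:

```bash
frsys simulate --n 500 --seed 42 --out synth.csv
frsys infer --input synth.csv --out pred.csv --mode knowledge --preset K2
frsys evaluate --input pred.csv
frsys experiment --n 500 --seed 42 --out report.csv
```

`frsys experiment` scores every premise-aggregation configuration (classic
Tm/Tp/Amean/OWA and knowledge K1–K5) against both the enumerated 81-rule set
and the LEM2-reduced set, reporting confusion counts, ACC/PRE/REC/SPE and a
per-rule effectiveness ranking.

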