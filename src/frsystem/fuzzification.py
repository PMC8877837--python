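"""Membership functions and linguistic variables for the posture features.

Four silhouette descriptors are fuzzified per depth frame:

* ``hw``    — H/W, bounding-box height/width ratio (dimensionless);
* ``hmax``  — H/Hmax, current box height over the person's physical height;
* ``sigma`` — max(sigma_x, sigma_z), maximal point-cloud spread from the
  centre of gravity along the camera axes (millimetres);
* ``p40``   — fraction of cloud points lying within 40 cm of the floor.

Each input variable carries three labels (Lo / Me / Hi) and the output
variable ``pose`` carries isLy / mayLy / notLy.  Low labels are quadratic
Z-splines, high labels S-splines, and middle labels two-sided Gaussians
(flat at 1 between the two centres).  The shipped parameter set is
expert-chosen, not fitted.
"""

from __future__ import annotations

import warnings
from typing import Literal, Mapping, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from .fuzzy_core import ConfigurationError, ParameterError

__all__ = [
    "MembershipFunction",
    "LinguisticVariable",
    "FeatureVector",
    "FEATURES",
    "POSE_LABELS",
    "eval_mf",
    "fuzzify",
    "load_default_config",
    "config_to_yaml",
    "config_from_yaml",
    "mf_core",
    "mf_width",
]

FEATURES = ("hw", "hmax", "sigma", "p40")
INPUT_LABELS = ("Lo", "Me", "Hi")
POSE_LABELS = ("isLy", "mayLy", "notLy")


class MembershipFunction(BaseModel):
    """A Z-spline, S-spline, or two-sided Gaussian membership curve.

    Z/S curves are parameterised by (a, m, b): the shoulder knots a and b
    carry the curve between full and zero membership, and m records the
    intended 0.5-crossover.  The curve itself is anchored on (a, b) with the
    crossover at their midpoint; a stored m that deviates from (a+b)/2 by
    more than 5% of the support width triggers a warning, not an error
    (two of the shipped curves deviate slightly).
    """

    model_config = ConfigDict(frozen=True)

    kind: Literal["z", "s", "gauss2"]
    a: Optional[float] = None
    m: Optional[float] = None
    b: Optional[float] = None
    c1: Optional[float] = None
    sigma1: Optional[float] = None
    c2: Optional[float] = None
    sigma2: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "MembershipFunction":
        if self.kind in ("z", "s"):
            if self.a is None or self.b is None:
                raise ParameterError(f"{self.kind} curve requires knots a and b")
            if not self.a <= self.b:
                raise ParameterError(f"{self.kind} curve requires a <= b, got ({self.a}, {self.b})")
            if self.m is not None:
                if not self.a <= self.m <= self.b:
                    raise ParameterError("crossover m must lie between the knots a and b")
                mid = (self.a + self.b) / 2.0
                if self.b > self.a and abs(self.m - mid) > 0.05 * (self.b - self.a):
                    warnings.warn(
                        f"{self.kind} curve: stored crossover m={self.m} deviates from the "
                        f"spline midpoint {(mid):g}; the curve is anchored on (a, b)",
                        stacklevel=2,
                    )
        else:
            if None in (self.c1, self.sigma1, self.c2, self.sigma2):
                raise ParameterError("gauss2 requires c1, sigma1, c2, sigma2")
            if self.sigma1 <= 0 or self.sigma2 <= 0:
                raise ParameterError("gauss2 widths must be positive")
            if self.c1 > self.c2:
                raise ParameterError("gauss2 requires c1 <= c2")
        return self


def eval_mf(mf: MembershipFunction, x):
    """Evaluate a membership curve at x (float or array), result in [0, 1]."""
    x = np.asarray(x, dtype=float)
    if mf.kind in ("z", "s"):
        a, b = mf.a, mf.b
        if b == a:  # degenerate knots: a crisp step
            up = (x >= a).astype(float)
            out = up if mf.kind == "s" else 1.0 - up
        else:
            mid = (a + b) / 2.0
            t = (x - a) / (b - a)
            s_curve = np.where(
                x <= a,
                0.0,
                np.where(
                    x <= mid,
                    2.0 * t**2,
                    np.where(x <= b, 1.0 - 2.0 * ((x - b) / (b - a)) ** 2, 1.0),
                ),
            )
            out = s_curve if mf.kind == "s" else 1.0 - s_curve
    else:
        left = np.exp(-((x - mf.c1) ** 2) / (2.0 * mf.sigma1**2))
        right = np.exp(-((x - mf.c2) ** 2) / (2.0 * mf.sigma2**2))
        out = np.where(x < mf.c1, left, np.where(x > mf.c2, right, 1.0))
    out = np.asarray(np.clip(out, 0.0, 1.0))
    return out if out.ndim else float(out)


def mf_core(mf: MembershipFunction, universe: tuple[float, float]) -> tuple[float, float]:
    """The full-membership interval of a curve, clipped to the universe."""
    lo, hi = universe
    if mf.kind == "z":
        return (lo, min(mf.a, hi))
    if mf.kind == "s":
        return (max(mf.b, lo), hi)
    return (max(mf.c1, lo), min(mf.c2, hi))


def mf_width(mf: MembershipFunction) -> float:
    """A transition-width scale for the curve (used to scale synthetic noise)."""
    if mf.kind in ("z", "s"):
        return float(mf.b - mf.a)
    return float((mf.c2 - mf.c1) + mf.sigma1 + mf.sigma2)


class LinguisticVariable(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str
    universe: tuple[float, float]
    labels: Mapping[str, MembershipFunction]  # insertion order is the label order

    @model_validator(mode="after")
    def _check(self) -> "LinguisticVariable":
        lo, hi = self.universe
        if not lo < hi:
            raise ParameterError(f"universe bounds must satisfy lo < hi, got {self.universe}")
        if len(self.labels) != 3:
            raise ParameterError(
                f"variable {self.name!r} must carry exactly 3 labels, got {len(self.labels)}"
            )
        return self

    @property
    def label_order(self) -> tuple[str, ...]:
        return tuple(self.labels)


def fuzzify(var: LinguisticVariable, x: float) -> dict[str, float]:
    """Membership degree of x in each label of the variable.

    x is clamped to the universe first (depth-feature outliers would otherwise
    still produce valid tail values, but clamping keeps behaviour explicit).
    Degrees need not sum to 1.
    """
    lo, hi = var.universe
    xc = float(np.clip(x, lo, hi))
    return {label: float(eval_mf(mf, xc)) for label, mf in var.labels.items()}


class FeatureVector(BaseModel):
    """One frame's crisp silhouette descriptors."""

    model_config = ConfigDict(frozen=True)

    hw: float
    hmax: float
    sigma: float
    p40: float

    @model_validator(mode="after")
    def _check(self) -> "FeatureVector":
        if self.hw < 0 or self.hmax < 0 or self.sigma < 0:
            raise ParameterError("hw, hmax and sigma are non-negative quantities")
        if not 0.0 <= self.p40 <= 1.0:
            raise ParameterError("p40 is a fraction and must lie in [0, 1]")
        return self


def _z(a: float, m: float, b: float) -> MembershipFunction:
    return MembershipFunction(kind="z", a=a, m=m, b=b)


def _s(a: float, m: float, b: float) -> MembershipFunction:
    return MembershipFunction(kind="s", a=a, m=m, b=b)


def _g2(c1: float, s1: float, c2: float, s2: float) -> MembershipFunction:
    return MembershipFunction(kind="gauss2", c1=c1, sigma1=s1, c2=c2, sigma2=s2)


def load_default_config() -> dict[str, LinguisticVariable]:
    """The shipped expert parameter set: four input variables plus the pose output.

    Universe bounds for the inputs are chosen to enclose every label's support
    with a modest margin; the pose universe is [0, 1] (its curve knots span
    0.22–0.77).
    """
    with warnings.catch_warnings():
        # two shipped crossovers legitimately deviate from the spline midpoint
        warnings.simplefilter("ignore")
        return {
            "hw": LinguisticVariable(
                name="hw",
                universe=(0.0, 4.0),
                labels={
                    "Lo": _z(0.5, 1.25, 2.0),
                    "Me": _g2(2.0, 0.5, 2.0, 0.4),
                    "Hi": _s(2.0, 2.6, 3.2),
                },
            ),
            "hmax": LinguisticVariable(
                name="hmax",
                universe=(0.0, 1.2),
                labels={
                    "Lo": _z(0.25, 0.4, 0.6),
                    "Me": _g2(0.6, 0.1, 0.6, 0.2),
                    "Hi": _s(0.6, 0.8, 1.0),
                },
            ),
            "sigma": LinguisticVariable(
                name="sigma",
                universe=(200.0, 470.0),
                labels={
                    "Lo": _z(260.0, 285.0, 310.0),
                    "Me": _g2(310.0, 17.0, 310.0, 33.0),
                    "Hi": _s(310.0, 360.0, 410.0),
                },
            ),
            "p40": LinguisticVariable(
                name="p40",
                universe=(0.0, 1.0),
                labels={
                    "Lo": _z(0.18, 0.3, 0.42),
                    "Me": _g2(0.42, 0.08, 0.42, 0.09),
                    "Hi": _s(0.42, 0.55, 0.68),
                },
            ),
            "pose": LinguisticVariable(
                name="pose",
                universe=(0.0, 1.0),
                labels={
                    "isLy": _z(0.22, 0.36, 0.5),
                    "mayLy": _g2(0.5, 0.09, 0.5, 0.09),
                    "notLy": _s(0.5, 0.63, 0.77),
                },
            ),
        }


# ---------------------------------------------------------------------------
# YAML round-trip
# ---------------------------------------------------------------------------


def _mf_to_dict(mf: MembershipFunction) -> dict:
    if mf.kind in ("z", "s"):
        return {"kind": mf.kind, "a": mf.a, "m": mf.m, "b": mf.b}
    return {"kind": "gauss2", "c1": mf.c1, "sigma1": mf.sigma1, "c2": mf.c2, "sigma2": mf.sigma2}


def config_to_yaml(config: Mapping[str, LinguisticVariable]) -> str:
    doc = {
        "variables": {
            name: {
                "universe": list(var.universe),
                "labels": {label: _mf_to_dict(mf) for label, mf in var.labels.items()},
            }
            for name, var in config.items()
        }
    }
    return yaml.safe_dump(doc, sort_keys=False)


def config_from_yaml(text: str) -> dict[str, LinguisticVariable]:
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "variables" not in doc:
        raise ConfigurationError("config YAML must contain a top-level 'variables' mapping")
    out: dict[str, LinguisticVariable] = {}
    for name, body in doc["variables"].items():
        labels = {label: MembershipFunction(**mf) for label, mf in body["labels"].items()}
        out[name] = LinguisticVariable(
            name=name, universe=tuple(body["universe"]), labels=labels
        )
    return out
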