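"""Individualized predicted step length and AGRF values.

A neurotypical reference value for each outcome is computed from a linear
equation in gait speed, leg length, mass, sex, and age. The coefficients are
not hard-coded: they are read from a versioned spec file so that published
model coefficients can be dropped in. The package ships
``data/prediction_spec_synthetic.yaml`` with clearly labelled synthetic
demonstration coefficients of plausible magnitude.

Trials whose speed, mean AGRF, or mean step length fall outside the training
domain of the prediction models (speed <= 0.36 m/s, AGRF <= 18.2 N, step
length <= 0.32 m) are excluded before predictions are compared to measured
values.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .events import TrialMetrics

# training-domain bounds of the prediction models
MIN_SPEED_MS = 0.36
MIN_AGRF_N = 18.2
MIN_STEP_LENGTH_M = 0.32

# sex is encoded 0/1; the mapping ships in the spec file header
DEFAULT_SEX_ENCODING = {"M": 0.0, "F": 1.0}

COVARIATES = ("speed", "leg_length", "mass", "sex", "age")

__all__ = [
    "ParticipantRecord",
    "PredictionSpec",
    "FilterDecision",
    "leg_length",
    "predict_value",
    "applicability_filter",
    "load_prediction_specs",
    "default_spec_path",
]


@dataclass
class ParticipantRecord:
    id: str
    sex: str  # 'M' | 'F'
    age: float  # years
    mass: float  # kg
    leg_length: float  # m
    paretic_side: str  # 'left' | 'right'
    dataset: int = 1

    def __post_init__(self) -> None:
        if self.age <= 0 or self.mass <= 0 or self.leg_length <= 0:
            raise ValueError("age, mass and leg_length must be > 0")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")


@dataclass
class PredictionSpec:
    """Linear prediction equation for one outcome plus applicability bounds."""

    outcome: str  # 'step_length' | 'agrf'
    intercept: float
    coefficients: dict[str, float]
    sex_encoding: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SEX_ENCODING))
    min_speed: float = MIN_SPEED_MS
    min_agrf: float = MIN_AGRF_N
    min_step_length: float = MIN_STEP_LENGTH_M
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.outcome not in ("step_length", "agrf"):
            raise ValueError("outcome must be 'step_length' or 'agrf'")
        unknown = set(self.coefficients) - set(COVARIATES)
        if unknown:
            raise ValueError(f"unknown covariates in spec: {sorted(unknown)}")
        for name, v in self.coefficients.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite coefficient for {name}")
        if not math.isfinite(self.intercept):
            raise ValueError("non-finite intercept")


@dataclass
class FilterDecision:
    keep: bool
    reasons: list[str] = field(default_factory=list)


def default_spec_path() -> Path:
    return Path(resources.files("gaitprop").joinpath("data/prediction_spec_synthetic.yaml"))


def load_prediction_specs(path: str | Path | None = None) -> dict[str, PredictionSpec]:
    """Load prediction specs for both outcomes from a YAML/JSON file."""
    path = Path(path) if path is not None else default_spec_path()
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    specs: dict[str, PredictionSpec] = {}
    bounds = raw.get("bounds", {})
    for outcome, entry in raw["models"].items():
        specs[outcome] = PredictionSpec(
            outcome=outcome,
            intercept=float(entry["intercept"]),
            coefficients={k: float(v) for k, v in entry["coefficients"].items()},
            sex_encoding={k: float(v) for k, v in raw.get("sex_encoding", DEFAULT_SEX_ENCODING).items()},
            min_speed=float(bounds.get("min_speed", MIN_SPEED_MS)),
            min_agrf=float(bounds.get("min_agrf", MIN_AGRF_N)),
            min_step_length=float(bounds.get("min_step_length", MIN_STEP_LENGTH_M)),
            provenance=str(raw.get("provenance", "")),
        )
    return specs


def leg_length(
    kinematic_time: np.ndarray,
    trochanter_vert: np.ndarray,
    malleolus_vert: np.ndarray,
    stances: list[tuple[float, float]],
) -> tuple[float, bool]:
    """Leg length as the trochanter-to-malleolus vertical distance at
    mid-stance, averaged across stances; negative values are flagged as
    implausible (inverted channels)."""
    t = np.asarray(kinematic_time, float)
    vals = []
    for fs, to in stances:
        mid = 0.5 * (fs + to)
        if not t[0] <= mid <= t[-1]:
            raise ValueError("mid-stance sample unavailable")
        troch = float(np.interp(mid, t, trochanter_vert))
        mall = float(np.interp(mid, t, malleolus_vert))
        vals.append(troch - mall)
    if not vals:
        raise ValueError("no stances supplied")
    ll = float(np.mean(vals))
    return ll, ll <= 0.0


def predict_value(spec: PredictionSpec, speed: float, participant: ParticipantRecord) -> float:
    """One predicted outcome per trial: intercept + sum(coef * covariate).

    The same predicted value is compared against both the paretic and the
    non-paretic limb.
    """
    if not math.isfinite(speed):
        raise ValueError("speed must be finite")
    values = {
        "speed": speed,
        "leg_length": participant.leg_length,
        "mass": participant.mass,
        "sex": spec.sex_encoding[participant.sex],
        "age": participant.age,
    }
    out = spec.intercept
    for name, coef in spec.coefficients.items():
        out += coef * values[name]
    return float(out)


def applicability_filter(metrics: TrialMetrics, spec: PredictionSpec) -> FilterDecision:
    """Exclude trials outside the prediction models' training domain.

    A trial is excluded if its speed <= min_speed, or either limb's mean AGRF
    <= min_agrf, or either limb's mean step length <= min_step_length. Every
    violated bound is reported.
    """
    reasons: list[str] = []
    if metrics.speed <= spec.min_speed:
        reasons.append("speed")
    if min(metrics.mean_agrf_paretic, metrics.mean_agrf_nonparetic) <= spec.min_agrf:
        reasons.append("agrf")
    if min(metrics.mean_step_length_paretic, metrics.mean_step_length_nonparetic) <= spec.min_step_length:
        reasons.append("step_length")
    return FilterDecision(keep=not reasons, reasons=reasons)
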