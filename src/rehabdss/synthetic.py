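"""Synthetic patients, sessions and case libraries.

Nothing in the clinical data pipeline is downloadable, so every other
module is exercised against simulated inputs with known structure.  The
simulator encodes only the qualitative relationships the decision rules
rely on — session-mean engagement and movement speed grow monotonically
with a latent patient ability in [0, 1], with additive Gaussian noise per
signal — plus the clinical-scale structure of the assessment records.  It
makes no attempt at biomechanical realism.

Two library generators are provided:

* :func:`generate_case_library` — session-level: simulates raw signal
  streams per patient per session, extracts the 20 features, and labels
  each case by an explicit threshold rule.  Features inherit the physical
  couplings of the signals (e.g. mean and median engagement co-vary).
* :func:`generate_feature_library` — feature-level: draws the 20-column
  feature matrix directly so that exactly two named columns carry label
  information and the remaining eighteen are independent noise.  This is
  the controlled setting for feature-selection and accuracy recovery
  experiments.

All generation is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .case_base import CaseLibrary, CaseRecord
from .metrics import (
    FEATURE_NAMES,
    Mode,
    SessionFeatures,
    SessionSignals,
    extract_features,
)
from .rule_engine import (
    Brunnstrom,
    MuscleTone,
    PatientAssessment,
    Prescription,
    RangeOfMotion,
    RuleBase,
    Side,
    StrengthLevel,
    infer_mode_and_level,
)

__all__ = [
    "PatientProfile",
    "LabelRule",
    "GenerationSpec",
    "generate_assessment",
    "generate_profile",
    "generate_session",
    "generate_case_library",
    "generate_feature_library",
    "DEFAULT_SAMPLES_PER_SESSION",
]

#: Samples per session per signal in the emulated device logs.
DEFAULT_SAMPLES_PER_SESSION = 12_000

#: Muscle tone grades compatible with each Brunnstrom stage in the rule base.
STAGE_TONES: dict[Brunnstrom, tuple[str, ...]] = {
    Brunnstrom.II: ("0", "1", "1+", "2"),
    Brunnstrom.III: ("1", "1+", "2", "3", "4"),
    Brunnstrom.IV: ("1", "1+", "2"),
    Brunnstrom.V: ("1", "1+", "2"),
}

#: Per-signal noise scales; chosen to give session statistics on the same
#: order as the deployed device's feature library (force ~1 N spread,
#: velocity ~0.03 m/s, percent traces ~15-20 points).
DEFAULT_NOISE_SD: dict[str, float] = {
    "force": 1.0,
    "velocity": 0.025,
    "fitness": 15.0,
    "engagement": 20.0,
}


@dataclass(frozen=True)
class PatientProfile:
    """Latent state driving a synthetic patient's signals."""

    assessment: PatientAssessment
    ability: float = 0.4
    recovery_rate: float = 0.01
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))

    def __post_init__(self) -> None:
        if not 0.0 <= self.ability <= 1.0:
            raise ValueError("ability must be in [0, 1]")
        if self.recovery_rate < 0:
            raise ValueError("recovery_rate must be >= 0")


@dataclass(frozen=True)
class LabelRule:
    """Explicit generative rule for the level-up label: the label is 1 iff
    every listed feature meets its threshold; then flipped with probability
    ``noise`` (label noise)."""

    thresholds: dict = field(
        default_factory=lambda: {"mean_engagement": 55.0, "mean_fitness": 78.0}
    )
    noise: float = 0.0

    def __post_init__(self) -> None:
        unknown = set(self.thresholds) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"label rule references unknown features: {sorted(unknown)}")
        if not 0.0 <= self.noise < 0.5:
            raise ValueError("label noise must be in [0, 0.5)")

    def apply(self, f: SessionFeatures | dict) -> bool:
        get = f.__getitem__ if isinstance(f, SessionFeatures) else f.get
        return all(get(name) >= thr for name, thr in self.thresholds.items())


@dataclass(frozen=True)
class GenerationSpec:
    n_patients: int = 50
    sessions_per_patient: int = 10
    samples_per_session: int = DEFAULT_SAMPLES_PER_SESSION
    seed: int = 0
    label_rule: LabelRule = field(default_factory=LabelRule)

    def __post_init__(self) -> None:
        for name in ("n_patients", "sessions_per_patient", "samples_per_session"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def generate_assessment(seed: int | np.random.Generator) -> PatientAssessment:
    """Draw an assessment uniform over the supported rehabilitation stages:
    Brunnstrom stage uniform on II-V, tone uniform over the grades the rule
    base supports for that stage."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    stage = Brunnstrom(rng.choice([s.value for s in Brunnstrom]))
    tone = MuscleTone(rng.choice(STAGE_TONES[stage]))
    return PatientAssessment(
        brunnstrom=stage,
        muscle_tone=tone,
        muscle_strength=int(rng.integers(0, 6)),
        rom=RangeOfMotion(rng.choice([r.value for r in RangeOfMotion])),
        affected_side=Side(rng.choice(["left", "right"])),
    )


def generate_profile(seed: int | np.random.Generator) -> PatientProfile:
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return PatientProfile(
        assessment=generate_assessment(rng),
        ability=float(rng.uniform(0.05, 0.95)),
        recovery_rate=float(rng.uniform(0.0, 0.03)),
    )


def _signal_means(ability: float, rx: Prescription) -> dict[str, float]:
    # Monotone ability -> signal-mean maps; a small strength-level effect on
    # engagement mirrors the observed positive level/engagement correlation.
    level_boost = 1.5 * (rx.strength_level.rank - 2)
    return {
        "force": 0.2 + 2.5 * ability,
        "velocity": 0.02 + 0.15 * ability,
        "fitness": 62.0 + 30.0 * ability,
        "engagement": min(5.0 + 90.0 * ability + level_boost, 100.0),
    }


def generate_session(
    p: PatientProfile,
    rx: Prescription,
    seed: int | np.random.Generator,
    samples: int = DEFAULT_SAMPLES_PER_SESSION,
) -> SessionSignals:
    """One session's four signal streams: per-signal constant generative
    mean (a deterministic function of ability and prescription) plus iid
    Gaussian noise; percent traces clipped to [0, 100], force and velocity
    to >= 0."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mu = _signal_means(p.ability, rx)
    sd = p.noise_sd
    force = np.clip(mu["force"] + sd["force"] * rng.standard_normal(samples), 0, None)
    velocity = np.clip(
        mu["velocity"] + sd["velocity"] * rng.standard_normal(samples), 0, None
    )
    fitness = np.clip(
        mu["fitness"] + sd["fitness"] * rng.standard_normal(samples), 0, 100
    )
    engagement = np.clip(
        mu["engagement"] + sd["engagement"] * rng.standard_normal(samples), 0, 100
    )
    return SessionSignals(
        force=force,
        velocity=velocity,
        fitness_trace=fitness,
        engagement_trace=engagement,
        mode=rx.mode,
    )


def generate_case_library(
    spec: GenerationSpec | None = None, rule_base: RuleBase | None = None
) -> CaseLibrary:
    """Session-level library: n_patients x sessions_per_patient cases.

    Each patient's mode and strength level come from the cycle-plan rules
    applied to their drawn assessment; ability increases by recovery_rate
    per session; the level-up label applies ``spec.label_rule`` to the
    extracted features, with the rule's label-noise flip probability.
    """
    spec = spec or GenerationSpec()
    rng = np.random.default_rng(spec.seed)
    lib = CaseLibrary()
    for i in range(spec.n_patients):
        profile = generate_profile(rng)
        mode, level = infer_mode_and_level(profile.assessment, rule_base)
        rx = Prescription(mode=mode, strength_level=level)
        ability = profile.ability
        for j in range(spec.sessions_per_patient):
            session = generate_session(
                PatientProfile(
                    assessment=profile.assessment,
                    ability=min(ability, 1.0),
                    recovery_rate=profile.recovery_rate,
                    noise_sd=profile.noise_sd,
                ),
                rx,
                rng,
                samples=spec.samples_per_session,
            )
            features = extract_features(session)
            label = spec.label_rule.apply(features)
            if spec.label_rule.noise > 0 and rng.random() < spec.label_rule.noise:
                label = not label
            lib.add(
                CaseRecord(
                    case_id=f"P{i:03d}S{j:03d}",
                    assessment=profile.assessment,
                    features=features,
                    prescription=rx,
                    level_up=label,
                )
            )
            ability += profile.recovery_rate
    return lib


# Plausible value ranges for the direct feature-level generator, per signal:
# (low, high) for the signal's location and a scale for its spread.
_FEATURE_RANGES = {
    "force": (0.0, 5.0, 1.0),
    "velocity": (0.0, 0.15, 0.03),
    "fitness": (0.0, 100.0, 15.0),
    "engagement": (0.0, 100.0, 20.0),
}


def generate_feature_library(
    n_cases: int,
    mode: Mode | str = Mode.PASSIVE,
    informative: tuple[str, str] = ("mean_engagement", "mean_velocity"),
    thresholds: dict | None = None,
    label_noise: float = 0.05,
    seed: int = 0,
) -> CaseLibrary:
    """Feature-level library: exactly two informative columns, 18 noise.

    The two ``informative`` features are drawn uniform over their signal's
    plausible range and the label is 1 iff both meet their threshold
    (defaults: the midpoint of each range), then flipped with probability
    ``label_noise``.  All other 18 columns are drawn independently of the
    label (order statistics per signal are kept internally consistent:
    min <= median <= max, sd >= 0).
    """
    mode = Mode(mode)
    if len(informative) != 2 or len(set(informative)) != 2:
        raise ValueError("exactly two distinct informative features required")
    rng = np.random.default_rng(seed)

    def _range_of(feat: str) -> tuple[float, float, float]:
        return _FEATURE_RANGES[feat.split("_", 1)[1]]

    if thresholds is None:
        thresholds = {
            feat: (_range_of(feat)[0] + _range_of(feat)[1]) / 2.0
            for feat in informative
        }
    rule = LabelRule(thresholds=thresholds, noise=label_noise)

    lib = CaseLibrary()
    assessment = PatientAssessment(brunnstrom=Brunnstrom.III, muscle_tone=MuscleTone.G2)
    rx = Prescription(mode=mode, strength_level=StrengthLevel.F2)
    for i in range(n_cases):
        values: dict[str, float] = {}
        for sig, (lo, hi, scale) in _FEATURE_RANGES.items():
            a, b = sorted(rng.uniform(lo, hi, size=2))
            values[f"min_{sig}"] = a
            values[f"max_{sig}"] = b
            values[f"median_{sig}"] = float(rng.uniform(a, b))
            values[f"sd_{sig}"] = float(abs(rng.normal(0, scale)))
            values[f"mean_{sig}"] = float(rng.uniform(lo, hi))
        for feat in informative:
            lo, hi, _ = _range_of(feat)
            values[feat] = float(rng.uniform(lo, hi))
        label = rule.apply(values)
        if label_noise > 0 and rng.random() < label_noise:
            label = not label
        lib.add(
            CaseRecord(
                case_id=f"F{i:05d}",
                assessment=assessment,
                features=SessionFeatures(values=values, mode=mode),
                prescription=rx,
                level_up=label,
            )
        )
    return lib
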