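"""Per-session quantitative metrics and the 20-statistic feature vector.

A training session on the desktop rehabilitation robot produces four
time-aligned signal streams: interaction force, movement speed of the
affected limb, trajectory fitness and engagement.  Two derived quantities
summarise how hard and how well the patient worked:

* **Engagement** — the percentage of the work a task requires from the arm
  that the patient's arm actually performed,
  ``100 * (W_total - W_motor) / (W_total - W_robot)``, where ``W_total`` is
  robot-plus-passive-arm work for the task, ``W_motor`` the robot's work
  during actual training and ``W_robot`` the robot's unloaded work.
* **Fitness** — the coefficient of determination (R^2, as a percentage)
  between the actual movement trajectory and the robot's preset trajectory.

Both are reported on a 0-100 scale; values are clipped to that range so a
patient who over-shoots the preset work, or whose residuals exceed the
trajectory variance, reports 100 or 0 rather than an out-of-range number.

Feature extraction condenses one session into exactly 20 statistics:
{mean, maximum, minimum, standard deviation, median} for each of the four
signals.  Standard deviation uses the sample (n-1) convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exceptions import (
    InvalidMeasurementError,
    MalformedSessionError,
    UndefinedFitnessError,
)

__all__ = [
    "Mode",
    "WorkMeasurements",
    "TrajectoryPair",
    "SessionSignals",
    "SessionFeatures",
    "SIGNAL_NAMES",
    "STATISTIC_NAMES",
    "FEATURE_NAMES",
    "compute_engagement",
    "compute_fitness",
    "extract_features",
]


class Mode(str, enum.Enum):
    """Robot training mode. Progression is passive -> assisted -> resisted."""

    PASSIVE = "passive"
    ASSISTED = "assisted"
    RESISTED = "resisted"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: The four per-session signal streams, in canonical order.
SIGNAL_NAMES: tuple[str, ...] = ("force", "velocity", "fitness", "engagement")

#: The five summary statistics applied to each signal, in canonical order.
STATISTIC_NAMES: tuple[str, ...] = ("mean", "max", "min", "sd", "median")

#: Canonical ordering of the 20 feature columns: statistics vary fastest
#: within a signal, i.e. mean_force, max_force, ..., median_engagement.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{stat}_{sig}" for sig in SIGNAL_NAMES for stat in STATISTIC_NAMES
)


@dataclass(frozen=True)
class WorkMeasurements:
    """Work quantities (J) measured for one training task.

    ``w_user`` (work done by the patient's arm) and ``w_arm`` (work the task
    requires from the arm alone) are derived differences and computed on
    construction.
    """

    w_total: float
    w_motor: float
    w_robot: float

    def __post_init__(self) -> None:
        for name in ("w_total", "w_motor", "w_robot"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise InvalidMeasurementError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def w_user(self) -> float:
        return self.w_total - self.w_motor

    @property
    def w_arm(self) -> float:
        return self.w_total - self.w_robot


@dataclass(frozen=True)
class TrajectoryPair:
    """Actual and preset trajectory samples for one session (same units)."""

    actual: np.ndarray
    preset: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "actual", np.asarray(self.actual, dtype=float))
        object.__setattr__(self, "preset", np.asarray(self.preset, dtype=float))
        if self.actual.ndim != 1 or self.preset.ndim != 1:
            raise UndefinedFitnessError("trajectories must be one-dimensional")
        if self.actual.shape != self.preset.shape:
            raise UndefinedFitnessError(
                f"actual ({self.actual.size}) and preset ({self.preset.size}) lengths differ"
            )
        if self.actual.size < 2:
            raise UndefinedFitnessError("need at least 2 observations")
        if not (np.isfinite(self.actual).all() and np.isfinite(self.preset).all()):
            raise UndefinedFitnessError("trajectories contain non-finite values")

    @property
    def n(self) -> int:
        return int(self.actual.size)


@dataclass(frozen=True)
class SessionSignals:
    """The four raw signal streams of one training session.

    force in N, velocity in m/s, fitness and engagement traces in percent.
    All four series share ``sample_count``.
    """

    force: np.ndarray
    velocity: np.ndarray
    fitness_trace: np.ndarray
    engagement_trace: np.ndarray
    mode: Mode

    def __post_init__(self) -> None:
        for name in ("force", "velocity", "fitness_trace", "engagement_trace"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.force.size
        if n == 0:
            raise MalformedSessionError("empty session")
        for name in ("velocity", "fitness_trace", "engagement_trace"):
            if getattr(self, name).size != n:
                raise MalformedSessionError(
                    f"{name} has {getattr(self, name).size} samples, force has {n}"
                )
        for name in ("fitness_trace", "engagement_trace"):
            series = getattr(self, name)
            if series.size and (series.min() < 0 or series.max() > 100):
                raise MalformedSessionError(f"{name} outside [0, 100]")
        object.__setattr__(self, "mode", Mode(self.mode))

    @property
    def sample_count(self) -> int:
        return int(self.force.size)


@dataclass(frozen=True)
class SessionFeatures:
    """The 20-statistic summary of one session, keyed by FEATURE_NAMES."""

    values: Mapping[str, float]
    mode: Mode

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.values)
        extra = set(self.values) - set(FEATURE_NAMES)
        if missing or extra:
            raise MalformedSessionError(
                f"feature vector must have exactly the 20 canonical fields; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        object.__setattr__(self, "values", dict(self.values))
        object.__setattr__(self, "mode", Mode(self.mode))

    def as_array(self) -> np.ndarray:
        """Feature values in canonical FEATURE_NAMES order."""
        return np.array([self.values[name] for name in FEATURE_NAMES], dtype=float)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def compute_engagement(w: WorkMeasurements) -> float:
    """Patient engagement for one task, in percent.

    Engagement = W_user / W_arm = (W_total - W_motor) / (W_total - W_robot),
    expressed as a percentage and clipped to [0, 100].

    Raises
    ------
    InvalidMeasurementError
        If W_total <= W_robot, which makes the required arm work
        non-positive and the ratio undefined.
    """
    denom = w.w_total - w.w_robot
    if denom <= 0:
        raise InvalidMeasurementError(
            f"W_total ({w.w_total}) must exceed W_robot ({w.w_robot}) "
            "for engagement to be defined"
        )
    raw = 100.0 * (w.w_total - w.w_motor) / denom
    return float(np.clip(raw, 0.0, 100.0))


def compute_fitness(t: TrajectoryPair) -> float:
    """Trajectory fitness for one session, in percent.

    R^2 = 1 - sum((y_i - yhat_i)^2) / sum((y_i - ybar)^2), where y is the
    actual trajectory, yhat the preset, and ybar the mean of the actual
    (observed) values.  Reported as R^2 * 100, clipped below at 0 — a
    trajectory that tracks the preset worse than its own mean scores 0.

    Raises
    ------
    UndefinedFitnessError
        If the actual sequence has zero variance.
    """
    y, yhat = t.actual, t.preset
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedFitnessError("actual trajectory is constant; fitness undefined")
    r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
    return float(np.clip(r2 * 100.0, 0.0, 100.0))


def _statistics(series: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(series)),
        "max": float(np.max(series)),
        "min": float(np.min(series)),
        "sd": float(np.std(series, ddof=1)),
        "median": float(np.median(series)),
    }


def extract_features(s: SessionSignals) -> SessionFeatures:
    """Condense one session into its 20-statistic feature vector.

    Five statistics (mean, max, min, sample sd, median) per signal,
    computed over the full session.
    """
    if s.sample_count < 2:
        raise MalformedSessionError("need at least 2 samples to extract features")
    values: dict[str, float] = {}
    for sig, series in zip(
        SIGNAL_NAMES, (s.force, s.velocity, s.fitness_trace, s.engagement_trace)
    ):
        for stat, v in _statistics(series).items():
            values[f"{stat}_{sig}"] = v
    return SessionFeatures(values=values, mode=s.mode)


def constant_session(
    mode: Mode | str,
    *,
    force: float = 1.0,
    velocity: float = 0.1,
    fitness: float = 80.0,
    engagement: float = 50.0,
    n: int = 100,
) -> SessionSignals:
    """Build a session whose four signals are constant — handy for threshold
    scans and tests where only the session means matter."""
    ones = np.ones(n)
    return SessionSignals(
        force=force * ones,
        velocity=velocity * ones,
        fitness_trace=fitness * ones,
        engagement_trace=engagement * ones,
        mode=Mode(mode),
    )
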