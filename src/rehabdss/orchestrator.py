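"""The end-to-end decision loop and the expert-rating arithmetic.

The loop fuses the two reasoning styles: the rule engine drafts the
cycle plan from the clinical assessment; then, after every training
session, the case-based/ML side refines it — first the strength level
(level-up classifier), then the training mode (threshold controller), in
that order — and the solved session is retained as a new case.  Only the
remaining (future) days of the plan are rewritten; completed days stay in
the trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .case_base import CaseLibrary, CaseRecord
from .exceptions import RehabDSSError
from .level_model import LevelModel, predict_level_up
from .metrics import Mode, SessionFeatures, SessionSignals, extract_features
from .mode_advance import AdvancementThresholds, check_advancement
from .rule_engine import (
    CyclePlan,
    PatientAssessment,
    Prescription,
    RuleBase,
    build_cycle_plan,
    build_daily_plan,
)

__all__ = [
    "DecisionTrace",
    "ExpertRating",
    "run_decision_loop",
    "score_expert_ratings",
]


@dataclass(frozen=True)
class DecisionTrace:
    """One session's decision record, serializable as a JSON line."""

    session_id: str
    mode_before: Mode
    level_before: str
    level_up_probability: float
    level_up: bool
    mode_advanced: bool
    mode_after: Mode
    level_after: str
    features: dict = field(repr=False, default_factory=dict)

    def to_json(self) -> str:
        d = {
            "session_id": self.session_id,
            "mode_before": self.mode_before.value,
            "level_before": self.level_before,
            "level_up_probability": self.level_up_probability,
            "level_up": self.level_up,
            "mode_advanced": self.mode_advanced,
            "mode_after": self.mode_after.value,
            "level_after": self.level_after,
            "features": self.features,
        }
        return json.dumps(d)


def run_decision_loop(
    assessment: PatientAssessment,
    sessions: Iterable[SessionSignals | SessionFeatures],
    models: Mapping[Mode, LevelModel],
    thresholds: AdvancementThresholds | None = None,
    library: CaseLibrary | None = None,
    rule_base: RuleBase | None = None,
    case_prefix: str = "case",
) -> tuple[CyclePlan, list[DecisionTrace], CaseLibrary]:
    """Run the full decision loop over a stream of sessions.

    The plan starts as the rule engine's cycle plan for ``assessment``.
    After session *i*: (1) the level-up classifier for the current mode
    scores the session's features and, on a positive decision, the
    strength level steps up one grade (saturating at F5); (2) the
    threshold controller checks mode advancement and, on advance, the
    strength level resets to the new mode's most conservative rule-base
    level; (3) the solved case is appended to the library with the
    level decision as its label; (4) all days after day *i* are rewritten
    with the updated prescription.

    Each incoming session must have been performed under the current
    prescription's mode; a missing model for a reached mode aborts.
    """
    thresholds = thresholds or AdvancementThresholds()
    library = library if library is not None else CaseLibrary()
    rb = rule_base or RuleBase.default()
    plan = build_cycle_plan(assessment, rule_base=rule_base)
    days = list(plan.days)
    current = plan.days[0].phases[1][1]  # stage-1 prescription
    traces: list[DecisionTrace] = []

    for i, session in enumerate(sessions):
        features = (
            session
            if isinstance(session, SessionFeatures)
            else extract_features(session)
        )
        if features.mode != current.mode:
            raise RehabDSSError(
                f"session {i} is {features.mode.value} but current plan mode "
                f"is {current.mode.value}"
            )
        model = models.get(current.mode)
        if model is None:
            raise RehabDSSError(
                f"no fitted level model for mode {current.mode.value}"
            )
        mode_before, level_before = current.mode, current.strength_level
        prob, level_up = predict_level_up(model, features)
        level = level_before.next() if level_up else level_before
        advanced, next_mode = check_advancement(current.mode, features, thresholds)
        if advanced:
            mode = next_mode
            level = rb.min_level_for_mode(next_mode)
        else:
            mode = current.mode
        new = Prescription(mode=mode, strength_level=level)

        library.add(
            CaseRecord(
                case_id=f"{case_prefix}-{i:04d}",
                assessment=assessment,
                features=features,
                prescription=Prescription(
                    mode=mode_before, strength_level=level_before
                ),
                level_up=level_up,
            )
        )
        traces.append(
            DecisionTrace(
                session_id=f"{case_prefix}-{i:04d}",
                mode_before=mode_before,
                level_before=level_before.value,
                level_up_probability=prob,
                level_up=level_up,
                mode_advanced=advanced,
                mode_after=mode,
                level_after=level.value,
                features=dict(features.values),
            )
        )
        if new != current:
            day = build_daily_plan(new)
            for j in range(i + 1, len(days)):
                days[j] = day
            current = new

    final = CyclePlan(
        brunnstrom=plan.brunnstrom,
        muscle_tone=plan.muscle_tone,
        weeks=plan.weeks,
        days=tuple(days),
    )
    return final, traces, library


@dataclass(frozen=True)
class ExpertRating:
    """One expert's marks for one training decision: mode and strength
    level each scored 0 or 5; the overall mark is their sum."""

    mode_mark: int
    level_mark: int

    def __post_init__(self) -> None:
        if self.mode_mark not in (0, 5) or self.level_mark not in (0, 5):
            raise ValueError("marks must be 0 or 5")

    @property
    def overall(self) -> int:
        return self.mode_mark + self.level_mark


def score_expert_ratings(
    ratings: Sequence[ExpertRating], expected_experts: int = 10
) -> tuple[float, float, float]:
    """(overall %, mode %, level %) for one training decision.

    Each of the ``expected_experts`` raters awards 0 or 5 for the mode and
    for the strength level; each component percentage is the summed marks
    over its full marks (5 per expert), and the overall percentage is the
    summed overall marks over 10 per expert.
    """
    if len(ratings) != expected_experts:
        raise ValueError(
            f"expected {expected_experts} expert ratings, got {len(ratings)}"
        )
    n = len(ratings)
    mode_total = sum(r.mode_mark for r in ratings)
    level_total = sum(r.level_mark for r in ratings)
    overall_total = sum(r.overall for r in ratings)
    return (
        100.0 * overall_total / (10 * n),
        100.0 * mode_total / (5 * n),
        100.0 * level_total / (5 * n),
    )
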