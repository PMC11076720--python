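"""Rule-based cycle-plan inference.

A therapist's opening decision — which training mode, which strength level,
how many weeks — is driven by two clinical scales: the Brunnstrom stage of
motor recovery (this system supports II-V) and the modified-Ashworth-style
muscle tone grade {0, 1, 1+, 2, 3, 4}.  The rule base maps each supported
(stage, tone) pair to exactly one prescription row; the engine assembles
from it a daily plan of four phases (2-min passive warm-up, two 10-min
training stages at the prescribed mode/level, 2-min passive relaxation) and
a cycle plan of at most 21 days (weeks x 7, capped — the 21-day limit
mirrors the insurance cap on consecutive training days at one facility).

The rule base ships as a versioned JSON resource and can be overridden by a
user-supplied file with the same schema; overrides are validated for
non-overlapping keys.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator

from .exceptions import RehabDSSError, UnsupportedAssessmentError
from .metrics import Mode

__all__ = [
    "Brunnstrom",
    "MuscleTone",
    "StrengthLevel",
    "RangeOfMotion",
    "Side",
    "PatientAssessment",
    "Prescription",
    "DailyPlan",
    "CyclePlan",
    "RuleBase",
    "PHASE_NAMES",
    "PHASE_DURATIONS_MIN",
    "MAX_PLAN_DAYS",
    "DEFAULT_SPEED_LEVEL",
    "infer_mode_and_level",
    "infer_weeks",
    "build_daily_plan",
    "build_cycle_plan",
]

PHASE_NAMES: tuple[str, ...] = ("warm-up", "stage1", "stage2", "relaxation")
PHASE_DURATIONS_MIN: tuple[int, ...] = (2, 10, 10, 2)
MAX_PLAN_DAYS = 21
DEFAULT_SPEED_LEVEL = 1


class Brunnstrom(str, enum.Enum):
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"


class MuscleTone(str, enum.Enum):
    G0 = "0"
    G1 = "1"
    G1P = "1+"
    G2 = "2"
    G3 = "3"
    G4 = "4"


class StrengthLevel(str, enum.Enum):
    """Robot strength level; difficulty increases from F1 to F5."""

    F1 = "F1"
    F2 = "F2"
    F3 = "F3"
    F4 = "F4"
    F5 = "F5"

    @property
    def rank(self) -> int:
        return int(self.value[1])

    def next(self) -> "StrengthLevel":
        """The next level up, saturating at F5."""
        return StrengthLevel(f"F{min(self.rank + 1, 5)}")


class RangeOfMotion(str, enum.Enum):
    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class PatientAssessment:
    """Clinical assessment record.

    Only brunnstrom and muscle_tone gate the rules; muscle strength, range
    of motion and affected side are carried for the case record.
    """

    brunnstrom: Brunnstrom
    muscle_tone: MuscleTone
    muscle_strength: int = 3
    rom: RangeOfMotion = RangeOfMotion.MEDIUM
    affected_side: Side = Side.RIGHT

    def __post_init__(self) -> None:
        object.__setattr__(self, "brunnstrom", Brunnstrom(self.brunnstrom))
        tone = self.muscle_tone
        if not isinstance(tone, MuscleTone):
            tone = MuscleTone(str(tone))
        object.__setattr__(self, "muscle_tone", tone)
        object.__setattr__(self, "rom", RangeOfMotion(self.rom))
        object.__setattr__(self, "affected_side", Side(self.affected_side))
        if not 0 <= int(self.muscle_strength) <= 5:
            raise UnsupportedAssessmentError(
                f"muscle strength must be 0-5, got {self.muscle_strength}"
            )

    def to_dict(self) -> dict:
        return {
            "brunnstrom": self.brunnstrom.value,
            "muscle_tone": self.muscle_tone.value,
            "muscle_strength": self.muscle_strength,
            "rom": self.rom.value,
            "affected_side": self.affected_side.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PatientAssessment":
        return cls(
            brunnstrom=Brunnstrom(d["brunnstrom"]),
            muscle_tone=MuscleTone(str(d["muscle_tone"])),
            muscle_strength=int(d.get("muscle_strength", 3)),
            rom=RangeOfMotion(d.get("rom", "medium")),
            affected_side=Side(d.get("affected_side", "right")),
        )


@dataclass(frozen=True)
class Prescription:
    mode: Mode
    strength_level: StrengthLevel
    speed_level: int = DEFAULT_SPEED_LEVEL
    duration_min: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", Mode(self.mode))
        object.__setattr__(self, "strength_level", StrengthLevel(self.strength_level))

    def to_dict(self) -> dict:
        return {
            "mode": self.mode.value,
            "strength_level": self.strength_level.value,
            "speed_level": self.speed_level,
            "duration_min": self.duration_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Prescription":
        return cls(
            mode=Mode(d["mode"]),
            strength_level=StrengthLevel(d["strength_level"]),
            speed_level=int(d["speed_level"]),
            duration_min=int(d["duration_min"]),
        )


#: Warm-up / relaxation phases always run passive mode at the lowest
#: difficulty (F1) and speed level 1 for 2 minutes.
REST_PRESCRIPTION = Prescription(
    mode=Mode.PASSIVE, strength_level=StrengthLevel.F1, duration_min=2
)


@dataclass(frozen=True)
class DailyPlan:
    """One day's four-phase schedule: warm-up, stage1, stage2, relaxation."""

    phases: tuple[tuple[str, Prescription], ...]

    def __post_init__(self) -> None:
        names = tuple(name for name, _ in self.phases)
        if names != PHASE_NAMES:
            raise RehabDSSError(f"daily plan phases must be {PHASE_NAMES}, got {names}")

    @property
    def total_minutes(self) -> int:
        return sum(p.duration_min for _, p in self.phases)

    def to_dict(self) -> dict:
        return {"phases": [[name, p.to_dict()] for name, p in self.phases]}

    @classmethod
    def from_dict(cls, d: dict) -> "DailyPlan":
        return cls(
            phases=tuple((name, Prescription.from_dict(p)) for name, p in d["phases"])
        )


@dataclass(frozen=True)
class CyclePlan:
    """The multi-day (<= 21) training schedule for one rehabilitation stage."""

    brunnstrom: Brunnstrom
    muscle_tone: MuscleTone
    weeks: int
    days: tuple[DailyPlan, ...]

    def to_dict(self) -> dict:
        return {
            "brunnstrom": self.brunnstrom.value,
            "muscle_tone": self.muscle_tone.value,
            "weeks": self.weeks,
            "days": [d.to_dict() for d in self.days],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CyclePlan":
        return cls(
            brunnstrom=Brunnstrom(d["brunnstrom"]),
            muscle_tone=MuscleTone(str(d["muscle_tone"])),
            weeks=int(d["weeks"]),
            days=tuple(DailyPlan.from_dict(x) for x in d["days"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, s: str) -> "CyclePlan":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class Rule:
    brunnstrom: Brunnstrom
    tones: frozenset[MuscleTone]
    weeks: int
    mode: Mode
    strength_level: StrengthLevel


class RuleBase:
    """The cycle-plan rule table: (stage, tone) -> (weeks, mode, level).

    Rows must not overlap: each supported (stage, tone) pair matches
    exactly one row.
    """

    def __init__(self, rules: list[Rule], version: int = 1):
        self.version = version
        self.rules = list(rules)
        seen: set[tuple[Brunnstrom, MuscleTone]] = set()
        for r in self.rules:
            for tone in r.tones:
                key = (r.brunnstrom, tone)
                if key in seen:
                    raise RehabDSSError(f"overlapping rule key {key}")
                seen.add(key)

    def __iter__(self) -> Iterator[Rule]:
        return iter(self.rules)

    def lookup(self, brunnstrom: Brunnstrom, tone: MuscleTone) -> Rule:
        for r in self.rules:
            if r.brunnstrom == brunnstrom and tone in r.tones:
                return r
        raise UnsupportedAssessmentError(
            f"no rule for Brunnstrom {brunnstrom.value}, muscle tone {tone.value}"
        )

    def supported_pairs(self) -> list[tuple[Brunnstrom, MuscleTone]]:
        return [(r.brunnstrom, tone) for r in self.rules for tone in sorted(r.tones, key=lambda t: t.value)]

    def min_level_for_mode(self, mode: Mode) -> StrengthLevel:
        """Most conservative strength level the rule base assigns a mode."""
        levels = [r.strength_level for r in self.rules if r.mode == mode]
        if not levels:
            raise UnsupportedAssessmentError(f"no rule-base row uses mode {mode}")
        return min(levels, key=lambda lv: lv.rank)

    @classmethod
    def from_dict(cls, d: dict) -> "RuleBase":
        rules = [
            Rule(
                brunnstrom=Brunnstrom(row["brunnstrom"]),
                tones=frozenset(MuscleTone(str(t)) for t in row["tones"]),
                weeks=int(row["weeks"]),
                mode=Mode(row["mode"]),
                strength_level=StrengthLevel(row["strength_level"]),
            )
            for row in d["rules"]
        ]
        return cls(rules, version=int(d.get("version", 1)))

    @classmethod
    def from_file(cls, path: str | Path) -> "RuleBase":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def default(cls) -> "RuleBase":
        text = resources.files("rehabdss.data").joinpath("rule_base.json").read_text()
        return cls.from_dict(json.loads(text))


_DEFAULT_RULES: RuleBase | None = None


def _rules(rule_base: RuleBase | None) -> RuleBase:
    global _DEFAULT_RULES
    if rule_base is not None:
        return rule_base
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = RuleBase.default()
    return _DEFAULT_RULES


def infer_mode_and_level(
    a: PatientAssessment, rule_base: RuleBase | None = None
) -> tuple[Mode, StrengthLevel]:
    """Training mode and strength level for an assessment, from the rule base."""
    r = _rules(rule_base).lookup(a.brunnstrom, a.muscle_tone)
    return r.mode, r.strength_level


def infer_weeks(a: PatientAssessment, rule_base: RuleBase | None = None) -> int:
    """Prescribed training weeks for an assessment (II->1, III->2, IV->5, V->8)."""
    return _rules(rule_base).lookup(a.brunnstrom, a.muscle_tone).weeks


def build_daily_plan(p: Prescription) -> DailyPlan:
    """Four-phase day: passive-F1 warm-up (2 min), two 10-min stages carrying
    the prescription, passive-F1 relaxation (2 min)."""
    stage = Prescription(
        mode=p.mode,
        strength_level=p.strength_level,
        speed_level=p.speed_level,
        duration_min=10,
    )
    return DailyPlan(
        phases=(
            ("warm-up", REST_PRESCRIPTION),
            ("stage1", stage),
            ("stage2", stage),
            ("relaxation", REST_PRESCRIPTION),
        )
    )


def build_cycle_plan(
    a: PatientAssessment, rule_base: RuleBase | None = None
) -> CyclePlan:
    """Full cycle plan: min(weeks x 7, 21) identical daily plans."""
    rb = _rules(rule_base)
    rule = rb.lookup(a.brunnstrom, a.muscle_tone)
    prescription = Prescription(mode=rule.mode, strength_level=rule.strength_level)
    n_days = min(rule.weeks * 7, MAX_PLAN_DAYS)
    day = build_daily_plan(prescription)
    return CyclePlan(
        brunnstrom=a.brunnstrom,
        muscle_tone=a.muscle_tone,
        weeks=rule.weeks,
        days=tuple(day for _ in range(n_days)),
    )
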