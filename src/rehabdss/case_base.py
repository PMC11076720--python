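"""Case library storage and similarity retrieval.

The case-based half of the system keeps every solved training session as a
:class:`CaseRecord` — assessment, 20-feature session summary, prescription
and the binary level-up outcome — partitioned by training mode, because the
three modes are modelled separately throughout.

Retrieval ranks a mode's cases by Euclidean distance to the query in
min-max-normalized feature space; the normalization bounds are fit on the
queried partition so every feature contributes on a comparable [0, 1]
scale.  Ties are broken by case id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DuplicateCaseError, NoCasesError
from .metrics import FEATURE_NAMES, Mode, SessionFeatures
from .rule_engine import PatientAssessment, Prescription

__all__ = ["CaseRecord", "CaseLibrary", "load_case_library", "save_case_library"]


@dataclass(frozen=True)
class CaseRecord:
    case_id: str
    assessment: PatientAssessment
    features: SessionFeatures
    prescription: Prescription
    level_up: bool

    def __post_init__(self) -> None:
        if self.features.mode != self.prescription.mode:
            raise ValueError(
                f"case {self.case_id}: features mode {self.features.mode} "
                f"!= prescription mode {self.prescription.mode}"
            )

    @property
    def mode(self) -> Mode:
        return self.prescription.mode


class CaseLibrary:
    """Solved cases partitioned by training mode, unique by case id."""

    def __init__(self, records: list[CaseRecord] | None = None):
        self._records: dict[str, CaseRecord] = {}
        self._by_mode: dict[Mode, list[CaseRecord]] = {m: [] for m in Mode}
        for r in records or []:
            self.add(r)

    def add(self, c: CaseRecord) -> None:
        if c.case_id in self._records:
            raise DuplicateCaseError(f"case id {c.case_id!r} already in library")
        self._records[c.case_id] = c
        self._by_mode[c.mode].append(c)

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, case_id: str) -> bool:
        return case_id in self._records

    def __getitem__(self, case_id: str) -> CaseRecord:
        return self._records[case_id]

    def partition(self, mode: Mode | str) -> list[CaseRecord]:
        return list(self._by_mode[Mode(mode)])

    def modes(self) -> dict[Mode, int]:
        return {m: len(recs) for m, recs in self._by_mode.items()}

    def feature_matrix(self, mode: Mode | str) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """(X, y, ids) for one mode's partition, columns in FEATURE_NAMES order."""
        recs = self.partition(mode)
        if not recs:
            raise NoCasesError(f"no cases for mode {Mode(mode).value}")
        X = np.vstack([r.features.as_array() for r in recs])
        y = np.array([int(r.level_up) for r in recs])
        return X, y, [r.case_id for r in recs]

    def retrieve_similar(
        self, query: SessionFeatures, mode: Mode | str, k: int = 5
    ) -> list[tuple[CaseRecord, float]]:
        """Up to ``k`` cases of ``mode`` by ascending normalized Euclidean
        distance to ``query``; ties broken by case id."""
        if k < 1:
            raise ValueError("k must be >= 1")
        recs = self.partition(mode)
        if not recs:
            raise NoCasesError(f"no cases for mode {Mode(mode).value}")
        X = np.vstack([r.features.as_array() for r in recs])
        q = query.as_array()
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = hi - lo
        # constant features carry no discriminative signal in this partition
        span[span == 0] = 1.0
        Xn = (X - lo) / span
        qn = (q - lo) / span
        d = np.sqrt(((Xn - qn) ** 2).sum(axis=1))
        order = sorted(range(len(recs)), key=lambda i: (d[i], recs[i].case_id))
        return [(recs[i], float(d[i])) for i in order[:k]]


# ---------------------------------------------------------------------------
# CSV round-trip: one row per case, 20 feature columns + assessment,
# prescription and label columns.

_META_COLS = [
    "case_id",
    "mode",
    "brunnstrom",
    "muscle_tone",
    "muscle_strength",
    "rom",
    "affected_side",
    "strength_level",
    "speed_level",
    "duration_min",
    "level_up",
]


def save_case_library(lib: CaseLibrary, path: str | Path) -> None:
    rows = []
    for mode in Mode:
        for r in lib.partition(mode):
            row = {
                "case_id": r.case_id,
                "mode": r.mode.value,
                "brunnstrom": r.assessment.brunnstrom.value,
                "muscle_tone": r.assessment.muscle_tone.value,
                "muscle_strength": r.assessment.muscle_strength,
                "rom": r.assessment.rom.value,
                "affected_side": r.assessment.affected_side.value,
                "strength_level": r.prescription.strength_level.value,
                "speed_level": r.prescription.speed_level,
                "duration_min": r.prescription.duration_min,
                "level_up": int(r.level_up),
            }
            row.update({name: r.features[name] for name in FEATURE_NAMES})
            rows.append(row)
    pd.DataFrame(rows, columns=_META_COLS + list(FEATURE_NAMES)).to_csv(
        path, index=False
    )


def load_case_library(path: str | Path) -> CaseLibrary:
    """Load a case-library CSV, validating the 20-feature-column contract."""
    df = pd.read_csv(path, dtype={"muscle_tone": str})
    missing = set(FEATURE_NAMES) - set(df.columns)
    if missing:
        raise ValueError(f"case CSV missing feature columns: {sorted(missing)}")
    lib = CaseLibrary()
    for _, row in df.iterrows():
        assessment = PatientAssessment(
            brunnstrom=row["brunnstrom"],
            muscle_tone=str(row["muscle_tone"]),
            muscle_strength=int(row["muscle_strength"]),
            rom=row["rom"],
            affected_side=row["affected_side"],
        )
        features = SessionFeatures(
            values={name: float(row[name]) for name in FEATURE_NAMES},
            mode=Mode(row["mode"]),
        )
        prescription = Prescription(
            mode=Mode(row["mode"]),
            strength_level=row["strength_level"],
            speed_level=int(row["speed_level"]),
            duration_min=int(row["duration_min"]),
        )
        lib.add(
            CaseRecord(
                case_id=str(row["case_id"]),
                assessment=assessment,
                features=features,
                prescription=prescription,
                level_up=bool(int(row["level_up"])),
            )
        )
    return lib
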