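"""Pattern-advancement submodel: threshold-controlled mode progression.

Machine learning is not usable for the mode transition (there are no
labelled transition examples during a patient's own training), so the
system uses fixed thresholds on session-average statistics:

* passive -> assisted when the session's mean engagement >= 70 %;
* assisted -> resisted when the session's mean movement speed >= 25 cm/s
  (0.25 m/s — velocity is stored in m/s internally);
* resisted is terminal.

Both comparisons are inclusive (>=).  A configurable lookback averages the
triggering statistic over the last N sessions (default 1, i.e. the current
session only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .exceptions import RehabDSSError
from .metrics import Mode, SessionFeatures

__all__ = ["AdvancementThresholds", "check_advancement", "NEXT_MODE"]

#: The acyclic mode-progression graph.
NEXT_MODE: dict[Mode, Mode | None] = {
    Mode.PASSIVE: Mode.ASSISTED,
    Mode.ASSISTED: Mode.RESISTED,
    Mode.RESISTED: None,
}


@dataclass(frozen=True)
class AdvancementThresholds:
    """engagement_min in percent (passive gate); speed_min in m/s
    (assisted gate)."""

    engagement_min: float = 70.0
    speed_min: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.engagement_min <= 100:
            raise ValueError("engagement_min must be in (0, 100]")
        if self.speed_min <= 0:
            raise ValueError("speed_min must be > 0")


def check_advancement(
    mode: Mode | str,
    f: SessionFeatures | Sequence[SessionFeatures],
    th: AdvancementThresholds | None = None,
) -> tuple[bool, Mode | None]:
    """Decide whether a session (or the mean over a lookback window of
    sessions) triggers progression to the next training mode.

    Returns ``(advance, next_mode)``; ``(False, None)`` when the gate is
    not met or the mode is terminal.
    """
    mode = Mode(mode)
    th = th or AdvancementThresholds()
    window = [f] if isinstance(f, SessionFeatures) else list(f)
    if not window:
        raise RehabDSSError("need at least one session to check advancement")
    for s in window:
        if s.mode != mode:
            raise RehabDSSError(
                f"session of mode {s.mode.value} passed to a {mode.value} check"
            )
    if mode == Mode.RESISTED:
        return False, None
    if mode == Mode.PASSIVE:
        stat = sum(s["mean_engagement"] for s in window) / len(window)
        passed = stat >= th.engagement_min
    else:  # assisted: gate on mean movement speed
        stat = sum(s["mean_velocity"] for s in window) / len(window)
        passed = stat >= th.speed_min
    return (True, NEXT_MODE[mode]) if passed else (False, None)
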