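"""Plain-text interchange formats.

One CSV per session, with a ``# mode=<mode>`` metadata header line.  Two
column layouts are accepted when reading:

* processed — ``time_s, force_n, velocity_mps, fitness_pct,
  engagement_pct`` (the layout this module writes);
* raw trajectory — ``time_s, force_n, velocity_mps, pos_actual,
  pos_preset, engagement_pct``: the fitness trace is then computed as a
  rolling-window R^2 between actual and preset positions (the engagement
  trace must be present, because engagement derives from work quantities
  the stream does not carry).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import MalformedSessionError
from .metrics import Mode, SessionSignals, TrajectoryPair, compute_fitness

__all__ = ["write_session_csv", "read_session_csv", "DEFAULT_SAMPLE_RATE_HZ"]

DEFAULT_SAMPLE_RATE_HZ = 10.0

#: Window length (samples) for the rolling R^2 when a raw trajectory
#: stream has to be converted into a fitness trace.
FITNESS_WINDOW = 50


def write_session_csv(
    s: SessionSignals, path: str | Path, sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
) -> None:
    path = Path(path)
    t = np.arange(s.sample_count) / sample_rate_hz
    df = pd.DataFrame(
        {
            "time_s": t,
            "force_n": s.force,
            "velocity_mps": s.velocity,
            "fitness_pct": s.fitness_trace,
            "engagement_pct": s.engagement_trace,
        }
    )
    with path.open("w") as fh:
        fh.write(f"# mode={s.mode.value}\n")
        df.to_csv(fh, index=False)


def _rolling_fitness(actual: np.ndarray, preset: np.ndarray) -> np.ndarray:
    n = actual.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - FITNESS_WINDOW + 1)
        a, p = actual[lo : i + 1], preset[lo : i + 1]
        if a.size < 2 or np.ptp(a) == 0:
            out[i] = out[i - 1] if i > 0 else 100.0
        else:
            out[i] = compute_fitness(TrajectoryPair(actual=a, preset=p))
    return out


def read_session_csv(path: str | Path) -> SessionSignals:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
    if not first.startswith("# mode="):
        raise MalformedSessionError(f"{path}: missing '# mode=' header line")
    mode = Mode(first.removeprefix("# mode=").strip())
    df = pd.read_csv(path, comment="#")
    required = {"force_n", "velocity_mps"}
    if not required.issubset(df.columns):
        raise MalformedSessionError(f"{path}: needs columns {sorted(required)}")
    if "fitness_pct" in df.columns:
        fitness = df["fitness_pct"].to_numpy(float)
    elif {"pos_actual", "pos_preset"}.issubset(df.columns):
        fitness = _rolling_fitness(
            df["pos_actual"].to_numpy(float), df["pos_preset"].to_numpy(float)
        )
    else:
        raise MalformedSessionError(
            f"{path}: needs fitness_pct or pos_actual/pos_preset columns"
        )
    if "engagement_pct" not in df.columns:
        raise MalformedSessionError(f"{path}: engagement_pct column is required")
    return SessionSignals(
        force=df["force_n"].to_numpy(float),
        velocity=df["velocity_mps"].to_numpy(float),
        fitness_trace=fitness,
        engagement_trace=df["engagement_pct"].to_numpy(float),
        mode=mode,
    )
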