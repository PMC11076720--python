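# rehabdss

Decision support for upper-limb rehabilitation robot training after
stroke. The package implements a hybrid reasoning system for desktop
rehabilitation robots: a **rule-based engine** turns a patient's clinical
assessment into an initial multi-day training plan, and a **case-based,
machine-learning-enhanced engine** adapts the plan session by session from
the robot's own measurements.

It is written for rehabilitation-informatics researchers and engineers who
need a transparent, testable reference implementation of this decision
loop — every rule table, threshold and model choice is explicit and
overridable.

## The model

**Cycle-plan inference (rule-based).** Two clinical scales gate the rules:
the Brunnstrom stage of motor recovery (supported range II–V) and the
muscle tone grade {0, 1, 1+, 2, 3, 4}. Each supported (stage, tone) pair
maps to exactly one row of the rule base: a training mode (passive /
assisted / resisted), a strength level F1–F5, and a number of training
weeks (II→1, III→2, IV→5, V→8). A day is four phases — 2-min passive
warm-up at F1, two 10-min training stages at the prescribed mode and
level, 2-min passive relaxation at F1 — and the plan spans
min(weeks × 7, 21) days; 21 is the insurance cap on consecutive training
days at one facility.

**Per-session metrics.** Each session yields four signal streams (force,
movement speed, trajectory fitness, engagement). Engagement is the share
of the task's required arm work the patient's arm delivered,

```
Engagement = W_user / W_arm = (W_total − W_motor) / (W_total − W_robot) × 100%
```

and fitness is the coefficient of determination between the actual and the
preset trajectory,

```
R² = 1 − Σ(yᵢ − ŷᵢ)² / Σ(yᵢ − ȳ)²,   Fitness = R² × 100%
```

both clipped to [0, 100]. A session is condensed into 20 features:
{mean, max, min, sample sd, median} × the four signals.

**Strength-level improvement (learned).** Whether a session warrants
promotion to the next strength level is a binary classification on the 20
features, fit per mode on the case library with the pipeline
*min-max normalization → chi-square feature selection (k = 19) → random
forest (54 trees, max depth 16, seed 70)*. A comparison harness
(`run_fusion_comparison`) crosses five classifiers with six
feature-processing schemes to reproduce the selection experiment that
motivates this pipeline.

**Pattern advancement (threshold control).** Mode progression is gated by
fixed thresholds, boundaries included: passive → assisted when
session-mean engagement ≥ 70 %, assisted → resisted when session-mean
speed ≥ 25 cm/s; resisted is terminal.

**The decision loop** (`run_decision_loop`) fuses the two: the rule engine
drafts the plan; after each session the level model updates the strength
level first, then the threshold controller updates the mode, the remaining
days are rewritten, and the solved session is retained as a new case.

## A worked example

`python examples/05_decision_loop.py` runs the full loop for a Brunnstrom
II / tone 0 patient (initial plan: passive F2, 7 days) over three sessions
whose statistics cross the gates in turn:

```
case-0000: passive F2 -> passive F2  (p_level_up=0.13, advanced=False)
case-0001: passive F2 -> assisted F2  (p_level_up=0.67, advanced=True)
case-0002: assisted F2 -> resisted F2  (p_level_up=0.78, advanced=True)
case base grew to 3 cases (one per solved session)
final day's training: resisted F2
```

Session 0 (40 % engagement) triggers nothing. Session 1 (92 % engagement)
crosses the 70 % gate, so the mode advances to assisted and the level
resets to the rule base's most conservative assisted level (F2). Session 2
(30 cm/s mean speed) crosses the 25 cm/s gate into resisted mode. Each
solved session becomes a retained case.

The other examples cover the cycle plan (`01`), the session metrics
(`02`), case retrieval (`03`), the learning pipeline on a controlled
library (`04`) and the expert-panel rating arithmetic (`06`). There is
also a thin CLI (`rehabdss plan|simulate|train|compare|update|score-experts`).

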