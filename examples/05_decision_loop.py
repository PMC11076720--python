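"""The full decision loop: rule-based plan, per-session CBR/ML updates.

A passive-mode patient's second session exceeds the 70% engagement gate,
so the controller advances the mode to assisted and rewrites the remaining
days of the cycle plan; every solved session is retained as a new case.
"""

from rehabdss import (
    CaseLibrary,
    GenerationSpec,
    Mode,
    PatientAssessment,
    fit_level_model,
    generate_case_library,
    run_decision_loop,
)
from rehabdss.metrics import constant_session

# fit a level model per mode on a synthetic case base
lib = generate_case_library(
    GenerationSpec(n_patients=40, sessions_per_patient=5, samples_per_session=300, seed=7)
)
models = {m: fit_level_model(lib, m) for m in Mode}

assessment = PatientAssessment(brunnstrom="II", muscle_tone="0")  # passive F2, 7 days
sessions = [
    constant_session("passive", engagement=40.0, velocity=0.05, fitness=70.0, n=100),
    constant_session("passive", engagement=92.0, velocity=0.10, fitness=90.0, n=100),
    constant_session("assisted", engagement=90.0, velocity=0.30, fitness=92.0, n=100),
]

plan, traces, case_base = run_decision_loop(assessment, sessions, models,
                                            library=CaseLibrary())
for t in traces:
    print(f"{t.session_id}: {t.mode_before.value} {t.level_before} -> "
          f"{t.mode_after.value} {t.level_after}  "
          f"(p_level_up={t.level_up_probability:.2f}, advanced={t.mode_advanced})")
print(f"case base grew to {len(case_base)} cases (one per solved session)")
final_stage1 = dict(plan.days[-1].phases)["stage1"]
print(f"final day's training: {final_stage1.mode.value} {final_stage1.strength_level.value}")
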