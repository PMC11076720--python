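"""Rule-based cycle plan: from clinical assessment to a 21-day schedule.

A Brunnstrom stage V patient with muscle tone 1+ is prescribed 8 weeks of
resisted-mode training at strength level F3, but the plan is capped at 21
days of four-phase sessions (2-min passive warm-up, two 10-min training
stages, 2-min passive relaxation).
"""

from rehabdss import PatientAssessment, build_cycle_plan, infer_mode_and_level, infer_weeks

assessment = PatientAssessment(brunnstrom="V", muscle_tone="1+")
mode, level = infer_mode_and_level(assessment)
plan = build_cycle_plan(assessment)

print(f"assessment: Brunnstrom {assessment.brunnstrom.value}, tone {assessment.muscle_tone.value}")
print(f"inferred prescription: {mode.value} mode, strength level {level.value}")
print(f"prescribed weeks: {infer_weeks(assessment)} -> scheduled days: {len(plan.days)} (cap 21)")
day = plan.days[0]
for name, rx in day.phases:
    print(f"  {name:<10} {rx.mode.value:<8} {rx.strength_level.value}  {rx.duration_min} min")
print(f"daily total: {day.total_minutes} min")
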