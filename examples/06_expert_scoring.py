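"""Expert-panel rating arithmetic for one training decision.

Ten experts each award 0 or 5 marks for the inferred mode and for the
strength level; the overall mark is their sum.  Here all ten endorse the
mode and eight endorse the level.
"""

from rehabdss import ExpertRating, score_expert_ratings

ratings = [ExpertRating(mode_mark=5, level_mark=5)] * 8 + [
    ExpertRating(mode_mark=5, level_mark=0)
] * 2
overall, mode_pct, level_pct = score_expert_ratings(ratings)
print(f"mode score:    {mode_pct:.0f} %  (50/50 marks)")
print(f"level score:   {level_pct:.0f} %  (40/50 marks)")
print(f"overall score: {overall:.0f} %  (90/100 marks)")
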