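"""Valence/arousal ratings: generation, rescaling, condition summaries.

Generates ratings for 18 participants with the default context effects
(fearful context: valence -0.93, arousal +0.79; happy context: valence
+0.46), rescales them so zero is each participant's grand mean, and prints
the per-condition summaries.
"""

from erpfield import condition_summary, generate_design, generate_ratings, rescale_scores

design = generate_design(18, seed=2)
ratings = generate_ratings(design, seed=2)
rescaled = rescale_scores(ratings)
summary = condition_summary(rescaled)
print(summary.to_string(index=False, float_format=lambda v: f"{v:+.3f}"))

per = (rescaled[rescaled.measure == "valence"]
       .groupby(["participant", "condition"])["score"].mean().unstack())
print(f"\nFear - Neutral valence difference: "
      f"{(per['Fear'] - per['Neutral']).mean():+.3f} (configured -0.93)")
print("Rescaled means are deviations from each participant's overall rating")
print("level: the fearful context lowers valence and raises arousal, the")
print("happy context raises valence.")
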