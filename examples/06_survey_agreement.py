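"""Interobserver agreement on simulated pathologist ratings.

Fleiss' kappa corrects multi-rater agreement for chance: 0 means chance
level, 1 perfect agreement, with conventional interpretation bands
(0.41-0.60 = moderate, etc.).
"""

from ramanstain import survey

# 35 images x 5 raters, with each rater reporting the true category 55% of
# the time and guessing otherwise
table = survey.simulate_ratings(seed=1, n_items=35, n_raters=5,
                                agreement=0.55)
res = survey.fleiss_kappa(table)
print(f"kappa = {res.kappa:.3f} (95% CI {res.ci_low:.3f}-{res.ci_high:.3f})")
print(f"interpretation: {res.interpretation}")

scores = survey.simulate_ratings(seed=2, n_items=35, n_raters=5,
                                 agreement=0.7, categories=(1, 2, 3, 4, 5))
summary = survey.summarize_scores(scores)
print("overall quality score:", summary["overall"]["formatted"])

# The CI uses the Fleiss large-sample variance; more items narrow it at
# the same agreement structure.
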