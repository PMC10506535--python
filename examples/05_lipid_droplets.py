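"""Lipid-droplet density per clinical-concern class.

Droplets are segmented by thresholding the SRS(2847)/SRS(2933) band ratio
(CH2-rich droplets exceed 1, protein-rich tissue stays below), densities
are area fractions per ROI, and classes are compared with one-way ANOVA
plus pairwise unpaired t tests.
"""

import numpy as np

from ramanstain import ldquant, phantom

lib = phantom.make_spectral_library(0)
threshold = lib.ld_ratio_threshold()
print(f"ratio threshold (midpoint of lipid and epithelium): {threshold:.3f}")

cohort = phantom.generate_ld_cohort(0, n_per_class=12, shape=(80, 80))
samples = [(it["bands"], ldquant.ROIAnnotation(it["roi"], it["class"]))
           for it in cohort]
stats = ldquant.ld_report(samples, threshold=threshold)

for cls, vals in stats.densities.items():
    print(f"{cls:9s}: mean density {np.mean(vals):.4f} "
          f"(IQR/mean {stats.heterogeneity[cls]:.3f})" if np.mean(vals) > 0
          else f"{cls:9s}: mean density {np.mean(vals):.4f}")
print(f"ANOVA: F = {stats.anova_F:.2f}, p = {stats.anova_p:.3e}")
for (a, b), res in stats.pairwise.items():
    print(f"  {a} vs {b}: t = {res['t']:+.2f}, p = {res['p']:.3e}")

# Moderate-concern glands carry the highest droplet load, then high, then
# low; stroma is essentially droplet-free.  The ANOVA p-value tests whether
# any class mean differs; the pairwise tests localize the differences.
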