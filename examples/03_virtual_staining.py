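"""Train the SRS -> H&E staining generator at desk scale and apply it.

Phase I fits pixel MSE only (sharp convergence, blurry output); phase II
continues from those weights with the adversarial + perceptual composite.
This desk-scale run uses 64x64 phantom patches and a few hundred
iterations; the full-scale configuration (50k + 200k iterations, batch 9,
384x384 crops) is `G1Config()`.
"""

import numpy as np

from ramanstain import phantom
from ramanstain.preprocess import PatchRecord
from ramanstain.train import G1Config, run_generator, train_g1

pairs = []
for i in range(8):
    s = phantom.generate_sample(i, shape=(64, 64),
                                grade_class=["low", "moderate", "high"][i % 3])
    pairs.append(PatchRecord(s.bands, s.ff_he, (0, 0), f"s{i}"))

cfg = G1Config.desk(seed=0, phase1_iters=60, phase2_iters=30)
gen, hist = train_g1(pairs, cfg)

p1 = [r["mse"] for r in hist.records if r["phase"] == 1]
print(f"phase-I MSE: {p1[0]:.4f} -> {p1[-1]:.4f}")

virtual = run_generator(gen, pairs[0].srs_patch.values)
real = pairs[0].he_patch.values
print(f"virtual stain vs real H&E mean |diff|: {np.abs(virtual - real).mean():.4f}")

# The MSE drop shows the warm-up learning the SRS->color mapping; the
# mean absolute difference compares the virtual stain with the paired
# ground-truth render.
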