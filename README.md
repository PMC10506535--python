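# ramanstain

Virtual H&E staining of stimulated-Raman-scattering (SRS) tissue images,
and the analysis around it.

SRS microscopy images fresh, unstained tissue in minutes by measuring
vibrational contrast in the CH-stretching window (2800–3105 cm⁻¹):
2847 cm⁻¹ highlights CH₂-rich lipid, 2933 cm⁻¹ CH₃-rich protein.
Pathologists, however, diagnose from H&E-stained thin sections — ideally
archival-quality FFPE ones that take hours to days to prepare.  This
package implements the computational bridge for prostate histopathology:

- **Virtual staining** — a U-Net generator G1 maps 7-band SRS images to
  fresh-frozen-style H&E, trained in two phases (pixel-MSE warm-up, then
  a least-squares GAN with multi-scale patch discriminators plus weighted
  pixel and perceptual terms: `L = L_adv + 0.01·L_MSE + 0.005·L_perc`).
- **Virtual FFPE** — cycle-consistent unpaired translation (G2: FF→FFPE,
  G3: FFPE→FF, `L = L_adv + 10·L_cyc` with L1 cycle loss), including
  multi-depth virtual sectioning of thick samples.
- **Band selection** — forward selection of discrete Raman shifts by how
  well OLS regression on them reconstructs the full 77-band spectrum on
  held-out pixels, with an exhaustive-subset reference.
- **Lipid-droplet quantification** — droplet segmentation by thresholding
  the SRS(2847)/SRS(2933) ratio, per-ROI area-fraction densities,
  IQR/mean heterogeneity, one-way ANOVA and pairwise unpaired t tests
  across clinical-concern classes.
- **Interobserver agreement** — Fleiss' kappa with 95% CI and the
  conventional interpretation bands, plus mean ± SD score summaries.
- **A seeded tissue phantom** — paired SRS cubes, band images, FF/FFPE
  H&E renders, ground-truth masks, FF artifacts (staining, freezing,
  knife cut, blurring), depth stacks, and planted lipid droplets, so the
  whole pipeline runs end to end with known ground truth.

The networks run on a compact NumPy reverse-mode autodiff engine included
in the package (`ramanstain.nn`); every gradient is validated against
finite differences in the test suite.

## Worked example

Quantify lipid-droplet density per clinical-concern class on a phantom
cohort (`examples/05_lipid_droplets.py`):

```python
from ramanstain import ldquant, phantom

lib = phantom.make_spectral_library(0)
cohort = phantom.generate_ld_cohort(0, n_per_class=12, shape=(80, 80))
samples = [(it["bands"], ldquant.ROIAnnotation(it["roi"], it["class"]))
           for it in cohort]
stats = ldquant.ld_report(samples, threshold=lib.ld_ratio_threshold())
```

prints

```
ratio threshold (midpoint of lipid and epithelium): 1.303
stroma   : mean density 0.0000
low      : mean density 0.0054 (IQR/mean 0.534)
moderate : mean density 0.0567 (IQR/mean 0.281)
high     : mean density 0.0301 (IQR/mean 0.344)
ANOVA: F = 178.20, p = 1.253e-24
```

The threshold sits between the epithelium and lipid band ratios, so
droplet pixels (ratio > 1) separate cleanly; the recovered class means
reproduce the planted ordering (moderate > high > low > stroma ≈ 0), and
the ANOVA confirms the classes differ.  Other examples cover phantom
generation, band selection, desk-scale training of both translation
models, multi-depth virtual sectioning, and agreement statistics.

A thin CLI wraps the same library functions:

```bash
ramanstain simulate --n 4 --seed 7 --out phantom_out
ramanstain select-bands --cube phantom_out/sample_000_cube.tif --k 7 --out model.json
ramanstain kappa --ratings ratings.csv
```

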