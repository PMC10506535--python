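# Methods

## Problem setting

Stimulated-Raman-scattering (SRS) microscopy measures label-free chemical
contrast from the CH-stretching region (2800–3105 cm⁻¹ at 4 cm⁻¹ steps, 77
bands): 2847 cm⁻¹ (CH₂, lipid), 2879, 2902, 2933 cm⁻¹ (CH₃, protein),
2960, 2979 and 3062 cm⁻¹ carry complementary protein/aromatic signal.
Fresh-frozen (FF) thick sections can be imaged this way in minutes, but
pathologists diagnose from H&E-stained thin sections, ideally from
archival-quality FFPE processing.  This package implements the
computational chain between those worlds:

1. **Virtual staining (G1)** — a paired image-to-image translation from
   7-band SRS images to FF-style H&E.
2. **Virtual FFPE (G2/G3)** — an unpaired, cycle-consistent translation
   from the FF H&E domain to the FFPE domain and back.
3. **Band selection** — which discrete Raman shifts suffice to reconstruct
   the full hyperspectral spectrum by regression.
4. **Lipid-droplet quantification** — segmentation by the 2847/2933 band
   ratio and per-ROI density statistics across clinical-concern classes.
5. **Interobserver agreement** — Fleiss' kappa with confidence intervals
   and conventional interpretation bands, plus score summaries.

A seeded synthetic tissue phantom supplies paired data for all of it, so
every stage is testable end to end on a laptop.

## Models and objectives

**Generators** are modified U-Nets: per level one 3×3 conv + instance
normalization + leaky-ReLU (slope 0.2), 2× average-pool downsampling,
nearest-neighbour upsampling with skip concatenation, and a final 1×1 conv
through a sigmoid so outputs always lie in [0, 1]³.  Inputs must be
divisible by 2^depth; the error message names the required padding.

**Discriminators** are multi-scale patch scorers: two networks of
identical layout and identical seeded initialization, one scoring the full
resolution image, the other always fed the 2× average-pooled input.  Each
is a stack of stride-2 conv blocks ending in a 1×1 conv that emits a
spatial realism map.

**Losses.**  The adversarial objective is the least-squares (LSGAN) form,
mean over scales of mean((score − target)²); the source equations for this
lineage render only as figures, and the LSGAN choice matches the
multi-scale-discriminator formulation this line of work builds on.  It is
isolated behind `loss_adversarial` so an alternative form is a one-function
change.  The staining model trains with

    L_G1 = L_adv + α·L_MSE + γ·L_perc,   α = 0.01, γ = 0.005,

where `L_perc` is the mean MSE between feature maps of prediction and
target under a *fixed* convolutional extractor.  α is assigned to the
pixel term and γ to the perceptual term; both are stabilizing regularizers
and the assignment is isolated in `LossWeights` so the alternative is a
config change.  The default extractor is a seeded random (never trained)
conv stack — deterministic, dependency-free, and sufficient for a
feature-space distance; conv weights exported from a pretrained VGG-19 can
be supplied as an `.npz` via the `pretrained_vgg19` provenance.  The
unpaired FFPE model trains G2 (FF→FFPE) and G3 (FFPE→FF) with

    L = L_adv(G2) + L_adv(G3) + λ·(L_cyc(FF) + L_cyc(FFPE)),   λ = 10,

with L1 cycle reconstruction, following the cycle-consistent formulation
for unpaired translation.  No image replay pool is kept — a deliberate
simplification.

**Optimization.**  Adam (β = 0.9, 0.999) with lr(t) = lr₀·0.96^⌊t/1000⌋.
The full-scale recipe is lr₀ = 10⁻⁴, 50,000 pixel-MSE iterations then
200,000 adversarial iterations at batch 9 for G1 (500×500 patches,
augmented by a seeded 384×384 crop plus a shared random affine), and
100,000 iterations at batch 6 for the cycle model.  Generator and
discriminator update 1:1 per iteration with the same learning rate.

**Desk-scale preset.**  The tested configuration runs the identical
algorithms at laptop scale: 64×64 patches, depth-2 U-Net at base width 16,
batch 4 (staining) / 2 (cycle), a few hundred iterations, and lr₀ = 10⁻³.
The hotter learning rate is the preset's own choice: at a few hundred
iterations the schedule barely decays, and 10⁻³ makes that budget
constitute real optimization for a network this small.  Problem sizes used
by the test suite and the reproduction script: 8 phantom pairs for the
staining smoke (300 + 300 iterations), 6 + 6 unpaired pools for the cycle
smoke (400 iterations), 24×24×77 cubes for band selection, 80 ROIs of
80×80 pixels for the droplet study, 35 items × 5 raters for agreement.

## Numerical substrate

The networks run on a compact reverse-mode autodiff engine over NumPy
arrays (`ramanstain.nn.autodiff`): broadcasting arithmetic, reductions,
activations, im2col-based 2-D convolution, average pooling, nearest
upsampling and concatenation, each op carrying an explicit backward
closure.  Scalars are coerced to the tensor's dtype so float32 graphs
never silently promote; the graph is acyclic by construction so memory is
reclaimed by reference counting.  Gradients of every op and every loss are
validated against central finite differences on float64 toys (rtol 1e-4).
Training at desk scale is single-threaded-CPU friendly (≈ 0.1 s per
staining iteration).

## The phantom

The generator emulates the study's data shapes, not tissue physics:

- **Spectra** (per class: stroma, nuclei, epithelium, lipid droplet) are
  sums of Gaussian peaks with small seeded jitter, max-normalized.  Lipid
  droplets satisfy I(2847)/I(2933) > 1; the protein classes < 1 — the
  contrast the droplet statistic rests on.  Background and lumen get weak
  flat spectra.
- **Morphology**: stroma background, circular glands with epithelial
  rings, nuclei dots, and lumens whose size tracks the clinical-concern
  class — low = open lumens, moderate = small crowded lumens, high = fused
  sheets without lumens.  Lipid droplets are disks carved out of
  epithelium until they occupy a requested fraction of the epithelial
  compartment (epithelium ∪ droplets), topped off pixel-by-pixel so the
  planted fraction is exact to one pixel; an unreachable request raises an
  error naming the achievable maximum.
- **Forward model**: pixel spectrum = class spectrum × smooth brightness
  field (+ optional Gaussian noise, optional blur, clipped at 0).  The
  model is deliberately the simplest one that preserves within-class band
  ratios.  Real SRS noise statistics are not published for this setting;
  the Gaussian stand-in is a placeholder and results under it say nothing
  about detector-specific noise.
- **H&E renders**: fixed per-class colors (hematoxylin blue-purple nuclei,
  eosin-pink stroma/epithelium, white lumens) modulated by a seeded smooth
  texture; FF and FFPE share the textured base and differ by a global
  contrast stretch (0.85 vs 1.25 about mid-gray), which guarantees the
  FFPE render has strictly higher per-channel contrast.  FF renders can
  carry four artifact families — staining unevenness (multiplicative
  field), freezing holes (white ellipses), knife cuts (straight raised
  streak of configured width/contrast), local blurring — FFPE renders are
  defined artifact-free.
- **Depth stacks**: gland centers/radii drift linearly with depth scaled
  by a decorrelation parameter (0 freezes morphology); a tumor-onset mode
  plants high-grade glands only at planes at or beyond a given depth.
- **Droplet fractions** per class default to stroma 0, low 0.005, high
  0.03, moderate 0.05 — moderate-concern glands carry the highest load,
  with ±30% per-ROI jitter for intraclass heterogeneity.

What passing tests on this phantom demonstrate: the pipeline's operations
are correct on data with known ground truth.  What they do not
demonstrate: performance on real tissue, where spectra overlap, morphology
is irregular, staining varies, and registration is imperfect.

## Statistics

- **ANOVA** is computed from explicit between/within sums of squares with
  p from the F distribution; the two-group case reduces exactly to the
  squared pooled t statistic (tested).
- **Pairwise t tests** default to the pooled-variance form (matching the
  common numerical-environment default); Welch is available via a flag.
  No multiplicity correction is applied — the pairwise tests are reported
  raw.
- **Heterogeneity** is IQR/mean with linear-interpolation quantiles
  (NumPy's default); scale-invariant by construction.
- **Fleiss' kappa** uses κ = (P̄ − P̄ₑ)/(1 − P̄ₑ) with the large-sample
  Fleiss variance and a normal 95% CI; a bootstrap CI (resampling items)
  is available behind a flag since the CI convention for such tables is
  not standardized.  Interpretation bands: ≤ 0 chance-or-worse,
  0.01–0.20 none-to-slight, 0.21–0.40 fair, 0.41–0.60 moderate, 0.61–0.80
  substantial, 0.81–1.00 almost perfect.
- **LD density** is an area fraction (droplet pixels / valid ROI pixels);
  a count-per-area definition is available behind a flag.  The ratio
  threshold is not hard-coded: the phantom library exposes the midpoint of
  its lipid and epithelium ratios, and the CLI requires the value
  explicitly and records it in the report.

## Numerical and design choices

- Nearest-band lookup for requested frequencies breaks exact ties toward
  the lower shift (deterministic; e.g. 2846 on the 4 cm⁻¹ grid resolves to
  2844).
- Bilinear 2× upsampling is origin-corner aligned: output pixel j samples
  input coordinate j/2 with edge clamping, so even rows/columns reproduce
  the input exactly.
- Affine registration is the closed-form least-squares fit to ≥ 3
  non-collinear control points; collinear configurations are rejected.
  Warping is inverse-mapped bilinear with out-of-bounds filled by the
  image median (avoids dark borders leaking into training).  Coordinates
  are 0-based (row, col), origin top-left, half-open patch windows.
- Augmentation draws the crop offset uniformly over all valid positions
  and applies one shared affine (±10° rotation, scale 0.9–1.1, ±5° shear —
  chosen defaults, not prescribed anywhere) to both patch members,
  sampling from the full source patch; crops at the patch border can pick
  up median fill under extreme draws.
- Band-subset scoring uses precomputed train/test Gram matrices so greedy
  and exhaustive searches are fast; a condition-number guard (cond > 1e10
  → score ∞) rejects near-singular subsets whose SSE would otherwise be
  catastrophically cancelled.  Selection ties break toward the lower
  shift, making the search order-invariant.  Held-out evaluation (default
  25% of pixels, seeded split) guards against optimistically noisy
  in-sample fits.  Note that on *exactly* noise-free low-rank cubes the
  optimal subset is degenerate (any invertible triple is exact), so
  peak-recovery claims are only meaningful with a noise floor.
- Tiled inference accumulates flat per-tile weights and normalizes by
  coverage, so blend weights sum to exactly 1 everywhere and an identity
  generator returns its input under any tiling.
- All file writes are atomic (temp + rename); cubes/band images travel as
  multi-page float32 TIFF (ascending wavenumber) with a JSON sidecar
  recording shifts, pixel size and depth.

## Known limitations

- The phantom's gland geometry is circular and its color model is a lookup,
  not a stain-physics model; networks trained on it will not transfer to
  real tissue.
- No deformable registration: alignment is global affine by design, as
  sophisticated nonrigid alignment is explicitly out of scope.
- The perceptual extractor's random provenance changes the loss landscape
  relative to a pretrained VGG-19; the contract (fixed, never trained,
  named taps) is identical.
- Desk-scale GAN smokes verify optimization mechanics (losses fall, warm
  starts are exact, histories reproduce bit-for-bit), not image quality.
- Full-scale training (hundreds of thousands of iterations) is configured
  but not exercised by the test suite.
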