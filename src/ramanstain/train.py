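"""Training loops and inference for the two translation models.

The staining generator (SRS bands → FF H&E) trains in two phases: a pixel
MSE warm-up, then adversarial fine-tuning with the composite loss.  The
FF→FFPE translator trains as a cycle-consistent pair of generators on
unpaired image pools.  Both use Adam with a stepped geometric learning-rate
decay, and both record a complete per-iteration history.

The ``desk`` presets run the identical algorithms at laptop scale (64×64
phantom patches, a few hundred iterations); the default configs mirror the
full-scale recipe (50k + 200k iterations at batch 9 for staining, 100k at
batch 6 for the cycle model).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,
    DiscriminatorSpec,
    FeatureExtractor,
    GeneratorSpec,
    LossWeights,
    MultiScaleDiscriminator,
    Tensor,
    UNetGenerator,
    cycle_total_loss,
    g1_total_loss,
    loss_adversarial,
    loss_cycle,
    loss_mse,
)
from .phantom import BandImage, RGBImage
from .preprocess import PatchRecord, augment

__all__ = [
    "G1Config",
    "CycleConfig",
    "TrainingHistory",
    "lr_schedule",
    "train_g1",
    "train_cycle",
    "run_generator",
    "infer_tiled",
    "virtual_sectioning",
]


@dataclass
class G1Config:
    """Staining-model training configuration (defaults = full recipe)."""

    phase1_iters: int = 50_000
    phase2_iters: int = 200_000
    batch: int = 9
    lr0: float = 1e-4
    decay_factor: float = 0.96
    decay_every: int = 1_000
    weights: LossWeights = field(default_factory=LossWeights)
    crop: int = 384
    seed: int = 0
    in_channels: int = 7
    base_width: int = 64
    depth: int = 4
    augment_affine: bool = True
    desk_scale: bool = False

    def __post_init__(self):
        if min(self.phase1_iters, self.phase2_iters, self.batch, self.decay_every) < 1:
            raise ValueError("iteration counts, batch and decay_every must be >= 1")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")

    @classmethod
    def desk(cls, seed: int = 0, phase1_iters: int = 300, phase2_iters: int = 300,
             batch: int = 4) -> "G1Config":
        """Laptop-scale preset: 64×64 crops, narrow network, hotter learning
        rate so a few hundred iterations constitute real optimisation."""
        return cls(phase1_iters=phase1_iters, phase2_iters=phase2_iters,
                   batch=batch, lr0=1e-3, crop=64, seed=seed, base_width=16,
                   depth=2, augment_affine=False, desk_scale=True)


@dataclass
class CycleConfig:
    """Unpaired FF→FFPE training configuration (defaults = full recipe)."""

    iters: int = 100_000
    batch: int = 6
    lr0: float = 1e-4
    decay_factor: float = 0.96
    decay_every: int = 1_000
    weights: LossWeights = field(default_factory=LossWeights)
    crop: int = 384
    seed: int = 0
    base_width: int = 64
    depth: int = 4
    desk_scale: bool = False

    def __post_init__(self):
        if min(self.iters, self.batch, self.decay_every) < 1:
            raise ValueError("iters, batch and decay_every must be >= 1")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")

    @classmethod
    def desk(cls, seed: int = 0, iters: int = 400, batch: int = 2) -> "CycleConfig":
        return cls(iters=iters, batch=batch, lr0=1e-3, crop=64, seed=seed,
                   base_width=16, depth=2, desk_scale=True)


@dataclass
class TrainingHistory:
    records: list = field(default_factory=list)
    phase_boundaries: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def column(self, key: str) -> np.ndarray:
        return np.array([r[key] for r in self.records if key in r])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.records)


def lr_schedule(lr0: float, factor: float = 0.96, every: int = 1_000):
    """Stepped geometric decay: lr(t) = lr0 · factor^⌊t/every⌋."""
    if lr0 <= 0 or not 0 < factor <= 1 or every < 1:
        raise ValueError("invalid schedule parameters")

    def lr(t: int) -> float:
        return lr0 * factor ** (t // every)

    return lr


def _check_finite(value: float, what: str, iteration: int) -> None:
    if not np.isfinite(value):
        raise RuntimeError(
            f"non-finite {what} ({value}) at iteration {iteration}; aborting"
        )


def _patch_batch(patches, cfg: G1Config, rng: np.random.Generator):
    """Draw and augment a batch, returning NCHW srs and he arrays."""
    n = len(patches)
    idx = rng.integers(0, n, size=cfg.batch)
    srs_list, he_list = [], []
    for i in idx:
        p = patches[int(i)]
        aug_seed = int(rng.integers(0, 2**31 - 1))
        a = augment(p, crop=cfg.crop, seed=aug_seed, affine=cfg.augment_affine)
        srs_list.append(a.srs_patch.to_chw())
        he_list.append(np.moveaxis(a.he_patch.values, -1, 0))
    return (
        np.stack(srs_list).astype(np.float32),
        np.stack(he_list).astype(np.float32),
        [int(i) for i in idx],
    )


def train_g1(patches: list[PatchRecord], cfg: G1Config):
    """Two-phase training of the staining generator.

    Phase I minimises pixel MSE alone; phase II continues from the phase-I
    weights with the composite adversarial + MSE + perceptual objective and
    1:1 alternating discriminator updates.  Returns the generator and the
    full history; the phase-I final parameter checksum is recorded so the
    warm-start contract is verifiable.
    """
    if not patches:
        raise ValueError("empty patch dataset")
    h, w = patches[0].srs_patch.shape[:2]
    if h < cfg.crop or w < cfg.crop:
        raise ValueError(f"patches {h}×{w} smaller than crop {cfg.crop}")
    rng = np.random.default_rng(cfg.seed)
    gen = UNetGenerator(GeneratorSpec(cfg.in_channels, 3, cfg.base_width, cfg.depth,
                                      seed=cfg.seed))
    disc = MultiScaleDiscriminator(DiscriminatorSpec(3, layers=3,
                                                     base_width=cfg.base_width,
                                                     seed=cfg.seed + 1))
    fx = FeatureExtractor(in_channels=3, seed=cfg.seed + 2)
    sched = lr_schedule(cfg.lr0, cfg.decay_factor, cfg.decay_every)
    opt_g = Adam(gen.parameters(), lr=cfg.lr0)
    opt_d = Adam(disc.parameters(), lr=cfg.lr0)
    history = TrainingHistory(meta={
        "weights": {"alpha": cfg.weights.alpha, "gamma": cfg.weights.gamma,
                    "lambda_cyc": cfg.weights.lambda_cyc},
        "lr0": cfg.lr0, "decay_factor": cfg.decay_factor,
        "decay_every": cfg.decay_every, "batch": cfg.batch, "seed": cfg.seed,
    })

    t = 0
    for _ in range(cfg.phase1_iters):
        lr = sched(t)
        opt_g.lr = lr
        srs, he, idx = _patch_batch(patches, cfg, rng)
        pred = gen(Tensor(srs))
        loss = loss_mse(pred, Tensor(he))
        _check_finite(loss.item(), "phase-I MSE", t)
        opt_g.zero_grad()
        loss.backward()
        opt_g.step()
        history.records.append({"iteration": t, "phase": 1, "lr": lr,
                                "mse": loss.item(), "indices": idx})
        t += 1

    history.phase_boundaries["phase1_end"] = t
    history.meta["phase1_final_checksum"] = gen.checksum()
    history.meta["phase2_initial_checksum"] = gen.checksum()

    for _ in range(cfg.phase2_iters):
        lr = sched(t)
        opt_g.lr = lr
        opt_d.lr = lr
        srs, he, idx = _patch_batch(patches, cfg, rng)
        real = Tensor(he)
        pred = gen(Tensor(srs))
        # discriminator step on detached fakes
        fake_detached = Tensor(pred.data.copy())
        d_real = loss_adversarial(disc(real), 1.0)
        d_fake = loss_adversarial(disc(fake_detached), 0.0)
        d_loss = (d_real + d_fake) * 0.5
        _check_finite(d_loss.item(), "discriminator loss", t)
        opt_d.zero_grad()
        d_loss.backward()
        opt_d.step()
        # generator step on the composite objective
        scores = disc(pred)
        g_loss, breakdown = g1_total_loss(pred, real, scores, fx, cfg.weights)
        _check_finite(g_loss.item(), "generator loss", t)
        opt_g.zero_grad()
        opt_d.zero_grad()  # discard discriminator grads from the G pass
        g_loss.backward()
        opt_g.step()
        history.records.append({
            "iteration": t, "phase": 2, "lr": lr, "d_loss": d_loss.item(),
            "g_total": breakdown["total"], "adversarial": breakdown["adversarial"],
            "mse": breakdown["mse"], "perceptual": breakdown["perceptual"],
            "indices": idx,
        })
        t += 1

    return gen, history


def _image_pool(images) -> list[np.ndarray]:
    out = []
    for im in images:
        arr = im.values if isinstance(im, RGBImage) else np.asarray(im)
        out.append(np.moveaxis(arr, -1, 0).astype(np.float32))
    return out


def train_cycle(vs_images, ffpe_images, cfg: CycleConfig):
    """Cycle-consistent unpaired training of the FF→FFPE translator (G2)
    and its inverse (G3) against per-domain multi-scale discriminators.

    Batches are drawn independently from each pool at every iteration.
    Returns (g2, g3, history).
    """
    vs_pool = _image_pool(vs_images)
    ffpe_pool = _image_pool(ffpe_images)
    if not vs_pool or not ffpe_pool:
        raise ValueError("both image pools must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    g2 = UNetGenerator(GeneratorSpec(3, 3, cfg.base_width, cfg.depth, seed=cfg.seed))
    g3 = UNetGenerator(GeneratorSpec(3, 3, cfg.base_width, cfg.depth, seed=cfg.seed + 1))
    d_ffpe = MultiScaleDiscriminator(DiscriminatorSpec(3, layers=3,
                                                       base_width=cfg.base_width,
                                                       seed=cfg.seed + 2))
    d_vs = MultiScaleDiscriminator(DiscriminatorSpec(3, layers=3,
                                                     base_width=cfg.base_width,
                                                     seed=cfg.seed + 3))
    sched = lr_schedule(cfg.lr0, cfg.decay_factor, cfg.decay_every)
    opt_g = Adam(g2.parameters() + g3.parameters(), lr=cfg.lr0)
    opt_d = Adam(d_ffpe.parameters() + d_vs.parameters(), lr=cfg.lr0)
    history = TrainingHistory(meta={
        "lambda_cyc": cfg.weights.lambda_cyc, "lr0": cfg.lr0, "batch": cfg.batch,
        "decay_factor": cfg.decay_factor, "decay_every": cfg.decay_every,
        "seed": cfg.seed,
    })

    for t in range(cfg.iters):
        lr = sched(t)
        opt_g.lr = lr
        opt_d.lr = lr
        idx_vs = rng.integers(0, len(vs_pool), size=cfg.batch)
        idx_ffpe = rng.integers(0, len(ffpe_pool), size=cfg.batch)
        vs = Tensor(np.stack([vs_pool[int(i)] for i in idx_vs]))
        ffpe = Tensor(np.stack([ffpe_pool[int(i)] for i in idx_ffpe]))

        fake_ffpe = g2(vs)
        rec_vs = g3(fake_ffpe)
        fake_vs = g3(ffpe)
        rec_ffpe = g2(fake_vs)

        cyc_a = loss_cycle(vs, rec_vs)
        cyc_b = loss_cycle(ffpe, rec_ffpe)
        adv_a = loss_adversarial(d_ffpe(fake_ffpe), 1.0)
        adv_b = loss_adversarial(d_vs(fake_vs), 1.0)
        g_loss = cycle_total_loss([adv_a, adv_b], [cyc_a, cyc_b], cfg.weights)
        _check_finite(g_loss.item(), "cycle generator loss", t)
        opt_g.zero_grad()
        opt_d.zero_grad()
        g_loss.backward()
        opt_g.step()

        d_loss = (
            loss_adversarial(d_ffpe(ffpe), 1.0)
            + loss_adversarial(d_ffpe(Tensor(fake_ffpe.data.copy())), 0.0)
            + loss_adversarial(d_vs(vs), 1.0)
            + loss_adversarial(d_vs(Tensor(fake_vs.data.copy())), 0.0)
        ) * 0.25
        _check_finite(d_loss.item(), "cycle discriminator loss", t)
        opt_d.zero_grad()
        d_loss.backward()
        opt_d.step()

        history.records.append({
            "iteration": t, "lr": lr, "g_total": g_loss.item(),
            "cycle": cyc_a.item() + cyc_b.item(),
            "adversarial": adv_a.item() + adv_b.item(),
            "d_loss": d_loss.item(),
            "indices_vs": [int(i) for i in idx_vs],
            "indices_ffpe": [int(i) for i in idx_ffpe],
        })

    return g2, g3, history


def run_generator(generator, image: np.ndarray) -> np.ndarray:
    """Apply a generator to one H×W×C image, returning H×W×3 in [0, 1]."""
    x = np.moveaxis(np.asarray(image, dtype=np.float32), -1, 0)[None]
    y = generator(Tensor(x))
    return np.moveaxis(y.data[0], 0, -1)


def infer_tiled(generator, image: np.ndarray, tile: int, overlap: int = 0) -> np.ndarray:
    """Whole-image inference by overlapping tiles with normalized blending.

    Per-pixel blend weights sum to exactly 1 (each tile contributes a flat
    weight which is normalized by the accumulated coverage), so a generator
    that is the identity returns the input unchanged under any tiling.  When
    ``tile`` covers the whole image this reduces to a single direct pass.
    """
    if overlap < 0 or tile < 1:
        raise ValueError("need tile >= 1 and overlap >= 0")
    if overlap >= tile:
        raise ValueError("overlap must be smaller than tile")
    img = np.asarray(image, dtype=np.float32)
    h, w = img.shape[:2]
    if tile >= h and tile >= w:
        return run_generator(generator, img)
    step = tile - overlap

    def starts(extent):
        if tile >= extent:
            return [0]
        s = list(range(0, extent - tile, step))
        s.append(extent - tile)
        return s

    out = None
    acc = np.zeros((h, w, 1), dtype=np.float64)
    for r in starts(h):
        for c in starts(w):
            th = min(tile, h)
            tw = min(tile, w)
            piece = run_generator(generator, img[r : r + th, c : c + tw])
            if out is None:
                out = np.zeros((h, w, piece.shape[2]), dtype=np.float64)
            out[r : r + th, c : c + tw] += piece
            acc[r : r + th, c : c + tw] += 1.0
    return (out / acc).astype(np.float32)


def virtual_sectioning(g1, g2, stack: list[BandImage], tile: int | None = None,
                       overlap: int = 0):
    """Per-depth virtual staining and FFPE conversion of a band-image stack.

    Each plane is processed independently: vf = g1(bands), vffpe = g2(vf);
    depth metadata is propagated.  Returns a list of dicts with keys
    ``depth_um``, ``virtual_ff``, ``virtual_ffpe``.
    """
    results = []
    for bands in stack:
        img = bands.values
        if tile is None:
            vf = run_generator(g1, img)
            vffpe = run_generator(g2, vf)
        else:
            vf = infer_tiled(g1, img, tile, overlap)
            vffpe = infer_tiled(g2, vf, tile, overlap)
        results.append({
            "depth_um": bands.depth_um,
            "virtual_ff": RGBImage(vf, "VIRTUAL_FF"),
            "virtual_ffpe": RGBImage(vffpe, "VIRTUAL_FFPE"),
        })
    return results
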