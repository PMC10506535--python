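"""Loss functions for the two translation models.

The virtual-staining generator (SRS bands → fresh-frozen H&E) trains against
a composite of least-squares adversarial loss, pixel MSE weighted by
``alpha``, and a perceptual (feature-map MSE) term weighted by ``gamma``.
The unpaired FF→FFPE translator trains a cycle-consistent pair of
generators with L1 cycle loss weighted by ``lambda_cyc``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .autodiff import Tensor
from .layers import FeatureExtractor

__all__ = [
    "LossWeights",
    "loss_mse",
    "loss_perceptual",
    "loss_adversarial",
    "g1_total_loss",
    "loss_cycle",
    "cycle_total_loss",
]


@dataclass
class LossWeights:
    """Default weights follow the virtual-staining training recipe:
    alpha = 0.01 (pixel MSE), gamma = 0.005 (perceptual), lambda = 10
    (cycle consistency)."""

    alpha: float = 0.01
    gamma: float = 0.005
    lambda_cyc: float = 10.0

    def __post_init__(self):
        if self.alpha < 0 or self.gamma < 0 or self.lambda_cyc < 0:
            raise ValueError("loss weights must be nonnegative")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _check_shapes(a: Tensor, b: Tensor, name: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{name}: shape mismatch {a.shape} vs {b.shape}")


def loss_mse(pred, target) -> Tensor:
    """Mean squared elementwise difference."""
    pred, target = _as_tensor(pred), _as_tensor(target)
    _check_shapes(pred, target, "loss_mse")
    d = pred - target
    return (d * d).mean()


def loss_perceptual(pred, target, fx: FeatureExtractor) -> Tensor:
    """Mean over feature taps of the MSE between feature maps of the two
    images under a fixed extractor."""
    pred, target = _as_tensor(pred), _as_tensor(target)
    _check_shapes(pred, target, "loss_perceptual")
    taps_p = fx(pred)
    taps_t = fx(target)
    total = None
    for fp, ft in zip(taps_p, taps_t):
        term = loss_mse(fp, ft)
        total = term if total is None else total + term
    return total * (1.0 / len(taps_p))


def loss_adversarial(d_scores_per_scale, target_label: float) -> Tensor:
    """Least-squares GAN objective, averaged over discriminator scales:
    mean over scales of mean((score - target)^2)."""
    scores = [_as_tensor(s) for s in d_scores_per_scale]
    if not scores:
        raise ValueError("loss_adversarial: no score maps given")
    total = None
    for s in scores:
        d = s - float(target_label)
        term = (d * d).mean()
        total = term if total is None else total + term
    return total * (1.0 / len(scores))


def g1_total_loss(pred, target, d_scores, fx: FeatureExtractor,
                  w: LossWeights) -> tuple[Tensor, dict]:
    """Composite staining-generator objective.

    total = adv(d_scores, 1) + alpha * MSE(pred, target)
          + gamma * perceptual(pred, target)

    Returns the total and a breakdown with the raw (unweighted) terms and
    their weighted contributions.
    """
    if w.alpha < 0 or w.gamma < 0:
        raise ValueError("loss weights must be nonnegative")
    adv = loss_adversarial(d_scores, 1.0)
    mse = loss_mse(pred, target)
    perc = loss_perceptual(pred, target, fx)
    total = adv + w.alpha * mse + w.gamma * perc
    breakdown = {
        "adversarial": adv.item(),
        "mse": mse.item(),
        "perceptual": perc.item(),
        "weighted_mse": w.alpha * mse.item(),
        "weighted_perceptual": w.gamma * perc.item(),
        "total": total.item(),
    }
    return total, breakdown


def loss_cycle(x, reconstruction) -> Tensor:
    """L1 distance between an image and its round-trip reconstruction."""
    x, reconstruction = _as_tensor(x), _as_tensor(reconstruction)
    _check_shapes(x, reconstruction, "loss_cycle")
    return (x - reconstruction).abs().mean()


def cycle_total_loss(adv_terms, cycle_terms, w: LossWeights) -> Tensor:
    """Full unpaired-translation objective: both generators' adversarial
    terms plus lambda-weighted cycle terms for both directions."""
    adv_terms = [_as_tensor(t) for t in adv_terms]
    cycle_terms = [_as_tensor(t) for t in cycle_terms]
    total = None
    for t in adv_terms:
        total = t if total is None else total + t
    for t in cycle_terms:
        term = w.lambda_cyc * t
        total = term if total is None else total + term
    if total is None:
        raise ValueError("cycle_total_loss: no terms supplied")
    return total
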