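"""Lipid-droplet quantification from SRS band ratios.

Lipid droplets carry a CH2-dominant spectrum, so the ratio
SRS(2847)/SRS(2933) exceeds 1 inside droplets and stays below 1 in the
protein-rich compartments.  Thresholding that ratio segments droplets;
per-ROI droplet density (area fraction) is then compared across
clinical-concern classes with one-way ANOVA and pairwise unpaired t tests,
and intraclass heterogeneity is summarised as IQR/mean.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from skimage import measure

from .phantom import BandImage

__all__ = [
    "ROIAnnotation",
    "LDResult",
    "GroupStats",
    "ratio_map",
    "segment_ld",
    "ld_density",
    "heterogeneity",
    "anova_oneway",
    "pairwise_t",
    "ld_report",
]

ROI_CLASSES = ("low", "moderate", "high", "stroma")


@dataclass
class ROIAnnotation:
    """A region of interest: either a boolean mask or a polygon (x, y
    vertices, converted to a mask on demand)."""

    region: np.ndarray  # bool H×W mask, or (n, 2) polygon vertices
    class_label: str

    def __post_init__(self):
        if self.class_label not in ROI_CLASSES:
            raise ValueError(f"class must be one of {ROI_CLASSES}")
        self.region = np.asarray(self.region)

    def mask(self, shape=None) -> np.ndarray:
        if self.region.dtype == bool:
            m = self.region
        else:
            from skimage.draw import polygon2mask

            if shape is None:
                raise ValueError("polygon ROI needs an image shape")
            # vertices are (x, y); polygon2mask wants (row, col)
            m = polygon2mask(shape, self.region[:, ::-1])
        if not m.any():
            raise ValueError("ROI region is empty")
        return m


@dataclass
class LDResult:
    roi: ROIAnnotation
    density: float

    def __post_init__(self):
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")


@dataclass
class GroupStats:
    densities: dict  # class -> list of per-ROI densities
    anova_F: float
    anova_p: float
    pairwise: dict  # (class_a, class_b) -> {"t": ..., "p": ...}
    heterogeneity: dict  # class -> IQR/mean (nan where mean == 0)
    n_per_class: dict = field(default_factory=dict)


def ratio_map(bands: BandImage, epsilon: float = 1e-6):
    """Elementwise r = S2847 / (S2933 + epsilon).

    Returns ``(ratio, valid)`` where ``valid`` is False wherever
    S2933 <= epsilon (the ratio is meaningless there and must be excluded
    downstream).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    try:
        s2847 = bands.channel(2847)
        s2933 = bands.channel(2933)
    except KeyError as exc:
        raise KeyError("ratio_map requires the 2847 and 2933 cm^-1 channels") from exc
    valid = s2933 > epsilon
    ratio = s2847 / (s2933 + epsilon)
    return ratio, valid


def segment_ld(ratio: np.ndarray, threshold: float, min_size: int = 0,
               valid: np.ndarray | None = None) -> np.ndarray:
    """Binary droplet mask: ratio > threshold, with connected components
    smaller than ``min_size`` pixels removed."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    mask = np.asarray(ratio) > threshold
    if valid is not None:
        mask &= valid
    if min_size > 1 and mask.any():
        labels = measure.label(mask, connectivity=2)
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_size)
        mask[np.isin(labels, small[small > 0])] = False
    return mask


def ld_density(mask: np.ndarray, roi: ROIAnnotation,
               valid: np.ndarray | None = None, mode: str = "area") -> LDResult:
    """Droplet density within an ROI.

    ``mode="area"`` (default): LD pixels ∩ ROI over valid ROI pixels.
    ``mode="count"``: connected droplet components per valid ROI pixel —
    the count-based alternative definition.
    """
    m = roi.mask(np.asarray(mask).shape)
    denom_mask = m if valid is None else (m & valid)
    denom = int(np.count_nonzero(denom_mask))
    if denom == 0:
        raise ValueError("ROI has no valid pixels")
    if mode == "area":
        num = int(np.count_nonzero(np.asarray(mask) & denom_mask))
    elif mode == "count":
        labels = measure.label(np.asarray(mask) & denom_mask, connectivity=2)
        num = int(labels.max())
    else:
        raise ValueError("mode must be 'area' or 'count'")
    return LDResult(roi=roi, density=min(num / denom, 1.0))


def heterogeneity(values) -> float:
    """Interquartile range over arithmetic mean (linear-interpolation
    quartiles).  Scale-invariant: both numerator and denominator scale with
    the data."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("values must be nonempty")
    m = arr.mean()
    if m <= 0:
        raise ValueError("heterogeneity is defined for positive-mean samples")
    q1, q3 = np.percentile(arr, [25, 75])  # linear interpolation
    return float((q3 - q1) / m)


def anova_oneway(groups) -> tuple[float, float]:
    """One-way ANOVA from explicit sums of squares.

    F = MS_between / MS_within; p from the F(k−1, N−k) distribution.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    n_total = all_values.size
    k = len(groups)
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0:
        if ss_between == 0:
            raise ValueError("F undefined: zero between- and within-group variance")
        return float("inf"), 0.0
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return float(f), p


def pairwise_t(groups: dict, welch: bool = False) -> dict:
    """Unpaired two-sample t tests for every unordered class pair
    (two-sided p, no multiplicity correction).  Pooled-variance by default;
    ``welch=True`` switches to the unequal-variance form."""
    out = {}
    for a, b in itertools.combinations(sorted(groups), 2):
        t, p = _t_two_sample(groups[a], groups[b], welch=welch)
        out[(a, b)] = {"t": t, "p": p}
    return out


def _t_two_sample(x, y, welch: bool = False) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    nx, ny = x.size, y.size
    dmean = x.mean() - y.mean()
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if welch:
        se2 = vx / nx + vy / ny
        df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    else:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se2 = sp2 * (1 / nx + 1 / ny)
        df = nx + ny - 2
    if se2 == 0:
        if dmean == 0:
            return 0.0, 1.0
        return float(np.sign(dmean)) * float("inf"), 0.0
    t = dmean / np.sqrt(se2)
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return float(t), p


def ld_report(samples, threshold: float, min_size: int = 0,
              epsilon: float = 1e-6, boxplot_path=None) -> GroupStats:
    """Run the full droplet chain over a cohort and compare classes.

    ``samples`` is an iterable of ``(BandImage, ROIAnnotation)`` pairs (one
    ROI each) or of ``(BandImage, [ROIAnnotation, ...])``.  Classes with
    fewer than 2 ROIs are excluded with a warning.
    """
    densities: dict = {}
    for bands, rois in samples:
        if isinstance(rois, ROIAnnotation):
            rois = [rois]
        ratio, valid = ratio_map(bands, epsilon)
        mask = segment_ld(ratio, threshold, min_size, valid)
        for roi in rois:
            res = ld_density(mask, roi, valid)
            densities.setdefault(roi.class_label, []).append(res.density)
    kept = {}
    for cls, vals in densities.items():
        if len(vals) < 2:
            warnings.warn(f"class {cls!r} has {len(vals)} ROI(s); excluded")
            continue
        kept[cls] = vals
    if len(kept) < 2:
        raise ValueError("need at least 2 classes with >= 2 ROIs each")
    f, p = anova_oneway(list(kept.values()))
    pairs = pairwise_t(kept)
    het = {}
    for cls, vals in kept.items():
        arr = np.asarray(vals)
        het[cls] = heterogeneity(arr) if arr.mean() > 0 else float("nan")
    stats_out = GroupStats(
        densities=kept, anova_F=f, anova_p=p, pairwise=pairs,
        heterogeneity=het, n_per_class={c: len(v) for c, v in kept.items()},
    )
    if boxplot_path is not None:
        _boxplot(kept, boxplot_path)
    return stats_out


def _boxplot(densities: dict, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = [c for c in ("stroma", "low", "moderate", "high") if c in densities]
    fig, ax = plt.subplots(figsize=(5, 4))
    data = [np.asarray(densities[c]) + 1e-6 for c in order]
    ax.boxplot(data, tick_labels=order)
    ax.set_yscale("log")
    ax.set_ylabel("LD density (log scale)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
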