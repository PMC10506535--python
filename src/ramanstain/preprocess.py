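"""Registration, resampling, tiling and augmentation.

SRS and H&E sections are acquired on different instruments, so they are
macroscopically aligned with user-picked control points and a least-squares
affine; SRS images acquired at 1 µm sampling are bilinearly upsampled 2x to
match 0.5 µm data.  Co-registered pairs are tiled into 500×500 patches, and
training draws seeded 384×384 crops with a shared random affine.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import BandImage, RGBImage

__all__ = [
    "ControlPoints",
    "AffineTransform",
    "PatchRecord",
    "upsample2x",
    "estimate_affine",
    "warp",
    "tile",
    "augment",
    "draw_crop_offset",
    "two_color",
]


@dataclass
class ControlPoints:
    """Paired landmarks: list of ((x, y) moving, (x, y) fixed) pixel coords."""

    pairs: list

    def __post_init__(self):
        self.pairs = [((float(mx), float(my)), (float(fx), float(fy)))
                      for (mx, my), (fx, fy) in self.pairs]

    def arrays(self):
        moving = np.array([p[0] for p in self.pairs])
        fixed = np.array([p[1] for p in self.pairs])
        return moving, fixed


@dataclass
class AffineTransform:
    """2×3 matrix mapping moving (x, y, 1) to fixed (x, y)."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (2, 3):
            raise ValueError("affine matrix must be 2×3")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("affine matrix must be finite")
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise ValueError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(xy)
        return xy @ self.matrix[:, :2].T + self.matrix[:, 2]

    def inverse(self) -> "AffineTransform":
        a = self.matrix[:, :2]
        t = self.matrix[:, 2]
        a_inv = np.linalg.inv(a)
        return AffineTransform(np.hstack([a_inv, (-a_inv @ t)[:, None]]))

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        a = self.matrix[:, :2] @ other.matrix[:, :2]
        t = self.matrix[:, :2] @ other.matrix[:, 2] + self.matrix[:, 2]
        return AffineTransform(np.hstack([a, t[:, None]]))


@dataclass
class PatchRecord:
    """Aligned SRS / H&E crop pair with provenance."""

    srs_patch: BandImage
    he_patch: RGBImage
    origin: tuple
    source_id: str = ""

    def __post_init__(self):
        if self.srs_patch.shape[:2] != self.he_patch.shape[:2]:
            raise ValueError("patch members must share H×W")


def upsample2x(image: np.ndarray) -> np.ndarray:
    """Bilinear 2x upsampling, origin-corner aligned.

    Output pixel j samples the input at coordinate j/2 (clamped at the far
    edge), so even rows/columns reproduce the input exactly and odd ones are
    midpoints — the convention used to bring 1 µm SRS sampling to 0.5 µm.
    """
    img = np.asarray(image, dtype=float)
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("image must be at least 2×2")

    def up_axis(a, axis):
        a = np.moveaxis(a, axis, 0)
        n = a.shape[0]
        out = np.empty((2 * n,) + a.shape[1:], dtype=a.dtype)
        out[0::2] = a
        out[1:-1:2] = 0.5 * (a[:-1] + a[1:])
        out[-1] = a[-1]  # clamp: no input sample beyond the last
        return np.moveaxis(out, 0, axis)

    return up_axis(up_axis(img, 0), 1)


def estimate_affine(points: ControlPoints) -> AffineTransform:
    """Least-squares affine from ≥3 non-collinear control-point pairs."""
    moving, fixed = points.arrays()
    if moving.shape[0] < 3:
        raise ValueError("affine estimation needs at least 3 control points")
    design = np.hstack([moving, np.ones((moving.shape[0], 1))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("control points are collinear; affine is underdetermined")
    sol, *_ = np.linalg.lstsq(design, fixed, rcond=None)
    return AffineTransform(sol.T)


def warp(image: np.ndarray, transform: AffineTransform, out_shape=None,
         fill=None) -> np.ndarray:
    """Inverse-mapped bilinear warp of ``image`` (moving) into the fixed
    frame.  Out-of-bounds pixels are filled with the image median unless
    ``fill`` overrides it."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape[:2]
    out_h, out_w = out_shape if out_shape is not None else (h, w)
    if fill is None:
        fill = float(np.median(img))
    inv = transform.inverse()
    ys, xs = np.mgrid[0:out_h, 0:out_w]
    coords_fixed = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    coords_moving = inv.apply(coords_fixed)
    sample = np.stack([coords_moving[:, 1], coords_moving[:, 0]])  # (row, col)
    if img.ndim == 2:
        out = ndimage.map_coordinates(img, sample, order=1, mode="constant",
                                      cval=fill)
        return out.reshape(out_h, out_w)
    chans = [
        ndimage.map_coordinates(img[:, :, c], sample, order=1, mode="constant",
                                cval=fill).reshape(out_h, out_w)
        for c in range(img.shape[2])
    ]
    return np.stack(chans, axis=-1)


def tile(srs: BandImage, he: RGBImage, size: int = 500, stride: int = 500,
         source_id: str = "") -> list[PatchRecord]:
    """Grid of fully in-bounds aligned patch pairs (row-major origins)."""
    if srs.shape[:2] != he.shape[:2]:
        raise ValueError("images must be co-registered with identical H×W")
    h, w = srs.shape[:2]
    if h < size or w < size:
        warnings.warn(f"image {h}×{w} smaller than patch size {size}; no patches")
        return []
    records = []
    for r in range(0, h - size + 1, stride):
        for c in range(0, w - size + 1, stride):
            records.append(
                PatchRecord(
                    BandImage(srs.values[r : r + size, c : c + size], srs.shifts,
                              srs.pixel_size_um, srs.depth_um),
                    RGBImage(he.values[r : r + size, c : c + size], he.style),
                    origin=(r, c),
                    source_id=source_id,
                )
            )
    return records


def draw_crop_offset(rng: np.random.Generator, max_y: int, max_x: int) -> tuple:
    """The crop-offset draw used by :func:`augment`: uniform over
    {0..max_y−1} × {0..max_x−1}."""
    return int(rng.integers(0, max_y)), int(rng.integers(0, max_x))


def _random_affine_about(center_xy, rng, rotation_deg=10.0, scale_range=(0.9, 1.1),
                         shear_deg=5.0) -> AffineTransform:
    theta = math.radians(rng.uniform(-rotation_deg, rotation_deg))
    s = rng.uniform(*scale_range)
    shear = math.radians(rng.uniform(-shear_deg, shear_deg))
    cx, cy = center_xy
    rot = np.array(
        [[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]]
    )
    shear_m = np.array([[1.0, math.tan(shear)], [0.0, 1.0]])
    a = s * rot @ shear_m
    t = np.array([cx, cy]) - a @ np.array([cx, cy])
    return AffineTransform(np.hstack([a, t[:, None]]))


def augment(patch: PatchRecord, crop: int = 384, seed: int = 0,
            rotation_deg: float = 10.0, scale_range=(0.9, 1.1),
            shear_deg: float = 5.0, affine: bool = True) -> PatchRecord:
    """Seeded random crop plus one shared random affine.

    Both patch members get the same crop offset (uniform over every valid
    position) and the same affine; the warp samples from the full source
    patch so crops near the centre pick up no fill pixels under the default
    parameter ranges.
    """
    h, w = patch.srs_patch.shape[:2]
    if crop > h or crop > w:
        raise ValueError(f"crop {crop} larger than patch {h}×{w}")
    rng = np.random.default_rng(seed)
    oy, ox = draw_crop_offset(rng, h - crop + 1, w - crop + 1)
    srs = patch.srs_patch.values
    he = patch.he_patch.values
    if affine:
        center = (ox + (crop - 1) / 2.0, oy + (crop - 1) / 2.0)
        aff = _random_affine_about(center, rng, rotation_deg, scale_range, shear_deg)
        # compose affine with the crop translation: output pixel (c, r) in the
        # crop frame maps to source (c + ox, r + oy) before the affine
        crop_shift = AffineTransform(
            np.array([[1.0, 0.0, -float(ox)], [0.0, 1.0, -float(oy)]])
        )
        total = crop_shift.compose(aff)
        srs_out = warp(srs, total, out_shape=(crop, crop))
        he_out = warp(he, total, out_shape=(crop, crop))
    else:
        srs_out = srs[oy : oy + crop, ox : ox + crop]
        he_out = he[oy : oy + crop, ox : ox + crop]
    return PatchRecord(
        BandImage(srs_out, patch.srs_patch.shifts, patch.srs_patch.pixel_size_um,
                  patch.srs_patch.depth_um),
        RGBImage(np.clip(he_out, 0.0, 1.0), patch.he_patch.style),
        origin=(oy, ox),
        source_id=patch.source_id,
    )


def two_color(bands: BandImage) -> RGBImage:
    """Dual-frequency false-color rendering: blue = max-normalized
    clip(S2933 − S2847, ≥0) (nuclei/stroma, DAPI-like), green =
    max-normalized S2847 (cytoplasm, actin-like), red = 0."""
    try:
        s2847 = bands.channel(2847)
        s2933 = bands.channel(2933)
    except KeyError as exc:
        raise KeyError("two_color requires the 2847 and 2933 cm^-1 channels") from exc
    blue = np.clip(s2933 - s2847, 0.0, None)
    if blue.max() > 0:
        blue = blue / blue.max()
    green = s2847 / s2847.max() if s2847.max() > 0 else s2847
    rgb = np.zeros(s2847.shape + (3,), dtype=float)
    rgb[:, :, 1] = green
    rgb[:, :, 2] = blue
    return RGBImage(rgb, "VIRTUAL_FF")
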