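"""Synthetic prostate-tissue phantoms with paired SRS cubes and H&E renders.

The generator emulates the data a coherent-Raman virtual-staining study
works with: hyperspectral stimulated-Raman-scattering (SRS) cubes over the
CH-stretching window (2800–3105 cm⁻¹), seven-band discrete-frequency
images, fresh-frozen (FF) and formalin-fixed paraffin-embedded (FFPE)
style H&E renderings of the same ground-truth tissue mask, multi-depth
section stacks, and lipid droplets planted at controlled area fractions
per clinical-concern class.

Everything is driven by explicit seeds: the same seed and configuration
reproduce a sample bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DEFAULT_BANDS",
    "CLASS_CODES",
    "CLASS_NAMES",
    "WavenumberAxis",
    "SpectralLibrary",
    "LabelMask",
    "HyperspectralCube",
    "BandImage",
    "RGBImage",
    "ArtifactConfig",
    "PhantomSample",
    "make_axis",
    "make_spectral_library",
    "extended_library",
    "generate_tissue_mask",
    "render_cube",
    "sample_bands",
    "render_he",
    "generate_sample",
    "generate_stack",
    "generate_dataset",
    "generate_ld_cohort",
]

#: The seven discrete Raman shifts used for band imaging (cm^-1).
DEFAULT_BANDS = (2847, 2879, 2902, 2933, 2960, 2979, 3062)

#: Label-mask class codes (8-bit PNG on disk uses these raw values).
CLASS_CODES = {
    "background": 0,
    "stroma": 1,
    "epithelium": 2,
    "nucleus": 3,
    "lumen": 4,
    "lipid_droplet": 5,
}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}

GRADE_CLASSES = ("low", "moderate", "high")

# Default planted lipid-droplet area fractions per clinical-concern class.
# Moderate-concern glands carry the highest droplet load, followed by high,
# then low; stroma is essentially droplet-free.
DEFAULT_LD_FRACTIONS = {"stroma": 0.0, "low": 0.005, "moderate": 0.05, "high": 0.03}
DEFAULT_GLAND_COUNTS = {"low": 4, "moderate": 7, "high": 5}


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing Raman-shift axis in cm^-1."""

    shifts: tuple

    def __post_init__(self):
        arr = np.asarray(self.shifts, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise ValueError("axis needs at least two shifts")
        if not np.all(np.diff(arr) > 0):
            raise ValueError("axis shifts must be strictly increasing")
        object.__setattr__(self, "shifts", tuple(float(s) for s in arr))

    def __len__(self):
        return len(self.shifts)

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.shifts)

    def nearest_index(self, freq: float) -> int:
        """Index of the nearest axis entry; exact ties resolve to the lower
        shift (the first of the two equidistant entries)."""
        arr = self.values
        if freq < arr[0] or freq > arr[-1]:
            raise ValueError(
                f"frequency {freq} cm^-1 outside axis range "
                f"[{arr[0]}, {arr[-1]}]"
            )
        return int(np.argmin(np.abs(arr - freq)))


def make_axis(start: float = 2800.0, stop: float = 3105.0, step: float = 4.0) -> WavenumberAxis:
    """Uniform hyperspectral axis; the default covers 2800–3105 cm^-1 at
    4 cm^-1 resolution (77 bands)."""
    return WavenumberAxis(tuple(np.arange(start, stop + 1e-9, step)))


@dataclass(frozen=True)
class SpectralLibrary:
    """Max-normalized per-class SRS spectra over a common axis.

    Lipid droplets carry the CH2-dominant profile, I(2847) > I(2933);
    the protein-rich classes (stroma, nuclei, epithelium) are CH3-dominant,
    I(2847) < I(2933).
    """

    axis: WavenumberAxis
    class_spectra: dict

    def __post_init__(self):
        for name, spec in self.class_spectra.items():
            spec = np.asarray(spec, dtype=float)
            if spec.shape != (len(self.axis),):
                raise ValueError(f"spectrum {name!r} length mismatch with axis")
            if np.any(spec < 0):
                raise ValueError(f"spectrum {name!r} has negative intensities")

    def spectrum(self, name: str) -> np.ndarray:
        return np.asarray(self.class_spectra[name], dtype=float)

    def ratio(self, name: str, num_shift: float = 2847.0, den_shift: float = 2933.0) -> float:
        s = self.spectrum(name)
        return float(
            s[self.axis.nearest_index(num_shift)] / s[self.axis.nearest_index(den_shift)]
        )

    def ld_ratio_threshold(self) -> float:
        """Midpoint of the lipid and epithelium 2847/2933 ratios — the
        planted decision boundary for droplet segmentation."""
        return 0.5 * (self.ratio("lipid_droplet") + self.ratio("epithelium"))


@dataclass
class LabelMask:
    """H×W integer ground-truth mask using :data:`CLASS_CODES`."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        bad = set(np.unique(self.labels)) - set(CLASS_CODES.values())
        if bad:
            raise ValueError(f"unknown class codes {sorted(bad)}")

    @property
    def shape(self):
        return self.labels.shape

    def area(self, class_name: str) -> int:
        return int(np.count_nonzero(self.labels == CLASS_CODES[class_name]))

    def class_counts(self) -> dict:
        return {name: self.area(name) for name in CLASS_CODES}


@dataclass
class HyperspectralCube:
    """H×W×B nonnegative SRS intensities with a wavenumber axis."""

    values: np.ndarray
    axis: WavenumberAxis
    pixel_size_um: float = 1.0
    depth_um: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or self.values.shape[2] != len(self.axis):
            raise ValueError(
                f"cube shape {self.values.shape} inconsistent with axis of "
                f"length {len(self.axis)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube contains non-finite values")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class BandImage:
    """K named discrete-frequency channels (H×W×K, channels last)."""

    values: np.ndarray
    shifts: tuple
    pixel_size_um: float = 1.0
    depth_um: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or self.values.shape[2] != len(self.shifts):
            raise ValueError("band count must match shift names")
        self.shifts = tuple(float(s) for s in self.shifts)

    @property
    def shape(self):
        return self.values.shape

    def channel(self, shift: float) -> np.ndarray:
        shifts = np.asarray(self.shifts)
        hit = np.nonzero(shifts == float(shift))[0]
        if hit.size == 0:
            raise KeyError(f"no channel named {shift} (have {self.shifts})")
        return self.values[:, :, int(hit[0])]

    def to_chw(self) -> np.ndarray:
        return np.moveaxis(self.values, -1, 0)


@dataclass
class RGBImage:
    """3-channel float image in [0, 1] with a stain-domain tag."""

    values: np.ndarray
    style: str = "FF_HE"  # FF_HE | FFPE_HE | VIRTUAL_FF | VIRTUAL_FFPE

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("RGB image must be H×W×3")

    @property
    def shape(self):
        return self.values.shape


ARTIFACT_KINDS = ("staining", "freezing", "knife_cut", "blurring")


@dataclass(frozen=True)
class ArtifactConfig:
    """Which fresh-frozen preparation artifacts to paint, and how hard."""

    kinds: frozenset = frozenset()
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        kinds = frozenset(self.kinds)
        bad = kinds - set(ARTIFACT_KINDS)
        if bad:
            raise ValueError(f"unknown artifact kinds {sorted(bad)}")
        object.__setattr__(self, "kinds", kinds)


@dataclass
class PhantomSample:
    mask: LabelMask
    cube: HyperspectralCube
    bands: BandImage
    ff_he: RGBImage
    ffpe_he: RGBImage
    grade_class: str
    ld_area_fraction: float
    seed: int
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# spectral library

# (center cm^-1, sigma cm^-1, amplitude) Gaussian components per class.
# 2847: CH2 symmetric stretch (lipid); 2879: CH2 asymmetric; 2933: CH3
# (protein); 2960/2979: protein CH3 asymmetric / CH shoulders; 3062:
# aromatic / =CH.
_PEAK_TABLE = {
    "lipid_droplet": [
        (2847, 12, 1.00), (2879, 12, 0.55), (2933, 14, 0.45),
        (2960, 14, 0.20), (3062, 10, 0.05),
    ],
    "stroma": [
        (2847, 12, 0.45), (2879, 12, 0.50), (2933, 15, 1.00),
        (2960, 13, 0.60), (2979, 12, 0.55), (3062, 10, 0.20),
    ],
    "nuclei": [
        (2847, 12, 0.35), (2879, 12, 0.45), (2933, 15, 1.00),
        (2960, 13, 0.70), (2979, 12, 0.50), (3062, 10, 0.25),
    ],
    "epithelium": [
        (2847, 12, 0.55), (2879, 12, 0.50), (2933, 15, 1.00),
        (2960, 13, 0.60), (2979, 12, 0.45), (3062, 10, 0.20),
    ],
}


def _gaussian_sum(axis: np.ndarray, peaks, rng: np.random.Generator | None) -> np.ndarray:
    spec = np.zeros_like(axis, dtype=float)
    for center, sigma, amp in peaks:
        if rng is not None:
            center = center + rng.uniform(-1.5, 1.5)
            amp = amp * (1.0 + rng.uniform(-0.04, 0.04))
        spec += amp * np.exp(-0.5 * ((axis - center) / sigma) ** 2)
    return spec


def make_spectral_library(seed: int = 0, axis: WavenumberAxis | None = None) -> SpectralLibrary:
    """Build the four-class spectral library as sums of Gaussian peaks with
    small seeded jitter, max-normalized per class."""
    axis = axis or make_axis()
    rng = np.random.default_rng(seed)
    av = axis.values
    spectra = {}
    for name, peaks in _PEAK_TABLE.items():
        spec = _gaussian_sum(av, peaks, rng)
        spectra[name] = spec / spec.max()
    lib = SpectralLibrary(axis=axis, class_spectra=spectra)
    if lib.ratio("lipid_droplet") <= 1.0:
        raise AssertionError("lipid spectrum lost its CH2 dominance")
    for name in ("stroma", "nuclei", "epithelium"):
        if lib.ratio(name) >= 1.0:
            raise AssertionError(f"{name} spectrum lost its CH3 dominance")
    return lib


def extended_library(library: SpectralLibrary) -> SpectralLibrary:
    """Add weak flat spectra for the non-tissue mask classes (background,
    lumen) so a full mask can be rendered."""
    spectra = dict(library.class_spectra)
    b = len(library.axis)
    spectra.setdefault("background", np.full(b, 0.01))
    spectra.setdefault("lumen", np.full(b, 0.03))
    return SpectralLibrary(axis=library.axis, class_spectra=spectra)


# ---------------------------------------------------------------------------
# tissue masks


@dataclass(frozen=True)
class _Gland:
    cy: float
    cx: float
    radius: float
    lumen_frac: float
    grade: str
    nucleus_seed: int


def _sample_glands(rng: np.random.Generator, shape, grade_class: str, count: int):
    h, w = shape
    scale = min(h, w)
    glands = []
    if grade_class == "low":
        r_lo, r_hi, lumen = 0.10, 0.16, 0.55
    elif grade_class == "moderate":
        r_lo, r_hi, lumen = 0.07, 0.11, 0.25
    else:  # high: fused sheets, no lumen
        r_lo, r_hi, lumen = 0.10, 0.17, 0.0
    for _ in range(count):
        radius = scale * rng.uniform(r_lo, r_hi)
        cy = rng.uniform(radius + 2, h - radius - 2) if h > 2 * (radius + 2) else h / 2
        cx = rng.uniform(radius + 2, w - radius - 2) if w > 2 * (radius + 2) else w / 2
        glands.append(
            _Gland(cy, cx, radius, lumen, grade_class, int(rng.integers(0, 2**31 - 1)))
        )
    return glands


def _paint_glands(labels: np.ndarray, glands) -> None:
    h, w = labels.shape
    yy, xx = np.mgrid[0:h, 0:w]
    for g in glands:
        d2 = (yy - g.cy) ** 2 + (xx - g.cx) ** 2
        outer = d2 <= g.radius**2
        labels[outer] = CLASS_CODES["epithelium"]
        if g.lumen_frac > 0:
            lumen_r = g.lumen_frac * g.radius
            labels[d2 <= lumen_r**2] = CLASS_CODES["lumen"]
        # nuclei: small disks sprinkled through the epithelial ring
        nrng = np.random.default_rng(g.nucleus_seed)
        ring_lo = g.lumen_frac * g.radius
        n_nuc = max(4, int(0.5 * g.radius))
        for _ in range(n_nuc):
            ang = nrng.uniform(0, 2 * math.pi)
            rad = nrng.uniform(ring_lo + 1, max(ring_lo + 1.5, g.radius - 1))
            ny, nx = g.cy + rad * math.sin(ang), g.cx + rad * math.cos(ang)
            nr = nrng.uniform(1.0, 2.0)
            nd2 = (yy - ny) ** 2 + (xx - nx) ** 2
            labels[(nd2 <= nr**2) & (labels == CLASS_CODES["epithelium"])] = CLASS_CODES[
                "nucleus"
            ]


def _plant_droplets(labels: np.ndarray, fraction: float, rng: np.random.Generator,
                    radius_range=(1.5, 3.0)) -> float:
    """Carve lipid-droplet disks out of epithelium until the droplet share of
    the original epithelial area (epithelium ∪ droplets) hits ``fraction``.

    Returns the achieved fraction; raises if it cannot be reached.
    """
    epi = CLASS_CODES["epithelium"]
    ld = CLASS_CODES["lipid_droplet"]
    e0 = int(np.count_nonzero(labels == epi))
    if fraction <= 0:
        return 0.0
    if e0 == 0:
        raise ValueError(
            f"ld_area_fraction={fraction} unattainable: no epithelium in mask "
            f"(achievable maximum 0)"
        )
    # a positive request always plants at least one pixel
    target = max(1, int(round(fraction * e0)))
    h, w = labels.shape
    yy, xx = np.mgrid[0:h, 0:w]
    planted = 0
    attempts = 0
    max_attempts = 200 * max(1, target)
    while planted < target and attempts < max_attempts:
        attempts += 1
        iy, ix = rng.integers(0, h), rng.integers(0, w)
        if labels[iy, ix] != epi:
            continue
        r = rng.uniform(*radius_range)
        disk = ((yy - iy) ** 2 + (xx - ix) ** 2 <= r**2) & (labels == epi)
        size = int(np.count_nonzero(disk))
        if size == 0 or planted + size > int(1.02 * target) + 1:
            continue
        labels[disk] = ld
        planted += size
    # top off one pixel at a time so the final count is exact; grow from the
    # droplet boundary (or seed a fresh pixel when the target is tiny)
    while planted < target:
        droplet = labels == ld
        if planted == 0:
            idx = np.flatnonzero(labels == epi)
        else:
            boundary = ndimage.binary_dilation(droplet) & (labels == epi)
            idx = np.flatnonzero(boundary)
            if idx.size == 0:
                idx = np.flatnonzero(labels == epi)
        if idx.size == 0:
            achieved = planted / e0
            raise ValueError(
                f"ld_area_fraction={fraction} unattainable; achieved maximum "
                f"{achieved:.4g}"
            )
        pick = idx[rng.integers(0, idx.size)]
        labels.flat[pick] = ld
        planted += 1
    return planted / e0


def _build_mask(shape, glands, ld_area_fraction: float, paint_seed: int,
                border: int = 2) -> LabelMask:
    h, w = shape
    labels = np.full((h, w), CLASS_CODES["stroma"], dtype=np.uint8)
    labels[:border, :] = labels[-border:, :] = CLASS_CODES["background"]
    labels[:, :border] = labels[:, -border:] = CLASS_CODES["background"]
    _paint_glands(labels, glands)
    if ld_area_fraction > 0:
        _plant_droplets(labels, ld_area_fraction, np.random.default_rng(paint_seed))
    return LabelMask(labels)


def generate_tissue_mask(seed: int, shape=(128, 128), grade_class: str = "low",
                         gland_count: int | None = None,
                         ld_area_fraction: float | None = None) -> LabelMask:
    """Ground-truth mask: stroma background, glands whose architecture tracks
    the clinical-concern class, and lipid droplets planted inside epithelium
    at a controlled area fraction.

    ``low`` renders open-lumen glands, ``moderate`` small crowded lumens, and
    ``high`` fused epithelial sheets without lumens.
    """
    if grade_class not in GRADE_CLASSES:
        raise ValueError(f"grade_class must be one of {GRADE_CLASSES}")
    h, w = shape
    if h < 64 or w < 64:
        raise ValueError("mask shape must be at least 64×64")
    if gland_count is None:
        gland_count = DEFAULT_GLAND_COUNTS[grade_class]
    if ld_area_fraction is None:
        ld_area_fraction = DEFAULT_LD_FRACTIONS[grade_class]
    if not 0 <= ld_area_fraction <= 0.2:
        raise ValueError("ld_area_fraction must lie in [0, 0.2]")
    rng = np.random.default_rng(seed)
    glands = _sample_glands(rng, shape, grade_class, gland_count)
    return _build_mask(shape, glands, ld_area_fraction, paint_seed=seed + 1)


# ---------------------------------------------------------------------------
# forward model: mask -> cube -> bands


def render_cube(mask: LabelMask, library: SpectralLibrary, noise_sd: float = 0.0,
                blur_sigma: float = 0.0, brightness_amp: float = 0.1,
                seed: int = 0, pixel_size_um: float = 1.0,
                depth_um: float = 0.0) -> HyperspectralCube:
    """Render an SRS cube from a label mask.

    Per-pixel spectrum = class spectrum × smooth brightness field, plus
    zero-mean Gaussian noise, optionally spatially blurred, clipped at 0.
    The forward model intentionally preserves band ratios within a class so
    the ratio-threshold droplet statistic sees the planted contrast.
    """
    if noise_sd < 0 or blur_sigma < 0:
        raise ValueError("noise_sd and blur_sigma must be >= 0")
    present = {CLASS_NAMES[c] for c in np.unique(mask.labels)}
    # mask code 3 is "nucleus"; the spectral library names the class "nuclei"
    alias = {"nucleus": "nuclei"}
    lib_name = {n: alias.get(n, n) for n in present}
    missing = {lib_name[n] for n in present} - set(library.class_spectra)
    if missing:
        raise KeyError(f"mask classes missing from library: {sorted(missing)}")
    h, w = mask.shape
    b = len(library.axis)
    rng = np.random.default_rng(seed)
    if brightness_amp > 0:
        rough = rng.standard_normal((h, w))
        smooth = ndimage.gaussian_filter(rough, sigma=8)
        smooth = smooth / max(np.abs(smooth).max(), 1e-12)
        brightness = 1.0 + brightness_amp * smooth
    else:
        brightness = np.ones((h, w))
    values = np.zeros((h, w, b), dtype=float)
    for name in present:
        sel = mask.labels == CLASS_CODES[name]
        values[sel] = library.spectrum(lib_name[name])[None, :]
    values *= brightness[:, :, None]
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    if blur_sigma > 0:
        values = ndimage.gaussian_filter(values, sigma=(blur_sigma, blur_sigma, 0))
    np.clip(values, 0.0, None, out=values)
    return HyperspectralCube(values, library.axis, pixel_size_um, depth_um)


def sample_bands(cube: HyperspectralCube, freqs=DEFAULT_BANDS) -> BandImage:
    """Extract discrete-frequency channels by nearest-band lookup (exact ties
    break toward the lower shift); channel names record the requested
    shifts."""
    idx = [cube.axis.nearest_index(f) for f in freqs]
    values = cube.values[:, :, idx]
    return BandImage(values, tuple(freqs), cube.pixel_size_um, cube.depth_um)


# ---------------------------------------------------------------------------
# H&E rendering

# Per-class base colors (RGB, [0,1]): hematoxylin blue-purple nuclei in
# eosin-pink stroma/epithelium, white lumens.
_HE_PALETTE = {
    "background": (0.97, 0.96, 0.97),
    "stroma": (0.91, 0.70, 0.79),
    "epithelium": (0.80, 0.58, 0.73),
    "nucleus": (0.36, 0.27, 0.56),
    "lumen": (0.96, 0.95, 0.97),
    "lipid_droplet": (0.93, 0.87, 0.92),
}
_FF_CONTRAST = 0.85
_FFPE_CONTRAST = 1.25


def _apply_artifacts(img: np.ndarray, cfg: ArtifactConfig) -> np.ndarray:
    rng = np.random.default_rng(cfg.seed)
    h, w, _ = img.shape
    out = img.copy()
    if "staining" in cfg.kinds:
        amp = cfg.params.get("staining", {}).get("amplitude", 0.25)
        rough = rng.standard_normal((h, w))
        fieldv = ndimage.gaussian_filter(rough, sigma=max(h, w) / 6)
        fieldv = fieldv / max(np.abs(fieldv).max(), 1e-12)
        out *= (1.0 + amp * fieldv)[:, :, None]
    if "freezing" in cfg.kinds:
        p = cfg.params.get("freezing", {})
        n_holes = p.get("n_holes", 3)
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(n_holes):
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            ry = rng.uniform(0.03, 0.08) * h
            rx = rng.uniform(0.03, 0.08) * w
            ang = rng.uniform(0, math.pi)
            ys, xs = yy - cy, xx - cx
            u = ys * math.cos(ang) + xs * math.sin(ang)
            v = -ys * math.sin(ang) + xs * math.cos(ang)
            hole = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
            out[hole] = 0.97
    if "knife_cut" in cfg.kinds:
        p = cfg.params.get("knife_cut", {})
        width = p.get("width", 3.0)
        contrast = p.get("contrast", 0.15)
        ang = rng.uniform(0, math.pi)
        # line through a random interior point, direction ang
        cy, cx = rng.uniform(0.3 * h, 0.7 * h), rng.uniform(0.3 * w, 0.7 * w)
        yy, xx = np.mgrid[0:h, 0:w]
        dist = np.abs(-(yy - cy) * math.sin(ang) + (xx - cx) * math.cos(ang))
        streak = dist <= width / 2
        out[streak] += contrast
    if "blurring" in cfg.kinds:
        p = cfg.params.get("blurring", {})
        sigma = p.get("sigma", 3.0)
        ph = max(8, h // 3)
        pw = max(8, w // 3)
        oy = rng.integers(0, h - ph + 1)
        ox = rng.integers(0, w - pw + 1)
        patch = out[oy : oy + ph, ox : ox + pw]
        out[oy : oy + ph, ox : ox + pw] = ndimage.gaussian_filter(
            patch, sigma=(sigma, sigma, 0)
        )
    return out


def render_he(mask: LabelMask, style: str = "FF_HE",
              artifacts: ArtifactConfig | None = None, seed: int = 0) -> RGBImage:
    """Render an H&E-style image from the mask.

    FFPE renders use a harder contrast stretch than FF (archival processing
    yields crisper, more saturated sections); artifacts model fresh-frozen
    preparation defects and are therefore only valid on FF renders.
    """
    if style not in ("FF_HE", "FFPE_HE"):
        raise ValueError("style must be FF_HE or FFPE_HE")
    if artifacts is not None and artifacts.kinds and style == "FFPE_HE":
        raise ValueError("FFPE renders are defined artifact-free")
    rng = np.random.default_rng(seed)
    h, w = mask.shape
    palette = np.array([_HE_PALETTE[CLASS_NAMES[c]] for c in range(6)])
    base = palette[mask.labels]
    rough = rng.standard_normal((h, w))
    texture = ndimage.gaussian_filter(rough, sigma=2.0)
    texture = 1.0 + 0.08 * texture / max(np.abs(texture).max(), 1e-12)
    base = base * texture[:, :, None]
    contrast = _FF_CONTRAST if style == "FF_HE" else _FFPE_CONTRAST
    img = 0.5 + contrast * (base - 0.5)
    if artifacts is not None and artifacts.kinds:
        img = _apply_artifacts(img, artifacts)
    return RGBImage(np.clip(img, 0.0, 1.0), style)


# ---------------------------------------------------------------------------
# full samples, stacks, datasets


def generate_sample(seed: int, shape=(128, 128), grade_class: str = "low",
                    gland_count: int | None = None,
                    ld_area_fraction: float | None = None,
                    noise_sd: float = 0.01, blur_sigma: float = 0.0,
                    artifacts: ArtifactConfig | None = None,
                    depth_um: float = 0.0,
                    library: SpectralLibrary | None = None) -> PhantomSample:
    """Generate one fully paired phantom sample."""
    if ld_area_fraction is None:
        ld_area_fraction = DEFAULT_LD_FRACTIONS[grade_class]
    mask = generate_tissue_mask(seed, shape, grade_class, gland_count, ld_area_fraction)
    library = library or make_spectral_library(seed)
    cube = render_cube(mask, extended_library(library), noise_sd=noise_sd,
                       blur_sigma=blur_sigma, seed=seed + 2, depth_um=depth_um)
    bands = sample_bands(cube)
    ff = render_he(mask, "FF_HE", artifacts=artifacts, seed=seed + 3)
    ffpe = render_he(mask, "FFPE_HE", seed=seed + 3)
    e0 = mask.area("epithelium") + mask.area("lipid_droplet")
    achieved = mask.area("lipid_droplet") / e0 if e0 else 0.0
    return PhantomSample(mask, cube, bands, ff, ffpe, grade_class, achieved, seed)


def generate_stack(seed: int, depths_um, decorrelation: float = 0.1,
                   shape=(128, 128), grade_class: str = "low",
                   gland_count: int | None = None,
                   ld_area_fraction: float | None = None,
                   noise_sd: float = 0.01,
                   tumor_onset_depth: float | None = None) -> list[PhantomSample]:
    """Multi-depth phantom stack with smoothly evolving morphology.

    Gland centers and radii drift with depth proportionally to
    ``decorrelation`` (0 freezes morphology across planes).  When
    ``tumor_onset_depth`` is set, an extra cohort of high-grade (fused,
    lumen-free) glands appears only at planes at or beyond that depth —
    the scenario where deeper virtual sections reveal tumor missed at the
    surface.
    """
    depths = list(depths_um)
    if not depths:
        raise ValueError("depths_um must be nonempty")
    if any(b < a for a, b in zip(depths, depths[1:])):
        raise ValueError("depths_um must be nondecreasing")
    rng = np.random.default_rng(seed)
    if gland_count is None:
        gland_count = DEFAULT_GLAND_COUNTS[grade_class]
    if ld_area_fraction is None:
        ld_area_fraction = DEFAULT_LD_FRACTIONS[grade_class]
    base_glands = _sample_glands(rng, shape, grade_class, gland_count)
    tumor_glands = []
    if tumor_onset_depth is not None:
        tumor_glands = _sample_glands(rng, shape, "high", max(2, gland_count // 2))
    drift = [
        (rng.uniform(-1, 1), rng.uniform(-1, 1), rng.uniform(-0.02, 0.02))
        for _ in range(len(base_glands) + len(tumor_glands))
    ]
    library = make_spectral_library(seed)
    samples = []
    z0 = depths[0]
    for plane, z in enumerate(depths):
        dz = z - z0
        glands = []
        all_glands = list(base_glands) + list(tumor_glands)
        for gi, (g, (dy, dx, dr)) in enumerate(zip(all_glands, drift)):
            is_tumor = gi >= len(base_glands)
            if is_tumor and (tumor_onset_depth is None or z < tumor_onset_depth):
                continue
            glands.append(
                _Gland(
                    g.cy + decorrelation * dz * dy,
                    g.cx + decorrelation * dz * dx,
                    g.radius * (1.0 + decorrelation * dz * dr),
                    g.lumen_frac,
                    g.grade,
                    g.nucleus_seed,
                )
            )
        mask = _build_mask(shape, glands, ld_area_fraction, paint_seed=seed + 1)
        cube = render_cube(mask, extended_library(library), noise_sd=noise_sd,
                           seed=seed + 2 + plane, depth_um=z)
        bands = sample_bands(cube)
        ff = render_he(mask, "FF_HE", seed=seed + 3)
        ffpe = render_he(mask, "FFPE_HE", seed=seed + 3)
        e0 = mask.area("epithelium") + mask.area("lipid_droplet")
        achieved = mask.area("lipid_droplet") / e0 if e0 else 0.0
        samples.append(
            PhantomSample(
                mask, cube, bands, ff, ffpe, grade_class, achieved, seed,
                meta={
                    "depth_um": z,
                    "n_tumor_glands": sum(1 for g in glands if g.grade == "high"
                                          and grade_class != "high"),
                },
            )
        )
    return samples


def generate_dataset(n: int, config: dict | None = None, out_dir=None) -> dict:
    """Write ``n`` phantom samples plus a JSON manifest to ``out_dir``.

    The manifest records every seed, grade class, achieved droplet fraction
    and file path, so the dataset is fully regenerable.
    """
    from . import io as rio  # deferred: io imports phantom containers

    if n < 1:
        raise ValueError("n must be >= 1")
    config = dict(config or {})
    seed = int(config.get("seed", 0))
    shape = tuple(config.get("shape", (128, 128)))
    noise_sd = float(config.get("noise_sd", 0.01))
    grade_mix = config.get("grade_mix")
    if grade_mix is None:
        grades = [GRADE_CLASSES[i % 3] for i in range(n)]
    else:
        grades = []
        for cls in GRADE_CLASSES:
            grades.extend([cls] * int(grade_mix.get(cls, 0)))
        if len(grades) != n:
            raise ValueError(f"grade_mix totals {len(grades)} but n={n}")
    return rio.write_dataset(out_dir, grades, seed, shape, noise_sd, config)


# ---------------------------------------------------------------------------
# lipid-droplet study cohort


def generate_ld_cohort(seed: int, n_per_class: int = 20,
                       class_fractions: dict | None = None,
                       shape=(96, 96), noise_sd: float = 0.0,
                       jitter: float = 0.3):
    """Phantom cohort for the lipid-droplet density study.

    One single-gland sample per ROI; the ROI covers the epithelial
    compartment (epithelium ∪ droplets) for gland classes and the stromal
    compartment for the stroma class.  Per-ROI planted fractions scatter
    uniformly within ±``jitter`` (relative) of the class mean, mirroring
    intraclass heterogeneity.

    Returns a list of dicts with keys ``bands``, ``roi`` (bool mask),
    ``class``, ``planted_fraction``.
    """
    fractions = dict(DEFAULT_LD_FRACTIONS)
    if class_fractions:
        fractions.update(class_fractions)
    rng = np.random.default_rng(seed)
    library = make_spectral_library(seed)
    ext = extended_library(library)
    cohort = []
    for cls in ("stroma", "low", "moderate", "high"):
        mean_f = fractions[cls]
        for i in range(n_per_class):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            grade = cls if cls in GRADE_CLASSES else "low"
            f = mean_f * rng.uniform(1 - jitter, 1 + jitter) if mean_f > 0 else 0.0
            mask = generate_tissue_mask(sub_seed, shape, grade, gland_count=1,
                                        ld_area_fraction=0.0 if cls == "stroma" else f)
            cube = render_cube(mask, ext, noise_sd=noise_sd, seed=sub_seed + 1)
            bands = sample_bands(cube)
            if cls == "stroma":
                roi = mask.labels == CLASS_CODES["stroma"]
            else:
                roi = (mask.labels == CLASS_CODES["epithelium"]) | (
                    mask.labels == CLASS_CODES["lipid_droplet"]
                )
            ld_px = int(np.count_nonzero(mask.labels[roi] == CLASS_CODES["lipid_droplet"]))
            planted = ld_px / max(int(np.count_nonzero(roi)), 1)
            cohort.append(
                {"bands": bands, "roi": roi, "class": cls, "planted_fraction": planted}
            )
    return cohort
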