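"""On-disk formats and run configuration.

Hyperspectral cubes and band images travel as multi-page TIFF (one page per
band, ascending wavenumber) with a JSON sidecar recording the shifts and
spatial metadata; RGB images are 8-bit PNG; masks are single-page 8-bit PNG
using the documented class codes.  All writes are atomic (temp file +
rename) so interrupted runs never leave half-written artifacts.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image

from .phantom import (
    BandImage,
    HyperspectralCube,
    LabelMask,
    RGBImage,
    WavenumberAxis,
    generate_sample,
)

__all__ = [
    "atomic_write_bytes",
    "write_cube",
    "read_cube",
    "write_rgb",
    "read_rgb",
    "write_mask",
    "read_mask",
    "write_json",
    "read_json",
    "load_config",
    "resolve_config",
    "write_dataset",
]

_CONFIG_SECTIONS = {"phantom", "spectra", "train", "ldquant", "survey"}
_CONFIG_GLOBALS = {"seed", "out_dir", "desk_scale"}


def atomic_write_bytes(path, payload: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(payload)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def write_cube(path, image: HyperspectralCube | BandImage) -> None:
    """Write a cube or band image as multi-page float32 TIFF + JSON sidecar."""
    if isinstance(image, HyperspectralCube):
        shifts = list(image.axis.shifts)
        kind = "cube"
    elif isinstance(image, BandImage):
        shifts = list(image.shifts)
        kind = "bands"
    else:
        raise TypeError(f"cannot write {type(image).__name__}")
    pages = np.moveaxis(image.values.astype(np.float32), -1, 0)
    import io as _io

    buf = _io.BytesIO()
    tifffile.imwrite(buf, pages, photometric="minisblack")
    atomic_write_bytes(path, buf.getvalue())
    sidecar = {
        "kind": kind,
        "shifts_cm1": shifts,
        "pixel_size_um": image.pixel_size_um,
        "depth_um": image.depth_um,
    }
    atomic_write_bytes(_sidecar_path(path),
                       json.dumps(sidecar, indent=1).encode())


def read_cube(path) -> HyperspectralCube | BandImage:
    """Read a multi-page TIFF + sidecar back into its container; the page
    count must match the sidecar shifts."""
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing band-metadata sidecar {sidecar_file}")
    with open(sidecar_file) as fh:
        sidecar = json.load(fh)
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    shifts = sidecar["shifts_cm1"]
    if pages.shape[0] != len(shifts):
        raise ValueError(
            f"TIFF has {pages.shape[0]} pages but sidecar lists "
            f"{len(shifts)} shifts"
        )
    values = np.moveaxis(pages, 0, -1)
    px = float(sidecar.get("pixel_size_um", 1.0))
    z = float(sidecar.get("depth_um", 0.0))
    if sidecar.get("kind") == "cube":
        return HyperspectralCube(values, WavenumberAxis(tuple(shifts)), px, z)
    return BandImage(values, tuple(shifts), px, z)


def write_rgb(path, image: RGBImage) -> None:
    arr = np.clip(np.asarray(image.values) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    import io as _io

    buf = _io.BytesIO()
    Image.fromarray(arr).save(buf, format="PNG")
    atomic_write_bytes(path, buf.getvalue())


def read_rgb(path, style: str = "FF_HE") -> RGBImage:
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float32) / 255.0
    return RGBImage(arr, style)


def write_mask(path, mask: LabelMask) -> None:
    import io as _io

    buf = _io.BytesIO()
    Image.fromarray(mask.labels.astype(np.uint8)).save(buf, format="PNG")
    atomic_write_bytes(path, buf.getvalue())


def read_mask(path) -> LabelMask:
    return LabelMask(np.asarray(Image.open(path), dtype=np.uint8))


def write_json(path, payload) -> None:
    atomic_write_bytes(path, json.dumps(payload, indent=1, sort_keys=True).encode())


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# configuration


def load_config(path) -> dict:
    """Load a YAML/JSON run configuration, rejecting unknown top-level keys."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(cfg) - _CONFIG_SECTIONS - _CONFIG_GLOBALS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def resolve_config(cfg: dict, out_dir) -> dict:
    """Fill defaults and persist the resolved config next to the outputs."""
    resolved = {"seed": 0, "desk_scale": True}
    resolved.update(cfg or {})
    resolved["out_dir"] = str(out_dir)
    write_json(Path(out_dir) / "resolved_config.json", resolved)
    return resolved


# ---------------------------------------------------------------------------
# dataset writer (called from phantom.generate_dataset)


def write_dataset(out_dir, grades, seed: int, shape, noise_sd: float,
                  config: dict) -> dict:
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory {out_dir} is not writable")
    entries = []
    for i, grade in enumerate(grades):
        sample_seed = seed + 1000 * i
        sample = generate_sample(sample_seed, shape=shape, grade_class=grade,
                                 noise_sd=noise_sd)
        stem = f"sample_{i:03d}"
        write_cube(out_dir / f"{stem}_cube.tif", sample.cube)
        write_cube(out_dir / f"{stem}_bands.tif", sample.bands)
        write_rgb(out_dir / f"{stem}_ff.png", sample.ff_he)
        write_rgb(out_dir / f"{stem}_ffpe.png", sample.ffpe_he)
        write_mask(out_dir / f"{stem}_mask.png", sample.mask)
        entries.append({
            "stem": stem,
            "seed": sample_seed,
            "grade_class": grade,
            "ld_area_fraction": sample.ld_area_fraction,
            "files": {
                "cube": f"{stem}_cube.tif",
                "bands": f"{stem}_bands.tif",
                "ff_he": f"{stem}_ff.png",
                "ffpe_he": f"{stem}_ffpe.png",
                "mask": f"{stem}_mask.png",
            },
        })
    manifest = {
        "seed": seed,
        "shape": list(shape),
        "noise_sd": noise_sd,
        "n": len(grades),
        "class_counts": {g: grades.count(g) for g in set(grades)},
        "samples": entries,
        "config": {k: v for k, v in config.items() if k != "out_dir"},
    }
    write_json(out_dir / "manifest.json", manifest)
    return manifest
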