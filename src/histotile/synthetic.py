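"""Procedural color-texture tile generator.

Generates class-per-folder tile datasets with the same layout as the real
colorectal-histology tile collections, so the whole pipeline can be
exercised without downloading anything.  Each class combines a
class-specific base hue with a class-specific periodic pattern (stripes,
checks, blobs or speckle at a class-specific frequency and orientation)
plus additive Gaussian pixel noise; the last class is near-uniform bright,
emulating the background/empty-slide class present in both real datasets.

The textures are parametric rather than realistic: difficulty is tuned via
``noise_sd`` and the hue spacing, which is what the test surface needs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage import color

from .manifest import DatasetManifest, scan_dataset

_PATTERNS = ("stripes", "checks", "blobs", "speckle")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic tile dataset."""

    n_classes: int = 8
    tiles_per_class: int = 625
    tile_size: tuple[int, int] = (150, 150)
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.n_classes <= 16):
            raise ValueError("n_classes must lie in [2, 16]")
        if self.tiles_per_class < 3:
            raise ValueError("tiles_per_class must be >= 3")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def class_name(self, class_id: int) -> str:
        return f"class_{class_id:02d}"


def _pattern_field(
    kind: str, shape: tuple[int, int], freq: float, theta: float, rng: np.random.Generator
) -> np.ndarray:
    """A texture field in [0, 1]; phase/realization jitter comes from ``rng``."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    u = (xx * np.cos(theta) + yy * np.sin(theta)) / max(h, w)
    v = (-xx * np.sin(theta) + yy * np.cos(theta)) / max(h, w)
    if kind == "stripes":
        phase = rng.uniform(0, 2 * np.pi)
        return 0.5 + 0.5 * np.sin(2 * np.pi * freq * u + phase)
    if kind == "checks":
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
        field = np.sin(2 * np.pi * freq * u + p1) * np.sin(2 * np.pi * freq * v + p2)
        return (field > 0).astype(float)
    if kind == "blobs":
        noise = rng.standard_normal(shape)
        smooth = gaussian_filter(noise, sigma=max(h, w) / (4.0 * freq), mode="wrap")
        lo, hi = smooth.min(), smooth.max()
        return (smooth - lo) / (hi - lo + 1e-12)
    if kind == "speckle":
        density = min(0.5, 0.05 * freq)
        field = (rng.random(shape) < density).astype(float)
        return np.clip(gaussian_filter(field, sigma=1.0) * 3.0, 0.0, 1.0)
    raise ValueError(f"unknown pattern kind {kind!r}")


def generate_class_texture(
    class_id: int, spec: SyntheticSpec, draw_index: int
) -> np.ndarray:
    """One tile of one class as an ``H x W x 3`` uint8 RGB array.

    Deterministic in ``(spec.seed, class_id, draw_index)``.
    """
    if not (0 <= class_id < spec.n_classes):
        raise ValueError(
            f"class_id {class_id} out of range for {spec.n_classes} classes"
        )
    rng = np.random.default_rng([spec.seed, class_id, draw_index])
    h, w = spec.tile_size
    base_hue = (class_id / spec.n_classes + 0.03) % 1.0
    if class_id == spec.n_classes - 1:
        # background class: near-uniform bright, almost unsaturated
        hsv = np.empty((h, w, 3))
        hsv[..., 0] = base_hue
        hsv[..., 1] = 0.04
        hsv[..., 2] = 0.93 + 0.02 * rng.random((h, w))
    else:
        kind = _PATTERNS[class_id % len(_PATTERNS)]
        freq = 3.0 + 1.5 * class_id
        theta = np.pi * class_id / max(1, spec.n_classes)
        field = _pattern_field(kind, (h, w), freq, theta, rng)
        hsv = np.empty((h, w, 3))
        hsv[..., 0] = (base_hue + 0.04 * (field - 0.5)) % 1.0
        hsv[..., 1] = 0.55 + 0.25 * field
        hsv[..., 2] = 0.35 + 0.45 * field
    rgb = color.hsv2rgb(hsv) * 255.0
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def generate_arrays(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """All tiles in memory: ``(tiles [n, H, W, 3] uint8, class ids [n])``."""
    tiles = np.empty(
        (spec.n_classes * spec.tiles_per_class, *spec.tile_size, 3), dtype=np.uint8
    )
    labels = np.empty(spec.n_classes * spec.tiles_per_class, dtype=int)
    i = 0
    for c in range(spec.n_classes):
        for d in range(spec.tiles_per_class):
            tiles[i] = generate_class_texture(c, spec, d)
            labels[i] = c
            i += 1
    return tiles, labels


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path) -> DatasetManifest:
    """Write the dataset as a class-per-folder PNG tree and return its manifest."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    for c in range(spec.n_classes):
        class_dir = out / spec.class_name(c)
        class_dir.mkdir(exist_ok=True)
        for d in range(spec.tiles_per_class):
            tile = generate_class_texture(c, spec, d)
            Image.fromarray(tile).save(class_dir / f"tile_{d:05d}.png")
    return scan_dataset(out)
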