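"""RGB -> HSV conversion and resizing of tiles into network inputs.

H&E-stained tissue differs between classes mainly in hue and saturation,
while staining intensity varies between slides; working in HSV separates
chromatic information from brightness.  All three HSV channels are kept on
a common [0, 1] scale and fed to the network channels-first.
"""

from __future__ import annotations

import numpy as np
from skimage import color
from skimage.transform import resize


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """Convert an ``H x W x 3`` uint8 RGB tile to float HSV.

    Standard hexcone conversion: hue on [0, 1) (red = 0), saturation and
    value on [0, 1].  Achromatic pixels (saturation 0) get hue 0.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB array, got shape {arr.shape}")
    hsv = color.rgb2hsv(arr)
    # rgb2hsv maps pure red to hue 1.0 in some edge paths; fold onto [0, 1)
    hsv[..., 0] = np.where(hsv[..., 0] >= 1.0, 0.0, hsv[..., 0])
    hsv[..., 0] = np.where(hsv[..., 1] == 0.0, 0.0, hsv[..., 0])
    return hsv


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    """Inverse hexcone conversion back to uint8 RGB (for round-trip checks)."""
    rgb = color.hsv2rgb(np.asarray(hsv, dtype=float))
    return np.clip(np.rint(rgb * 255.0), 0, 255).astype(np.uint8)


def normalize_tile(hsv: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """Bilinear-resize an HSV tile and lay it out channels-first.

    Returns a ``3 x H' x W'`` float32 array with values in [0, 1].
    """
    th, tw = target_size
    if th < 1 or tw < 1:
        raise ValueError(f"target size must be positive, got {target_size}")
    arr = np.asarray(hsv, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 HSV array, got shape {arr.shape}")
    if arr.shape[:2] != (th, tw):
        arr = resize(
            arr, (th, tw), order=1, mode="edge", anti_aliasing=False,
            preserve_range=True,
        )
    out = np.clip(arr, 0.0, 1.0).transpose(2, 0, 1)
    return np.ascontiguousarray(out, dtype=np.float32)


def prepare_tile(rgb: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """RGB uint8 tile -> channels-first HSV model input in one step."""
    return normalize_tile(rgb_to_hsv(rgb), target_size)
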