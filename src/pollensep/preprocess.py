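"""Image input/output and color-space conversion.

Stained pollen slides are photographed in RGB, but the purple methyl-green
stain is most cleanly separated from the pale background in the CIELAB
space, whose a* axis (green–red) carries almost all of the stain contrast.
All downstream segmentation and texture measurement therefore works on
L*a*b* planes kept on their native scales (L in [0, 100], a and b roughly
in [-128, 127]).
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image
from skimage import color

__all__ = ["read_image", "write_image", "rgb_to_lab", "save_lab", "load_lab"]


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read an 8-bit PNG or BMP image as an H×W×3 uint8 array.

    Grayscale sources are replicated across the three channels; an alpha
    channel, if present, is dropped.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        If the file cannot be decoded as an image.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("RGB"))
    except (OSError, SyntaxError) as exc:
        raise ValueError(f"cannot decode image file {path}: {exc}") from exc
    return arr.astype(np.uint8)


def write_image(path: str | os.PathLike, pixels: np.ndarray) -> None:
    """Write an H×W (grayscale/bool) or H×W×3 uint8 array as PNG or BMP."""
    arr = np.asarray(pixels)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    Image.fromarray(arr.astype(np.uint8)).save(os.fspath(path))


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an H×W×3 8-bit sRGB image to CIELAB (D65), float64 H×W×3.

    Channel 0 is L* in [0, 100]; channels 1 and 2 are a* and b* on their
    native scales (no 8-bit requantization), so color distances downstream
    are in true Lab units.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected H×W×3 RGB array, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    return color.rgb2lab(arr)


def save_lab(path: str | os.PathLike, lab: np.ndarray) -> None:
    """Persist a real-valued Lab image as a compressed .npz container."""
    lab = np.asarray(lab, dtype=np.float64)
    np.savez_compressed(os.fspath(path), L=lab[..., 0], a=lab[..., 1], b=lab[..., 2])


def load_lab(path: str | os.PathLike) -> np.ndarray:
    """Load a Lab image written by :func:`save_lab`."""
    with np.load(os.fspath(path)) as data:
        return np.stack([data["L"], data["a"], data["b"]], axis=-1)
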