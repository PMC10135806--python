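"""Image preprocessing: grayscale conversion, resizing, normalization.

The network consumes single-channel 512x512 images with intensities in
[0, 1].  Microphotographs (4:3, e.g. 2592x1944 or 1600x1200) are stretched
directly to the square target with bilinear interpolation; label masks
follow with nearest-neighbor interpolation so no fractional labels appear.

Resampling uses the half-pixel-center convention: output pixel ``i`` samples
input coordinate ``(i + 0.5) * scale - 0.5``, clamped to the frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .annotations import LabelMask

#: ITU-R BT.601 luminance weights (R, G, B).
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

NETWORK_INPUT_SIZE = 512


@dataclass
class ImageSample:
    """A grayscale image in [0, 1] with an optional aligned label mask."""

    image: np.ndarray
    mask: LabelMask | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim != 2:
            raise ValueError("image must be a 2-D grayscale array")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image intensities must lie in [0, 1]")
        if self.mask is not None and self.mask.grid.shape != self.image.shape:
            raise ValueError(
                f"mask shape {self.mask.grid.shape} does not match image "
                f"shape {self.image.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


def to_grayscale(image: np.ndarray,
                 weights: tuple[float, float, float] = LUMA_WEIGHTS) -> np.ndarray:
    """Convert an RGB image to single-channel luminance in [0, 1].

    Accepts ``(H, W, 3)`` arrays, either 8-bit (0-255, divided by 255) or
    float in [0, 1].  A 2-D array is already grayscale and passes through
    unchanged (after 8-bit scaling if needed).
    """
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer):
        image = image.astype(np.float32) / 255.0
    else:
        image = image.astype(np.float32)
    if image.ndim == 2:
        return image
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(
            f"expected an (H, W, 3) RGB or (H, W) grayscale image, got shape "
            f"{image.shape}"
        )
    w = np.asarray(weights, dtype=np.float32)
    return image @ w


def _resample_coords(in_size: int, out_size: int) -> np.ndarray:
    scale = in_size / out_size
    coords = (np.arange(out_size) + 0.5) * scale - 0.5
    return np.clip(coords, 0, in_size - 1)


def _resample(arr: np.ndarray, target: tuple[int, int], order: int) -> np.ndarray:
    h, w = arr.shape
    th, tw = target
    rr = _resample_coords(h, th)
    cc = _resample_coords(w, tw)
    grid = np.meshgrid(rr, cc, indexing="ij")
    return ndimage.map_coordinates(arr, grid, order=order, mode="nearest")


def resize_image(image: np.ndarray, target: int = NETWORK_INPUT_SIZE) -> np.ndarray:
    """Bilinearly resize a grayscale image to ``target x target`` (stretch)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 1:
        raise ValueError("expected a non-empty 2-D grayscale image")
    if image.shape == (target, target):
        return image.astype(np.float32)
    return _resample(image, (target, target), order=1).astype(np.float32)


def resize_mask(mask: LabelMask | np.ndarray,
                target: int = NETWORK_INPUT_SIZE) -> LabelMask:
    """Resize a label mask with nearest-neighbor interpolation.

    Nearest-neighbor guarantees the output label set is a subset of the
    input's — interpolation can never invent a class.
    """
    grid = mask.grid if isinstance(mask, LabelMask) else np.asarray(mask)
    LabelMask(grid)
    if grid.shape == (target, target):
        return LabelMask(grid.copy())
    out = _resample(grid.astype(np.float64), (target, target), order=0)
    return LabelMask(np.rint(out).astype(np.uint8))


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG file as a grayscale [0, 1] array."""
    from PIL import Image

    arr = np.asarray(Image.open(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., :3]  # drop alpha
    return to_grayscale(arr)


def prepare_sample(image: np.ndarray, mask: LabelMask | None = None,
                   target: int = NETWORK_INPUT_SIZE,
                   sample_id: str = "") -> ImageSample:
    """Full preprocessing: grayscale, resize, and mask alignment."""
    gray = to_grayscale(image)
    resized = np.clip(resize_image(gray, target), 0.0, 1.0)
    rmask = resize_mask(mask, target) if mask is not None else None
    return ImageSample(resized, rmask, sample_id)
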