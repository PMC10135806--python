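"""Joint image+mask stochastic augmentation.

Each training sample is perturbed on the fly by horizontal/vertical flips,
90-degree rotations, zoom in [0.8, 1.2] and shear up to 0.2 rad, with the
image interpolated bilinearly and the mask nearest-neighbor under the SAME
geometric transform so the pair stays registered.  Flips and rotations are
exact pixel permutations; zoom and shear go through a single affine resample
about the image center (edge replication fills the image, background fills
the mask).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

from .annotations import LabelMask
from .preprocess import ImageSample

ZOOM_RANGE = (0.8, 1.2)
SHEAR_MAX = 0.2  # radians


@dataclass(frozen=True)
class AugmentationParams:
    h_flip: bool = False
    v_flip: bool = False
    rot90_k: int = 0
    zoom: float = 1.0
    shear_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.rot90_k not in (0, 1, 2, 3):
            raise ValueError("rot90_k must be in {0, 1, 2, 3}")
        if not ZOOM_RANGE[0] <= self.zoom <= ZOOM_RANGE[1]:
            raise ValueError(f"zoom {self.zoom} outside {ZOOM_RANGE}")
        if abs(self.shear_rad) > SHEAR_MAX:
            raise ValueError(f"|shear_rad| must be <= {SHEAR_MAX}")

    def to_dict(self) -> dict:
        return asdict(self)


def sample_params(rng: np.random.Generator) -> AugmentationParams:
    """Draw one augmentation: flips Bernoulli(1/2), rotation uniform on
    {0..3} quarter turns, zoom uniform on [0.8, 1.2], shear uniform on
    [-0.2, 0.2] rad.  Deterministic given the generator state."""
    return AugmentationParams(
        h_flip=bool(rng.random() < 0.5),
        v_flip=bool(rng.random() < 0.5),
        rot90_k=int(rng.integers(0, 4)),
        zoom=float(rng.uniform(*ZOOM_RANGE)),
        shear_rad=float(rng.uniform(-SHEAR_MAX, SHEAR_MAX)),
    )


def _affine_matrix(params: AugmentationParams, shape: tuple[int, int]) -> np.ndarray:
    """Inverse (output->input) affine map in (row, col) coordinates for the
    zoom+shear part, about the image center."""
    z = params.zoom
    s = math.tan(params.shear_rad)
    # forward: col' = z * (col + s * row_centered), row' = z * row  (centered)
    fwd = np.array([[z, 0.0], [z * s, z]])  # maps (row, col) -> (row', col')
    inv = np.linalg.inv(fwd)
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    offset = center - inv @ center
    return inv, offset


def _warp(arr: np.ndarray, params: AugmentationParams, order: int,
          mode: str, cval: float = 0.0) -> np.ndarray:
    out = arr
    if params.h_flip:
        out = out[:, ::-1]
    if params.v_flip:
        out = out[::-1, :]
    if params.rot90_k:
        out = np.rot90(out, params.rot90_k)
    if params.zoom != 1.0 or params.shear_rad != 0.0:
        inv, offset = _affine_matrix(params, out.shape)
        out = ndimage.affine_transform(
            np.ascontiguousarray(out, dtype=np.float64), inv, offset=offset,
            order=order, mode=mode, cval=cval, prefilter=False,
        )
    return np.ascontiguousarray(out)


def apply(sample: ImageSample, params: AugmentationParams) -> ImageSample:
    """Apply one augmentation jointly to an image and its mask.

    The image uses bilinear interpolation with nearest-edge replication
    outside the frame; the mask uses nearest-neighbor with background fill.
    Output dimensions equal input dimensions; square images only (90-degree
    rotation preserves shape).
    """
    img = sample.image
    if img.shape[0] != img.shape[1] and params.rot90_k % 2 == 1:
        raise ValueError("90/270-degree rotation requires a square image")
    if sample.mask is not None and sample.mask.grid.shape != img.shape:
        raise ValueError("image and mask dimensions differ")
    out_img = np.clip(_warp(img, params, order=1, mode="nearest"), 0.0, 1.0)
    out_mask = None
    if sample.mask is not None:
        warped = _warp(sample.mask.grid, params, order=0, mode="constant",
                       cval=0.0)
        out_mask = LabelMask(np.rint(warped).astype(np.uint8))
    return ImageSample(out_img.astype(np.float32), out_mask, sample.sample_id)


def augment(sample: ImageSample, rng: np.random.Generator) -> ImageSample:
    """Sample parameters and apply them — the per-epoch training transform."""
    return apply(sample, sample_params(rng))
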