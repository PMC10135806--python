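"""Synthetic osteon-like microphotographs with exact ground truth.

Real cortical-bone microphotographs show crowded annular secondary osteons
(concentric lamellae around a dark Haversian canal), irregular arc- or
crescent-shaped remnants of older osteons partially removed by later
remodeling, and a textured interstitial background.  The generator emulates
those features geometrically: intact osteons are wobbly ellipses rendered
with sinusoidal lamellar rings and a dark central canal, fragments are
annular-sector (crescent) polygons, and the background is low-frequency
texture with faint streaks plus Gaussian noise.

Scenes are built polygon-first: structures are placed as polygons, the
label mask is produced by the SAME rasterizer used for real annotations
(fragment first, intact on top), and the image is rendered last — so the
ground truth is exact by construction and the emitted VIA JSON reproduces
each mask bit-exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .annotations import (
    AnnotationSet,
    LabelMask,
    PolygonRegion,
    points_in_polygon,
    rasterize_mask,
    write_mask_png,
    write_via_annotations,
)
from .preprocess import ImageSample


@dataclass
class SyntheticConfig:
    """Scene parameters.  Ranges are inclusive low/high bounds."""

    image_size: int = 256
    n_intact: tuple[int, int] = (4, 12)
    n_fragment: tuple[int, int] = (3, 10)
    osteon_radius: tuple[float, float] = (12.0, 32.0)
    canal_radius_fraction: tuple[float, float] = (0.15, 0.3)
    fragment_arc: tuple[float, float] = (1.0, 4.0)   # radians
    overlap_probability: float = 0.6
    lamellar_contrast: float = 0.12
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        for name in ("n_intact", "n_fragment", "osteon_radius",
                     "canal_radius_fraction", "fragment_arc"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range not ordered: ({lo}, {hi})")
        if not 0.0 <= self.overlap_probability <= 1.0:
            raise ValueError("overlap_probability must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Placement:
    """One placed structure, for area accounting and rendering."""

    kind: str                 # "intact" | "fragment"
    center: tuple[float, float]
    radius_a: float
    radius_b: float
    angle: float
    canal_fraction: float = 0.0
    arc: float = 0.0
    inner_fraction: float = 0.0


@dataclass
class Scene:
    sample: ImageSample
    annotation: AnnotationSet
    placements: list[Placement] = field(default_factory=list)


def _ellipse_polygon(rng, cx, cy, a, b, angle, n_vertices=48, wobble=0.06):
    """Closed wobbly ellipse contour (a simple polygon)."""
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    # smooth radial wobble from a few low-order harmonics
    r_mod = np.ones_like(t)
    for harmonic in (2, 3, 5):
        r_mod += wobble / harmonic * rng.normal() * np.sin(
            harmonic * t + rng.uniform(0, 2 * np.pi)
        )
    x0 = a * r_mod * np.cos(t)
    y0 = b * r_mod * np.sin(t)
    ca, sa = np.cos(angle), np.sin(angle)
    return np.column_stack([cx + ca * x0 - sa * y0, cy + sa * x0 + ca * y0])


def _crescent_polygon(rng, cx, cy, r_out, inner_frac, arc, angle, n=24):
    """Annular-sector (crescent) polygon: outer arc plus reversed inner arc."""
    t = np.linspace(-arc / 2, arc / 2, n) + angle
    r_in = r_out * inner_frac
    outer = np.column_stack([cx + r_out * np.cos(t), cy + r_out * np.sin(t)])
    inner = np.column_stack([cx + r_in * np.cos(t[::-1]),
                             cy + r_in * np.sin(t[::-1])])
    return np.vstack([outer, inner])


def _build_scene(config: SyntheticConfig, rng: np.random.Generator,
                 sample_id: str = "scene") -> Scene:
    size = config.image_size
    n_int = int(rng.integers(config.n_intact[0], config.n_intact[1] + 1))
    n_frag = int(rng.integers(config.n_fragment[0], config.n_fragment[1] + 1))

    placements: list[Placement] = []
    regions: list[PolygonRegion] = []

    # intact osteons: wobbly ellipses, centers anywhere in frame (border
    # clipping mimics frame-cut osteons)
    for _ in range(n_int):
        a = rng.uniform(*config.osteon_radius)
        b = a * rng.uniform(0.7, 1.0)
        cx, cy = rng.uniform(0, size, size=2)
        angle = rng.uniform(0, np.pi)
        canal = rng.uniform(*config.canal_radius_fraction)
        verts = _ellipse_polygon(rng, cx, cy, a, b, angle)
        regions.append(PolygonRegion(verts, "intact", len(regions)))
        placements.append(Placement("intact", (cx, cy), a, b, angle,
                                    canal_fraction=canal))

    # fragments: crescents, preferentially abutting an existing structure
    for _ in range(n_frag):
        r = rng.uniform(*config.osteon_radius)
        if placements and rng.random() < config.overlap_probability:
            host = placements[int(rng.integers(len(placements)))]
            direction = rng.uniform(0, 2 * np.pi)
            dist = host.radius_a + 0.4 * r
            cx = host.center[0] + dist * np.cos(direction)
            cy = host.center[1] + dist * np.sin(direction)
        else:
            cx, cy = rng.uniform(0, size, size=2)
        arc = rng.uniform(*config.fragment_arc)
        inner = rng.uniform(0.4, 0.75)
        angle = rng.uniform(0, 2 * np.pi)
        verts = _crescent_polygon(rng, cx, cy, r, inner, arc, angle)
        regions.append(PolygonRegion(verts, "fragment", len(regions)))
        placements.append(Placement("fragment", (cx, cy), r, r, angle,
                                    arc=arc, inner_fraction=inner))

    ann = AnnotationSet(f"{sample_id}.png", size, size, regions)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate polygons cannot occur here
        mask = rasterize_mask(ann)
    image = _render_image(config, rng, placements, regions)
    return Scene(ImageSample(image, mask, sample_id), ann, placements)


def _structure_pixels(region: PolygonRegion, size: int):
    """(rows, cols) of pixels inside one structure polygon, frame-clipped."""
    v = region.vertices
    c0 = max(int(np.floor(v[:, 0].min() - 0.5)), 0)
    c1 = min(int(np.ceil(v[:, 0].max() + 0.5)), size - 1)
    r0 = max(int(np.floor(v[:, 1].min() - 0.5)), 0)
    r1 = min(int(np.ceil(v[:, 1].max() + 0.5)), size - 1)
    if c0 > c1 or r0 > r1:
        return np.empty(0, int), np.empty(0, int)
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    inside = points_in_polygon(cols[None, :] + 0.5, rows[:, None] + 0.5, v)
    rr, cc = np.nonzero(inside)
    return rows[rr], cols[cc]


def _render_image(config: SyntheticConfig, rng, placements, regions):
    size = config.image_size
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64) + 0.5

    # interstitial background: smooth blotches + faint lamellar streaks
    blotch = ndimage.gaussian_filter(rng.normal(0, 1, (size, size)), size / 16)
    bstd = blotch.std() or 1.0
    streak_angle = rng.uniform(0, np.pi)
    streaks = np.sin(
        2 * np.pi * (xx * np.cos(streak_angle) + yy * np.sin(streak_angle))
        / rng.uniform(12, 24)
    )
    image = 0.55 + 0.08 * blotch / bstd + 0.03 * streaks

    order = [i for i, p in enumerate(placements) if p.kind == "fragment"]
    order += [i for i, p in enumerate(placements) if p.kind == "intact"]
    for i in order:
        p, reg = placements[i], regions[i]
        rr, cc = _structure_pixels(reg, size)
        if rr.size == 0:
            continue
        dx = cc + 0.5 - p.center[0]
        dy = rr + 0.5 - p.center[1]
        ca, sa = np.cos(p.angle), np.sin(p.angle)
        u = (ca * dx + sa * dy) / p.radius_a
        w = (-sa * dx + ca * dy) / p.radius_b
        rho = np.sqrt(u * u + w * w)
        n_rings = max(3.0, p.radius_a / 4.0)
        phase = rng.uniform(0, 2 * np.pi)
        lam = config.lamellar_contrast * np.sin(2 * np.pi * n_rings * rho + phase)
        if p.kind == "intact":
            image[rr, cc] = 0.62 + lam * (1.0 - 0.5 * rho)
            canal = rho <= p.canal_fraction
            image[rr[canal], cc[canal]] = 0.12 + 0.03 * rng.normal()
        else:
            image[rr, cc] = 0.45 + lam

    image += rng.normal(0, config.noise_sd, (size, size))
    return np.clip(image, 0.0, 1.0).astype(np.float32)


def generate_scene(config: SyntheticConfig | None = None,
                   rng: np.random.Generator | int | None = None,
                   sample_id: str = "scene") -> ImageSample:
    """Generate one synthetic scene (image plus exact label mask)."""
    return generate_scene_details(config, rng, sample_id).sample


def generate_scene_details(config: SyntheticConfig | None = None,
                           rng: np.random.Generator | int | None = None,
                           sample_id: str = "scene") -> Scene:
    """As :func:`generate_scene`, also returning the generating polygons and
    the placement log (centers, radii) for area accounting."""
    config = config or SyntheticConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    return _build_scene(config, rng, sample_id)


def generate_samples(n: int, config: SyntheticConfig | None = None,
                     seed: int = 0) -> list[ImageSample]:
    """Generate ``n`` independent scenes with per-scene derived seeds."""
    config = config or SyntheticConfig()
    children = np.random.SeedSequence(seed).spawn(n)
    return [
        generate_scene(config, np.random.default_rng(c), f"scene_{i:03d}")
        for i, c in enumerate(children)
    ]


def generate_dataset(n_images: int, config: SyntheticConfig | None = None,
                     seed: int = 0, out_dir=None):
    """Write a synthetic dataset to disk and return its manifest.

    Emits per scene an 8-bit grayscale image PNG and an indexed mask PNG, a
    single VIA-format JSON of the generating polygons (rasterizing it
    reproduces every mask bit-exactly), and a manifest CSV with per-class
    pixel counts.
    """
    import pandas as pd
    from PIL import Image

    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    config = config or SyntheticConfig()
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    children = np.random.SeedSequence(seed).spawn(n_images)
    rows, annotations = [], []
    for i, child in enumerate(children):
        sid = f"scene_{i:03d}"
        scene = generate_scene_details(config, np.random.default_rng(child), sid)
        img8 = np.rint(scene.sample.image * 255).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(out / "images" / f"{sid}.png")
        write_mask_png(scene.sample.mask, out / "masks" / f"{sid}.png")
        annotations.append(scene.annotation)
        counts = scene.sample.mask.class_counts()
        rows.append({
            "id": sid, "seed": seed, "n_regions": len(scene.annotation.regions),
            "background_px": int(counts[0]), "fragment_px": int(counts[1]),
            "intact_px": int(counts[2]),
        })
    write_via_annotations(annotations, out / "via_annotations.json")
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
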