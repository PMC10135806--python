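"""VIA polygon annotations and their rasterization into 3-class label masks.

Conventions, used consistently across the package:

* Coordinates are VIA's: ``x`` = column, ``y`` = row, pixel units, origin at
  the top-left corner, 0-based.
* A pixel ``(row, col)`` is sampled at its center ``(x, y) = (col + 0.5,
  row + 0.5)``.  A pixel belongs to a polygon if its center is strictly
  inside under the even-odd rule, or lies exactly on an edge.
* Class encoding: 0 = background, 1 = fragmentary osteon, 2 = intact osteon.
  Annotators never trace background; it is everything left over.
* Where an intact osteon was traced over a fragmentary one, the overlap is
  intact: fragment polygons are painted first, intact polygons second.
  Same-class overlaps merge.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

BACKGROUND, FRAGMENT, INTACT = 0, 1, 2
CLASS_NAMES = ("background", "fragment", "intact")
CLASS_VALUES = {"background": BACKGROUND, "fragment": FRAGMENT, "intact": INTACT}

#: Default mapping from annotation strings to the two osteon classes
#: (case-insensitive; extend via ``synonyms`` in :func:`read_via_annotations`).
DEFAULT_SYNONYMS = {
    "intact": "intact",
    "intact osteon": "intact",
    "fragment": "fragment",
    "frag": "fragment",
    "fragmentary": "fragment",
    "fragmentary osteon": "fragment",
}

#: Indexed-PNG palette: background black, fragment blue, intact orange.
MASK_PALETTE = [(0, 0, 0), (33, 102, 172), (230, 97, 1)]


class ViaParseError(ValueError):
    """Raised when a VIA JSON document violates the expected layout."""


@dataclass
class PolygonRegion:
    """One traced osteon contour.

    Parameters
    ----------
    vertices : (n, 2) float array
        Ordered ``(x, y)`` pixel coordinates in the original image frame.
    class_label : {"intact", "fragment"}
    region_index : int
        Ordinal of the region within its image (annotation order).
    """

    vertices: np.ndarray
    class_label: str
    region_index: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y) points")
        if len(self.vertices) < 3:
            raise ValueError(
                f"region {self.region_index}: polygon needs >= 3 vertices, "
                f"got {len(self.vertices)}"
            )
        if not np.isfinite(self.vertices).all():
            raise ValueError(f"region {self.region_index}: non-finite vertex")
        if self.class_label not in ("intact", "fragment"):
            raise ValueError(
                f"region {self.region_index}: class_label must be 'intact' or "
                f"'fragment', got {self.class_label!r}"
            )

    def signed_area(self) -> float:
        """Shoelace area; zero for degenerate polygons."""
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class AnnotationSet:
    """All regions traced on one microphotograph."""

    image_id: str
    image_width: int
    image_height: int
    regions: list[PolygonRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError(
                f"{self.image_id}: image dimensions must be positive, got "
                f"{self.image_width}x{self.image_height}"
            )


@dataclass
class LabelMask:
    """Integer label grid over pixels; values in {0, 1, 2}."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("mask grid must be integer-typed")
        bad = (self.grid < 0) | (self.grid > 2)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"mask value {int(self.grid[r, c])} at (row={r}, col={c}) "
                "outside {0, 1, 2}"
            )

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.grid.ravel(), minlength=3)[:3]


# ---------------------------------------------------------------------------
# VIA v2 JSON I/O
# ---------------------------------------------------------------------------

def _via_image_entries(doc: dict) -> dict:
    if "_via_img_metadata" in doc:  # project-file layout
        return doc["_via_img_metadata"]
    # flat region-export layout: every value should look like an image entry
    if all(isinstance(v, dict) and "regions" in v for v in doc.values()) and doc:
        return doc
    if not doc:
        return {}
    bad = next(k for k, v in doc.items() if not (isinstance(v, dict) and "regions" in v))
    raise ViaParseError(
        f"document is neither a VIA project nor a region export; "
        f"offending key: {bad!r}"
    )


def _map_class(raw: str, synonyms: Mapping[str, str]) -> str | None:
    return synonyms.get(str(raw).strip().lower())


def read_via_annotations(
    source,
    class_attribute_name: str = "class",
    synonyms: Mapping[str, str] | None = None,
    image_sizes: Mapping[str, tuple[int, int]] | None = None,
) -> list[AnnotationSet]:
    """Parse a VIA v2 JSON document into :class:`AnnotationSet` objects.

    Accepts both the project-file layout (``_via_img_metadata``) and the flat
    region-export layout, and both ``polygon`` and ``polyline`` shapes (VIA's
    polyline tool is routinely used to trace closed regions).

    VIA itself does not record image pixel dimensions (its ``size`` key is
    the file size in bytes), so dimensions are taken from per-image
    ``file_attributes`` ``width``/``height`` when present, else from
    ``image_sizes`` (a ``{filename: (width, height)}`` mapping).

    Parameters
    ----------
    source : path, str of JSON, or parsed dict
    class_attribute_name : str
        Name of the region attribute holding the osteon class.
    synonyms : mapping, optional
        Case-insensitive map from annotation strings to ``{"intact",
        "fragment"}``; defaults to :data:`DEFAULT_SYNONYMS`.
    image_sizes : mapping, optional
        Fallback ``{filename: (width, height)}``.

    Raises
    ------
    ViaParseError
        Malformed document, region with fewer than 3 points, missing class
        attribute, unknown class string, or unknown image dimensions.
    """
    if isinstance(source, (str, Path)) and (
        isinstance(source, Path) or not source.lstrip().startswith("{")
    ):
        text = Path(source).read_text()
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ViaParseError(f"{source}: invalid JSON ({exc})") from exc
    elif isinstance(source, str):
        try:
            doc = json.loads(source)
        except json.JSONDecodeError as exc:
            raise ViaParseError(f"invalid JSON ({exc})") from exc
    else:
        doc = source
    if not isinstance(doc, dict):
        raise ViaParseError("VIA document must be a JSON object")

    synonyms = {k.lower(): v for k, v in (synonyms or DEFAULT_SYNONYMS).items()}
    out: list[AnnotationSet] = []
    for key, entry in _via_image_entries(doc).items():
        filename = entry.get("filename", key)
        fattr = entry.get("file_attributes", {}) or {}
        if "width" in fattr and "height" in fattr:
            w, h = int(fattr["width"]), int(fattr["height"])
        elif image_sizes and filename in image_sizes:
            w, h = map(int, image_sizes[filename])
        else:
            raise ViaParseError(
                f"{filename}: image dimensions unknown; provide them via "
                "file_attributes width/height or the image_sizes argument"
            )
        regions: list[PolygonRegion] = []
        for idx, reg in enumerate(entry.get("regions", [])):
            shape = reg.get("shape_attributes", {})
            name = shape.get("name")
            if name not in ("polygon", "polyline"):
                raise ViaParseError(
                    f"{filename} region {idx}: unsupported shape {name!r} "
                    "(expected polygon or polyline)"
                )
            xs, ys = shape.get("all_points_x", []), shape.get("all_points_y", [])
            if len(xs) != len(ys):
                raise ViaParseError(
                    f"{filename} region {idx}: all_points_x and all_points_y "
                    "lengths differ"
                )
            if len(xs) < 3:
                raise ViaParseError(
                    f"{filename} region {idx}: polygon has {len(xs)} points, "
                    "need >= 3"
                )
            rattr = reg.get("region_attributes", {}) or {}
            if class_attribute_name not in rattr:
                raise ViaParseError(
                    f"{filename} region {idx}: missing region attribute "
                    f"{class_attribute_name!r}; available: {sorted(rattr)}"
                )
            label = _map_class(rattr[class_attribute_name], synonyms)
            if label is None:
                raise ViaParseError(
                    f"{filename} region {idx}: unknown class "
                    f"{rattr[class_attribute_name]!r}; known: "
                    f"{sorted(set(synonyms))}"
                )
            regions.append(
                PolygonRegion(np.column_stack([xs, ys]), label, region_index=idx)
            )
        out.append(AnnotationSet(filename, w, h, regions))
    return out


def write_via_annotations(annotations: Iterable[AnnotationSet], path=None,
                          class_attribute_name: str = "class") -> dict:
    """Serialize annotation sets to VIA flat region-export JSON.

    Image dimensions are stored in ``file_attributes`` so the document
    round-trips through :func:`read_via_annotations` without external size
    information.  Returns the document dict; writes it to ``path`` if given.
    """
    doc: dict = {}
    for ann in annotations:
        doc[ann.image_id] = {
            "filename": ann.image_id,
            "size": -1,
            "file_attributes": {"width": ann.image_width,
                                "height": ann.image_height},
            "regions": [
                {
                    "shape_attributes": {
                        "name": "polygon",
                        "all_points_x": [float(v) for v in r.vertices[:, 0]],
                        "all_points_y": [float(v) for v in r.vertices[:, 1]],
                    },
                    "region_attributes": {class_attribute_name: r.class_label},
                }
                for r in ann.regions
            ],
        }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def points_in_polygon(px: np.ndarray, py: np.ndarray,
                      vertices: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (crossing-number) point-in-polygon test.

    Points exactly on a polygon edge count as inside.  ``px``/``py`` are
    broadcastable arrays of query coordinates.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    v = np.asarray(vertices, dtype=float)
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    inside = np.zeros(np.broadcast(px, py).shape, dtype=bool)
    on_edge = np.zeros_like(inside)
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        # even-odd crossing of the upward ray, half-open in y to avoid
        # double-counting vertices
        crosses = (ey1 > py) != (ey2 > py)
        if crosses.any():
            xint = ex1 + (py - ey1) * (ex2 - ex1) / (ey2 - ey1)
            inside ^= crosses & (px < xint)
        # exact on-edge inclusion
        cross = (ex2 - ex1) * (py - ey1) - (ey2 - ey1) * (px - ex1)
        on_edge |= (
            (cross == 0.0)
            & (px >= min(ex1, ex2)) & (px <= max(ex1, ex2))
            & (py >= min(ey1, ey2)) & (py <= max(ey1, ey2))
        )
    return inside | on_edge


def _paint_region(grid: np.ndarray, region: PolygonRegion) -> None:
    h, w = grid.shape
    v = region.vertices
    # restrict the test to the polygon's bounding box, clipped to the frame
    c0 = max(int(np.floor(v[:, 0].min() - 0.5)), 0)
    c1 = min(int(np.ceil(v[:, 0].max() + 0.5)), w - 1)
    r0 = max(int(np.floor(v[:, 1].min() - 0.5)), 0)
    r1 = min(int(np.ceil(v[:, 1].max() + 0.5)), h - 1)
    if c0 > c1 or r0 > r1:
        return
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    px = cols[None, :] + 0.5
    py = rows[:, None] + 0.5
    inside = points_in_polygon(px, py, v)
    sub = grid[r0:r1 + 1, c0:c1 + 1]
    sub[inside] = CLASS_VALUES[region.class_label]


def rasterize_mask(annotation: AnnotationSet,
                   width: int | None = None,
                   height: int | None = None) -> LabelMask:
    """Rasterize an annotation set into a 3-class label mask.

    Fragment polygons are painted first and intact polygons second, so where
    an intact osteon was traced over a fragmentary one the overlap is labelled
    intact.  Polygons extending past the frame are clipped; degenerate
    (zero-area) polygons contribute no pixels and trigger a warning.
    """
    w = annotation.image_width if width is None else width
    h = annotation.image_height if height is None else height
    if w != annotation.image_width or h != annotation.image_height:
        raise ValueError(
            f"{annotation.image_id}: requested mask {w}x{h} does not match "
            f"annotated image {annotation.image_width}x{annotation.image_height}"
        )
    grid = np.zeros((h, w), dtype=np.uint8)
    ordered = [r for r in annotation.regions if r.class_label == "fragment"]
    ordered += [r for r in annotation.regions if r.class_label == "intact"]
    for region in ordered:
        if region.signed_area() == 0.0:
            warnings.warn(
                f"{annotation.image_id} region {region.region_index}: "
                "zero-area polygon skipped",
                stacklevel=2,
            )
            continue
        _paint_region(grid, region)
    return LabelMask(grid)


# ---------------------------------------------------------------------------
# Mask PNG I/O
# ---------------------------------------------------------------------------

def write_mask_png(mask: LabelMask | np.ndarray, path) -> None:
    """Write a label mask as an 8-bit indexed PNG (palette: black/blue/orange)."""
    from PIL import Image

    grid = mask.grid if isinstance(mask, LabelMask) else np.asarray(mask)
    LabelMask(grid)  # validates range
    img = Image.fromarray(grid.astype(np.uint8), mode="P")
    palette = [c for rgb in MASK_PALETTE for c in rgb] + [0] * (768 - 9)
    img.putpalette(palette)
    img.save(path, format="PNG")


def read_mask_png(path) -> LabelMask:
    """Read an indexed (or grayscale) PNG back into a :class:`LabelMask`."""
    from PIL import Image

    grid = np.asarray(Image.open(path)).astype(np.int64)
    bad = (grid < 0) | (grid > 2)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: mask value {int(grid[r, c])} at (row={r}, col={c}) "
            "outside {0, 1, 2}"
        )
    return LabelMask(grid.astype(np.uint8))
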