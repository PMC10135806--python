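"""Shared fixtures: the reference confusion matrix, VIA fixtures, and an
independent brute-force point-in-polygon oracle for rasterization checks."""

import numpy as np
import pytest

from osteoseg.evaluate import ConfusionMatrix

#: Reference normalized confusion matrix from a 10-fold cross-validation of
#: the segmentation network on 99 annotated microphotographs (rows = manual
#: class, columns = predicted class, order background / fragment / intact).
#: Used as fixed input data for metric fidelity checks.
REFERENCE_CM = np.array([
    [0.406, 0.090, 0.050],
    [0.025, 0.066, 0.044],
    [0.028, 0.054, 0.236],
])


@pytest.fixture
def reference_cm() -> ConfusionMatrix:
    return ConfusionMatrix(REFERENCE_CM.copy())


@pytest.fixture
def via_fixture() -> dict:
    """Handcrafted flat VIA export: one triangle 'intact', one quad 'fragment'."""
    return {
        "img1.png": {
            "filename": "img1.png",
            "size": -1,
            "file_attributes": {"width": 64, "height": 64},
            "regions": [
                {
                    "shape_attributes": {
                        "name": "polygon",
                        "all_points_x": [10, 30, 20],
                        "all_points_y": [10, 10, 30],
                    },
                    "region_attributes": {"class": "intact"},
                },
                {
                    "shape_attributes": {
                        "name": "polyline",
                        "all_points_x": [40, 55, 55, 40],
                        "all_points_y": [40, 40, 55, 55],
                    },
                    "region_attributes": {"class": "fragment"},
                },
            ],
        }
    }


# ---------------------------------------------------------------------------
# Independent rasterization oracle (pure per-pixel loop; no shared code with
# the implementation)
# ---------------------------------------------------------------------------

def point_in_polygon_oracle(px: float, py: float, vertices) -> bool:
    """Classic ray-casting even-odd test for one point, edges inclusive."""
    n = len(vertices)
    inside = False
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        # on-edge: collinear and within the edge's bounding box
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        if cross == 0.0 and min(x1, x2) <= px <= max(x1, x2) \
                and min(y1, y2) <= py <= max(y1, y2):
            return True
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


def rasterize_oracle(regions, width: int, height: int) -> np.ndarray:
    """Brute-force mask: every pixel center against every polygon, fragments
    painted before intacts."""
    grid = np.zeros((height, width), dtype=np.uint8)
    order = [r for r in regions if r.class_label == "fragment"]
    order += [r for r in regions if r.class_label == "intact"]
    for region in order:
        value = 1 if region.class_label == "fragment" else 2
        verts = [tuple(v) for v in region.vertices]
        xs = [v[0] for v in verts]
        ys = [v[1] for v in verts]
        xlo, xhi, ylo, yhi = min(xs), max(xs), min(ys), max(ys)
        for row in range(height):
            py = row + 0.5
            if py < ylo or py > yhi:
                continue
            for col in range(width):
                px = col + 0.5
                if px < xlo or px > xhi:
                    continue
                if point_in_polygon_oracle(px, py, verts):
                    grid[row, col] = value
    return grid


def random_scene_regions(rng: np.random.Generator, size: int,
                         max_polygons: int = 6):
    """Random star-shaped (hence simple) polygons with mixed classes."""
    from osteoseg.annotations import PolygonRegion

    regions = []
    n_polygons = int(rng.integers(1, max_polygons + 1))
    while len(regions) < n_polygons:
        n_vert = int(rng.integers(3, 9))
        cx, cy = rng.uniform(-5, size + 5, size=2)
        angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
        radii = rng.uniform(3, size / 2.5, n_vert)
        xs = cx + radii * np.cos(angles)
        ys = cy + radii * np.sin(angles)
        # mix of float and integer-snapped vertices exercises on-edge cases
        if rng.random() < 0.5:
            xs, ys = np.round(xs), np.round(ys)
        label = "intact" if rng.random() < 0.5 else "fragment"
        region = PolygonRegion(np.column_stack([xs, ys]), label, len(regions))
        if abs(region.signed_area()) < 1.0:  # avoid degenerate polygons
            continue
        regions.append(region)
    return regions
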