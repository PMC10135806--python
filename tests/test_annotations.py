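"""VIA parsing, polygon rasterization, and mask PNG round-trips."""

import json

import numpy as np
import pytest

from osteoseg.annotations import (
    AnnotationSet,
    LabelMask,
    PolygonRegion,
    ViaParseError,
    rasterize_mask,
    read_mask_png,
    read_via_annotations,
    write_mask_png,
    write_via_annotations,
)

from conftest import rasterize_oracle, random_scene_regions


def square(x0, y0, x1, y1):
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], dtype=float)


class TestViaParsing:
    def test_fixture_regions_and_labels(self, via_fixture):
        (ann,) = read_via_annotations(via_fixture)
        assert ann.image_id == "img1.png"
        assert (ann.image_width, ann.image_height) == (64, 64)
        assert [r.class_label for r in ann.regions] == ["intact", "fragment"]
        assert [len(r.vertices) for r in ann.regions] == [3, 4]

    def test_empty_regions(self):
        doc = {"a.png": {"filename": "a.png", "regions": [],
                         "file_attributes": {"width": 8, "height": 8}}}
        (ann,) = read_via_annotations(doc)
        assert ann.regions == []

    def test_project_layout(self, via_fixture):
        project = {"_via_img_metadata": via_fixture, "_via_settings": {}}
        (ann,) = read_via_annotations(project)
        assert len(ann.regions) == 2

    def test_round_trip_preserves_geometry(self, via_fixture):
        (original,) = read_via_annotations(via_fixture)
        doc = write_via_annotations([original])
        (reparsed,) = read_via_annotations(json.dumps(doc))
        assert reparsed.image_id == original.image_id
        for a, b in zip(original.regions, reparsed.regions):
            assert a.class_label == b.class_label
            np.testing.assert_array_equal(a.vertices, b.vertices)

    def test_malformed_json_names_source(self, tmp_path):
        bad = tmp_path / "broken.json"
        bad.write_text("{not json")
        with pytest.raises(ViaParseError, match="broken.json"):
            read_via_annotations(bad)

    def test_too_few_points_rejected(self, via_fixture):
        via_fixture["img1.png"]["regions"][0]["shape_attributes"] = {
            "name": "polygon", "all_points_x": [1, 2], "all_points_y": [1, 2]}
        with pytest.raises(ViaParseError, match=r"img1.png region 0.*2 points"):
            read_via_annotations(via_fixture)

    def test_missing_class_attribute_lists_available(self, via_fixture):
        via_fixture["img1.png"]["regions"][0]["region_attributes"] = {"typ": "x"}
        with pytest.raises(ViaParseError, match="typ"):
            read_via_annotations(via_fixture)

    def test_unknown_class_string_reported(self, via_fixture):
        via_fixture["img1.png"]["regions"][1]["region_attributes"] = {
            "class": "mystery"}
        with pytest.raises(ViaParseError, match="mystery"):
            read_via_annotations(via_fixture)

    def test_case_insensitive_synonyms(self, via_fixture):
        via_fixture["img1.png"]["regions"][0]["region_attributes"] = {
            "class": "Intact Osteon"}
        (ann,) = read_via_annotations(via_fixture)
        assert ann.regions[0].class_label == "intact"

    def test_missing_dimensions_requires_image_sizes(self, via_fixture):
        del via_fixture["img1.png"]["file_attributes"]
        with pytest.raises(ViaParseError, match="dimensions"):
            read_via_annotations(via_fixture)
        (ann,) = read_via_annotations(via_fixture,
                                      image_sizes={"img1.png": (32, 24)})
        assert (ann.image_width, ann.image_height) == (32, 24)


class TestRasterize:
    def test_no_regions_all_background(self):
        mask = rasterize_mask(AnnotationSet("x", 64, 64, []))
        assert mask.grid.shape == (64, 64)
        assert (mask.grid == 0).all()

    def test_square_matches_oracle_and_count(self):
        region = PolygonRegion(square(10, 10, 20, 20), "intact")
        ann = AnnotationSet("x", 64, 64, [region])
        mask = rasterize_mask(ann)
        oracle = rasterize_oracle([region], 64, 64)
        np.testing.assert_array_equal(mask.grid, oracle)
        # centers 10.5..19.5 fall inside in both axes -> 10x10 pixels
        assert int((mask.grid == 2).sum()) == 100

    def test_intact_paints_over_fragment(self):
        frag = PolygonRegion(square(0, 0, 20, 20), "fragment", 0)
        intact = PolygonRegion(square(10, 10, 30, 30), "intact", 1)
        # region order must not matter: intact wins the overlap either way
        for regions in ([frag, intact], [intact, frag]):
            mask = rasterize_mask(AnnotationSet("x", 64, 64, regions))
            overlap = mask.grid[11:20, 11:20]
            assert (overlap == 2).all()
            only_frag = mask.grid[1:10, 1:10]
            assert (only_frag == 1).all()

    def test_same_class_overlap_merges(self):
        a = PolygonRegion(square(0, 0, 20, 20), "fragment", 0)
        b = PolygonRegion(square(10, 10, 30, 30), "fragment", 1)
        mask = rasterize_mask(AnnotationSet("x", 64, 64, [a, b]))
        assert set(np.unique(mask.grid)) == {0, 1}

    def test_out_of_frame_clipped(self):
        region = PolygonRegion(square(-10, -10, 5, 5), "intact")
        mask = rasterize_mask(AnnotationSet("x", 16, 16, [region]))
        assert (mask.grid[:5, :5] == 2).all()
        assert mask.grid.shape == (16, 16)

    def test_degenerate_polygon_warns_and_paints_nothing(self):
        line = PolygonRegion(np.array([[1, 1], [5, 5], [9, 9]]), "intact")
        with pytest.warns(UserWarning, match="zero-area"):
            mask = rasterize_mask(AnnotationSet("x", 16, 16, [line]))
        assert (mask.grid == 0).all()

    def test_dimension_mismatch_rejected(self):
        ann = AnnotationSet("x", 16, 16, [])
        with pytest.raises(ValueError, match="does not match"):
            rasterize_mask(ann, width=32, height=32)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_scenes_match_oracle(self, seed):
        """Property: rasterization equals the per-pixel brute-force oracle."""
        rng = np.random.default_rng(seed)
        size = int(rng.integers(16, 49))
        regions = random_scene_regions(rng, size)
        mask = rasterize_mask(AnnotationSet("x", size, size, regions))
        np.testing.assert_array_equal(
            mask.grid, rasterize_oracle(regions, size, size)
        )

    @pytest.mark.parametrize("seed", range(4))
    def test_paint_order_partition(self, seed):
        """Class 2 covers the union of intact interiors; class 1 is exactly
        the union of fragment interiors minus it."""
        rng = np.random.default_rng(100 + seed)
        size = 48
        regions = random_scene_regions(rng, size)
        mask = rasterize_mask(AnnotationSet("x", size, size, regions))
        intact_union = rasterize_oracle(
            [r for r in regions if r.class_label == "intact"], size, size
        ) > 0
        frag_union = rasterize_oracle(
            [r for r in regions if r.class_label == "fragment"], size, size
        ) > 0
        np.testing.assert_array_equal(mask.grid == 2, intact_union)
        np.testing.assert_array_equal(mask.grid == 1,
                                      frag_union & ~intact_union)


class TestPointInPolygon:
    from hypothesis import given, settings, strategies as st

    coord = st.floats(min_value=-20.0, max_value=40.0, allow_nan=False,
                      allow_infinity=False)

    @given(st.lists(st.tuples(coord, coord), min_size=3, max_size=7),
           st.tuples(coord, coord))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_vectorized_test_agrees_with_scalar_oracle(self, verts, point):
        """The vectorized even-odd test matches the per-point ray-casting
        oracle for arbitrary (possibly degenerate) polygons."""
        from conftest import point_in_polygon_oracle
        from osteoseg.annotations import points_in_polygon

        px, py = point
        got = points_in_polygon(np.array([px]), np.array([py]),
                                np.array(verts, dtype=float))
        assert bool(got[0]) == point_in_polygon_oracle(px, py, verts)


class TestMaskPng:
    def test_round_trip_zeros(self, tmp_path):
        mask = LabelMask(np.zeros((8, 8), dtype=np.uint8))
        write_mask_png(mask, tmp_path / "m.png")
        back = read_mask_png(tmp_path / "m.png")
        np.testing.assert_array_equal(back.grid, mask.grid)

    def test_round_trip_checkerboard(self, tmp_path):
        grid = (np.add.outer(np.arange(9), np.arange(9)) % 3).astype(np.uint8)
        write_mask_png(LabelMask(grid), tmp_path / "m.png")
        np.testing.assert_array_equal(read_mask_png(tmp_path / "m.png").grid,
                                      grid)

    def test_out_of_range_value_rejected_on_write(self, tmp_path):
        with pytest.raises(ValueError, match="3"):
            write_mask_png(np.full((4, 4), 3, dtype=np.uint8),
                           tmp_path / "m.png")

    def test_bad_value_on_read_names_position(self, tmp_path):
        from PIL import Image

        grid = np.zeros((4, 4), dtype=np.uint8)
        grid[2, 1] = 3
        Image.fromarray(grid, mode="L").save(tmp_path / "bad.png")
        with pytest.raises(ValueError, match=r"3 at \(row=2, col=1\)"):
            read_mask_png(tmp_path / "bad.png")
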