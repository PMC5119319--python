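import numpy as np
import pytest

from conftest import flood_fill_label, nearest_seed_labels, same_partition
from provimage.segment import (
    Region,
    SegmentedImage,
    connected_components,
    false_colour,
    false_colour_png,
    watershed_with_seeds,
)


def seg_from(labels):
    return SegmentedImage.from_array(np.asarray(labels))


class TestConnectedComponents:
    def test_two_separated_groups(self):
        seg = connected_components(
            np.array([[1, 1, 0], [0, 0, 0], [0, 1, 1]]), background=0
        )
        assert seg.identifiers == [1, 2]

    def test_all_background_has_no_identifiers(self):
        seg = connected_components(np.zeros((4, 4), dtype=int), background=0)
        assert seg.identifiers == []

    def test_labels_consecutive_in_raster_order(self):
        arr = np.zeros((5, 5), dtype=int)
        arr[4, 4] = 1  # later in raster order
        arr[0, 0] = 1
        seg = connected_components(arr, background=0)
        assert np.asarray(seg)[0, 0] == 1
        assert np.asarray(seg)[4, 4] == 2

    def test_matches_flood_fill_oracle_on_random_binaries(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            arr = (rng.random((16, 16)) > 0.5).astype(int)
            seg = connected_components(arr, background=0)
            assert same_partition(np.asarray(seg), flood_fill_label(arr))

    def test_idempotent_under_relabelling(self):
        rng = np.random.default_rng(12)
        arr = (rng.random((16, 16)) > 0.6).astype(int)
        first = connected_components(arr, background=0)
        second = connected_components(np.asarray(first), background=0)
        assert same_partition(np.asarray(first), np.asarray(second))


class TestWatershed:
    def test_flat_terrain_matches_nearest_seed_oracle(self):
        land = np.zeros((9, 13))
        seeds = np.zeros((9, 13), dtype=int)
        seeds[4, 2] = 1
        seeds[4, 10] = 2
        seg = watershed_with_seeds(land, seeds=seg_from(seeds))
        oracle = nearest_seed_labels((9, 13), [(4, 2, 1), (4, 10, 2)])
        np.testing.assert_array_equal(np.asarray(seg), oracle)

    def test_single_seed_floods_everything(self):
        seeds = np.zeros((6, 6), dtype=int)
        seeds[3, 3] = 5
        seg = watershed_with_seeds(np.zeros((6, 6)), seeds=seg_from(seeds))
        assert (np.asarray(seg) == 5).all()

    def test_mask_keeps_outside_background(self):
        seeds = np.zeros((6, 6), dtype=int)
        seeds[0, 0] = 1
        mask = np.zeros((6, 6), dtype=bool)
        mask[:3, :] = True
        seg = watershed_with_seeds(np.zeros((6, 6)), seeds=seg_from(seeds), mask=mask)
        arr = np.asarray(seg)
        assert (arr[:3] == 1).all() and (arr[3:] == 0).all()

    def test_no_mask_labels_every_pixel_with_seed_labels(self):
        rng = np.random.default_rng(13)
        land = rng.random((20, 20))
        seeds = np.zeros((20, 20), dtype=int)
        seeds[3, 3], seeds[16, 4], seeds[9, 15] = 1, 2, 3
        seg = watershed_with_seeds(land, seeds=seg_from(seeds))
        arr = np.asarray(seg)
        assert (arr > 0).all()
        assert set(np.unique(arr)) <= {1, 2, 3}

    def test_shape_mismatch_and_empty_seeds_rejected(self):
        with pytest.raises(ValueError):
            watershed_with_seeds(np.zeros((4, 4)), seeds=seg_from(np.zeros((5, 5), int)))
        with pytest.raises(ValueError):
            watershed_with_seeds(np.zeros((4, 4)), seeds=np.zeros((4, 4), int))


class TestSegmentedImage:
    def test_identifiers_sorted_distinct_positive(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[0, 0] = 7
        labels[2, 2] = 3
        assert seg_from(labels).identifiers == [3, 7]

    def test_region_mask_matches_label(self):
        labels = np.array([[0, 1], [2, 1]])
        region = seg_from(labels).region_by_identifier(1)
        np.testing.assert_array_equal(
            np.asarray(region), [[False, True], [False, True]]
        )
        assert region.area == 2

    def test_absent_identifier_raises(self):
        seg = seg_from(np.ones((2, 2), dtype=int))
        with pytest.raises(KeyError):
            seg.region_by_identifier(9)
        with pytest.raises(KeyError):
            seg.remove_region(9)

    def test_remove_region_zeroes_pixels_without_renumbering(self):
        labels = np.array([[3, 3, 0], [0, 7, 7]])
        seg = seg_from(labels)
        before = np.count_nonzero(np.asarray(seg))
        seg.remove_region(3)
        assert seg.identifiers == [7]
        assert before - np.count_nonzero(np.asarray(seg)) == 2

    def test_removing_only_region_leaves_background(self):
        seg = seg_from(np.ones((3, 3), dtype=int))
        seg.remove_region(1)
        assert seg.identifiers == []
        assert not np.asarray(seg).any()

    def test_regions_partition_foreground(self):
        rng = np.random.default_rng(14)
        seg = connected_components((rng.random((16, 16)) > 0.5).astype(int),
                                   background=0)
        union = np.zeros(seg.shape, dtype=bool)
        for i in seg.identifiers:
            mask = np.asarray(seg.region_by_identifier(i))
            assert not (union & mask).any()  # pairwise disjoint
            union |= mask
        np.testing.assert_array_equal(union, np.asarray(seg) > 0)


class TestRegionMorphology:
    def test_solid_square_inner_border_perimeter(self):
        region = Region(np.ones((3, 3), dtype=bool))
        assert region.area == 9
        inner = np.asarray(region.inner)
        assert inner.sum() == 1 and inner[1, 1]
        assert region.border.area == 8
        assert region.perimeter == 8

    def test_singleton(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        region = Region(mask)
        assert region.inner.area == 0
        assert region.perimeter == 1
        assert region.centroid == (1.0, 1.0)

    def test_border_inner_partition_mask(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            region = Region(rng.random((10, 10)) > 0.4)
            border, inner = np.asarray(region.border), np.asarray(region.inner)
            assert not (border & inner).any()
            np.testing.assert_array_equal(border | inner, np.asarray(region))
            assert region.area == region.border.area + region.inner.area
            assert region.perimeter <= region.area

    def test_dilate_extensive_and_clipped(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        dilated = np.asarray(Region(mask).dilate())
        assert dilated.shape == (4, 4)
        assert dilated[0, 0] and dilated[0, 1] and dilated[1, 0]
        assert dilated.sum() == 3
        assert Region(np.zeros((4, 4), bool)).dilate().area == 0

    def test_centroid_of_2x2_block(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0:2, 0:2] = True
        assert Region(mask).centroid == (0.5, 0.5)

    def test_centroid_on_symmetry_axis(self):
        mask = np.zeros((5, 7), dtype=bool)
        mask[1:4, 2:5] = True
        mask[2, 1] = mask[2, 5] = True
        row, col = Region(mask).centroid
        assert row == 2.0 and col == 3.0


class TestConvexHull:
    def test_rectangle_is_fixed_point(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[1:4, 2:5] = True
        np.testing.assert_array_equal(np.asarray(Region(mask).convex_hull), mask)

    def test_triangle_interior_is_filled(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[0, 0] = mask[0, 4] = mask[4, 0] = True
        hull = np.asarray(Region(mask).convex_hull)
        # half-plane test over pixel centres: row + col <= 4 inside the triangle
        rows, cols = np.mgrid[0:6, 0:6]
        np.testing.assert_array_equal(hull, rows + cols <= 4)

    def test_collinear_pixels_fill_the_segment(self):
        mask = np.zeros((3, 5), dtype=bool)
        mask[1, 0] = mask[1, 4] = True
        hull = np.asarray(Region(mask).convex_hull)
        expected = np.zeros((3, 5), dtype=bool)
        expected[1, :] = True
        np.testing.assert_array_equal(hull, expected)

    def test_single_pixel_is_its_own_hull(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 2] = True
        np.testing.assert_array_equal(np.asarray(Region(mask).convex_hull), mask)

    def test_hull_is_superset_and_idempotent(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            region = Region(rng.random((9, 9)) > 0.75)
            hull = region.convex_hull
            assert (np.asarray(hull) | np.asarray(region)).sum() == hull.area
            np.testing.assert_array_equal(
                np.asarray(hull.convex_hull), np.asarray(hull)
            )

    def test_matches_independent_geometry_oracle(self):
        # oracle: shapely convex hull of the member pixel centres
        import shapely.geometry as geom

        rng = np.random.default_rng(17)
        for _ in range(5):
            mask = rng.random((8, 8)) > 0.8
            if not mask.any():
                mask[3, 3] = True
            pts = [(float(r), float(c)) for r, c in np.argwhere(mask)]
            poly = geom.MultiPoint(pts).convex_hull.buffer(1e-9)
            expected = np.zeros_like(mask)
            for r in range(8):
                for c in range(8):
                    expected[r, c] = poly.contains(geom.Point(r, c))
            np.testing.assert_array_equal(
                np.asarray(Region(mask).convex_hull), expected
            )


class TestFalseColour:
    def test_background_black_segments_uniform(self):
        labels = np.array([[0, 1], [2, 1]])
        rgb = false_colour(labels)
        assert tuple(rgb[0, 0]) == (0, 0, 0)
        assert tuple(rgb[0, 1]) == tuple(rgb[1, 1])
        assert tuple(rgb[0, 1]) != tuple(rgb[1, 0])

    def test_png_byte_identical_across_calls(self):
        labels = np.arange(9).reshape(3, 3) % 4
        assert false_colour_png(labels) == false_colour_png(labels)
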