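"""Segmentation-stage contracts: thresholds, clustering, splitting, shrink."""

import numpy as np
import pytest

from furrow.segmentation import (
    SegParams,
    SegmentedObject,
    cluster_foreground,
    extract_foreground,
    segment_image,
    select_widest_section,
    shrink_contour,
    split_concave_object,
)


def _disc_image(centers, radius=8.0, amps=None, shape=(60, 90), background=0.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, background, dtype=float)
    amps = amps or [100.0] * len(centers)
    for (cx, cy), amp in zip(centers, amps):
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2] = amp
    return img


class TestSegParams:
    def test_table_defaults(self):
        p = SegParams()
        assert (
            p.intensity_range,
            p.window_size,
            p.spatial_range,
            p.concavity_threshold,
            p.noise_intensity,
        ) == (7, 30, 10, 5, 30)

    def test_pipeline_run_set(self):
        p = SegParams.pipeline_defaults()
        assert (
            p.intensity_range,
            p.window_size,
            p.spatial_range,
            p.concavity_threshold,
            p.noise_intensity,
            p.shrink,
            p.shrink_level,
        ) == (6, 30, 3, 5, 30, True, 4)

    @pytest.mark.parametrize(
        "field,value",
        [("intensity_range", 21), ("window_size", 3), ("noise_intensity", 0)],
    )
    def test_out_of_range_rejected(self, field, value):
        with pytest.raises(ValueError):
            SegParams(**{field: value})


class TestExtractForeground:
    def test_uniform_subnoise_image_is_background(self):
        img = np.full((40, 40), 20.0)
        mask = extract_foreground(img, SegParams(noise_intensity=30))
        assert not mask.any()

    def test_two_blobs_recovered(self):
        img = _disc_image([(25, 30), (65, 30)])
        truth = img > 0
        mask = extract_foreground(img, SegParams())
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou > 0.9

    def test_inverted_contrast_rejected(self):
        img = 200.0 - _disc_image([(25, 30), (65, 30)])
        with pytest.raises(ValueError):
            extract_foreground(img, SegParams())

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            extract_foreground(np.empty((0, 0)), SegParams())


class TestClusterForeground:
    def test_disconnected_blobs_two_objects(self):
        img = _disc_image([(25, 30), (65, 30)])
        p = SegParams()
        objs = cluster_foreground(extract_foreground(img, p), img, p)
        assert len(objs) == 2

    def test_small_object_merged_into_neighbor(self):
        # one blob below window_size (area ~13 < P2=30) near a large one
        img = _disc_image([(30, 30)], radius=9.0)
        img[(np.mgrid[0:60, 0:90][1] - 44) ** 2
            + (np.mgrid[0:60, 0:90][0] - 30) ** 2 <= 4.0] = 100.0
        p = SegParams()
        objs = cluster_foreground(extract_foreground(img, p), img, p)
        assert len(objs) == 1

    def test_intensity_range_monotone_object_count(self):
        # two touching blobs with distinct intensities: raising P1 can only
        # merge them, never split further
        img = _disc_image([(30, 30), (44, 30)], radius=8.0, amps=[90.0, 200.0])
        counts = []
        for p1 in (1, 3, 6, 12, 20):
            p = SegParams(intensity_range=p1, spatial_range=3)
            objs = cluster_foreground(extract_foreground(img, p), img, p)
            counts.append(len(objs))
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[0] >= 2 and counts[-1] == 1


def _dumbbell_object():
    yy, xx = np.mgrid[0:40, 0:60]
    blob = ((xx - 18) ** 2 + (yy - 20) ** 2 <= 81) | (
        (xx - 42) ** 2 + (yy - 20) ** 2 <= 81
    ) | ((np.abs(yy - 20) <= 2) & (xx >= 18) & (xx <= 42))
    return SegmentedObject(1, np.column_stack(np.nonzero(blob)))


class TestConcavitySplit:
    def test_convex_disc_unchanged(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disc = SegmentedObject(1, np.column_stack(np.nonzero((xx - 20) ** 2 + (yy - 20) ** 2 <= 100)))
        assert len(split_concave_object(disc, 5)) == 1

    def test_dumbbell_splits_at_default_threshold(self):
        parts = split_concave_object(_dumbbell_object(), 5)
        assert len(parts) == 2
        areas = sorted(p.area for p in parts)
        assert areas[0] > 0.25 * areas[1]  # two comparable lobes, not a sliver

    def test_dumbbell_kept_whole_at_max_threshold(self):
        assert len(split_concave_object(_dumbbell_object(), 20)) == 1

    def test_split_count_monotone_in_threshold(self):
        counts = [len(split_concave_object(_dumbbell_object(), p4)) for p4 in (2, 5, 10, 20)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_tiny_object_returned_unsplit(self):
        tiny = SegmentedObject(1, np.array([[0, 0], [0, 1], [1, 0]]))
        assert split_concave_object(tiny, 5) == [tiny]


class TestShrink:
    def test_square_eroded_to_known_area(self):
        yy, xx = np.mgrid[0:20, 0:20]
        square = SegmentedObject(
            1, np.column_stack(np.nonzero((xx >= 4) & (xx <= 14) & (yy >= 4) & (yy <= 14)))
        )
        shrunk = shrink_contour(square, 4)
        assert shrunk.area == 9  # 11x11 square, disc radius 4 -> 3x3 core

    def test_zero_level_is_identity(self):
        obj = SegmentedObject(1, np.array([[3, 3], [3, 4], [4, 3], [4, 4]]))
        assert shrink_contour(obj, 0) is obj

    def test_erosion_never_grows(self, sparse_grid_rendered):
        _, img, mask, _ = sparse_grid_rendered
        objs = segment_image(img[0], SegParams(shrink=False))
        for obj in objs[:10]:
            assert shrink_contour(obj, 2).area <= obj.area

    def test_vanishing_object_kept_and_flagged(self):
        obj = SegmentedObject(1, np.array([[5, 5], [5, 6], [6, 5], [6, 6]]))
        out = shrink_contour(obj, 4)
        assert out.shrink_failed and out.area == obj.area


class TestWidestSection:
    @pytest.mark.parametrize(
        "areas,expected",
        [({0: 10, 1: 50, 2: 30}, 1), ({4: 25}, 4), ({0: 40, 1: 40}, 0)],
    )
    def test_selection_and_tie_rule(self, areas, expected):
        assert select_widest_section(areas) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_widest_section({})


class TestEndToEnd:
    def test_separated_nuclei_count_and_centroids(self, sparse_grid_rendered):
        sample, img, mask, (x0, y0) = sparse_grid_rendered
        objs = segment_image(img[0], SegParams.pipeline_defaults())
        assert len(objs) == len(sample.cells)
        from scipy.spatial import cKDTree

        xy = sample.cells[["x_px", "y_px"]].to_numpy()
        cents = np.array([o.centroid for o in objs]) + np.array([x0, y0])
        d, _ = cKDTree(cents).query(xy)
        assert (d < 2.0).mean() >= 0.95

    def test_final_labels_disjoint(self, sparse_grid_rendered):
        _, img, _, _ = sparse_grid_rendered
        objs = segment_image(img[0], SegParams.pipeline_defaults())
        seen = set()
        for o in objs:
            pix = set(map(tuple, o.pixels))
            assert not (pix & seen)
            seen |= pix
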