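"""Region table fidelity, polygon rasterization, and trace extraction."""

import hashlib

import numpy as np
import pytest

from roipulse import (
    ConfigError,
    FaceMeshFrame,
    InputError,
    ROIDefinition,
    extract_rgb_trace,
    get_roi,
    load_roi_table,
    polygon_mask,
    roi_table_as_json,
)
from roipulse.roi_scheme import N_LANDMARKS

ROI_TABLE_SHA256 = "8649d621d14d5634d540478d909d73c8635f877c4e3c128f616fb7b4a27b9286"


def brute_force_inside(vertices, px, py):
    """Independent scalar even-odd point-in-polygon test (PNPOLY form)."""
    inside = False
    n = len(vertices)
    j = n - 1
    for i in range(n):
        xi, yi = vertices[i]
        xj, yj = vertices[j]
        if (yi > py) != (yj > py):
            if px < (xj - xi) * (py - yi) / (yj - yi) + xi:
                inside = not inside
        j = i
    return inside


def brute_force_mask(vertices, height, width):
    mask = np.zeros((height, width), dtype=bool)
    for r in range(height):
        for c in range(width):
            mask[r, c] = brute_force_inside(vertices, c + 0.5, r + 0.5)
    return mask


class TestROITable:
    def test_28_regions_in_index_order(self):
        table = load_roi_table()
        assert len(table) == 28
        assert [r.index_k for r in table] == list(range(1, 29))

    def test_known_rows(self):
        table = {r.index_k: r for r in load_roi_table()}
        assert table[1].name == "medial forehead"
        assert table[1].keypoint_list == (10, 109, 108, 151, 337, 338)
        assert table[4].name == "glabella"
        assert table[4].keypoint_list == (151, 108, 107, 55, 8, 285, 336, 337)
        assert table[26].name == "chin"
        assert table[26].keypoint_list == (
            18, 83, 182, 194, 32, 140, 176, 148, 152, 377, 400, 369, 262,
            418, 406, 313,
        )

    def test_keypoint_invariants(self):
        for roi in load_roi_table():
            assert len(roi.keypoint_list) >= 3
            assert len(set(roi.keypoint_list)) == len(roi.keypoint_list)
            assert all(0 <= k < N_LANDMARKS for k in roi.keypoint_list)

    def test_table_checksum(self):
        digest = hashlib.sha256(roi_table_as_json().encode()).hexdigest()
        assert digest == ROI_TABLE_SHA256

    def test_lookup_by_name_and_index(self):
        assert get_roi("glabella").index_k == 4
        assert get_roi(22).name == "left malar"
        with pytest.raises(ConfigError):
            get_roi("forehead")

    def test_out_of_range_keypoint_rejected(self):
        with pytest.raises(ConfigError):
            ROIDefinition(1, "bogus", (1, 2, 468))


def _frame_with(points_map, fill=(0.0, 0.0)):
    pts = np.full((N_LANDMARKS, 2), fill, dtype=float)
    for idx, xy in points_map.items():
        pts[idx] = xy
    return FaceMeshFrame(0, pts)


class TestPolygonMask:
    def test_axis_aligned_square(self):
        roi = ROIDefinition(1, "medial forehead", (0, 1, 2, 3))
        frame = _frame_with({0: (0.5, 0.5), 1: (10.5, 0.5),
                             2: (10.5, 10.5), 3: (0.5, 10.5)})
        assert polygon_mask(frame, roi, 20, 20).pixel_count == 100

    def test_collinear_points_zero_area(self):
        roi = ROIDefinition(1, "medial forehead", (0, 1, 2))
        frame = _frame_with({0: (1.0, 1.0), 1: (5.0, 5.0), 2: (9.0, 9.0)})
        assert polygon_mask(frame, roi, 20, 20).pixel_count == 0

    def test_polygon_outside_frame_clipped(self):
        roi = ROIDefinition(1, "medial forehead", (0, 1, 2))
        frame = _frame_with({0: (-30.0, -30.0), 1: (-10.0, -30.0),
                             2: (-20.0, -10.0)})
        assert polygon_mask(frame, roi, 20, 20).pixel_count == 0

    def test_matches_brute_force_on_random_polygons(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n_vert = int(rng.integers(3, 10))
            verts = rng.uniform(-4, 22, (n_vert, 2))
            roi = ROIDefinition(1, "medial forehead", tuple(range(n_vert)))
            frame = _frame_with({i: verts[i] for i in range(n_vert)})
            got = polygon_mask(frame, roi, 18, 18).mask
            expected = brute_force_mask(verts, 18, 18)
            np.testing.assert_array_equal(got, expected)

    def test_template_rois_match_brute_force(self, template):
        """Every shipped region, randomly displaced, agrees pixel-for-pixel
        with the independent even-odd oracle."""
        rng = np.random.default_rng(11)
        offset = rng.uniform(-6, 6, 2)
        frame = FaceMeshFrame(0, template.points + offset)
        for roi in load_roi_table():
            got = polygon_mask(frame, roi, template.height, template.width)
            verts = frame.landmarks[list(roi.keypoint_list)]
            r0 = max(int(verts[:, 1].min()) - 2, 0)
            r1 = min(int(verts[:, 1].max()) + 3, template.height)
            c0 = max(int(verts[:, 0].min()) - 2, 0)
            c1 = min(int(verts[:, 0].max()) + 3, template.width)
            sub = brute_force_mask_window(verts, r0, r1, c0, c1)
            np.testing.assert_array_equal(got.mask[r0:r1, c0:c1], sub)
            assert got.pixel_count > 0
            # nothing outside the bounding window
            outside = got.mask.copy()
            outside[r0:r1, c0:c1] = False
            assert not outside.any()


def brute_force_mask_window(vertices, r0, r1, c0, c1):
    mask = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    for r in range(r0, r1):
        for c in range(c0, c1):
            mask[r - r0, c - c0] = brute_force_inside(vertices, c + 0.5, r + 0.5)
    return mask


class TestExtractTrace:
    def _square_frame(self):
        return _frame_with({0: (2.0, 2.0), 1: (14.0, 2.0),
                            2: (14.0, 14.0), 3: (2.0, 14.0)})

    def test_constant_field_mean(self):
        roi = ROIDefinition(1, "medial forehead", (0, 1, 2, 3))
        mesh = [self._square_frame()] * 5
        frames = [np.full((20, 20, 3), 128.0) for _ in range(5)]
        trace = extract_rgb_trace(frames, mesh, roi, 30.0)
        assert trace.valid_mask.all()
        np.testing.assert_allclose(trace.samples, 128.0)

    def test_constant_color_all_28_rois(self, template):
        mesh = [FaceMeshFrame(0, template.points)] * 2
        frames = [np.full((template.height, template.width, 3), 77.0)] * 2
        for roi in load_roi_table():
            trace = extract_rgb_trace(frames, mesh, roi, 30.0)
            np.testing.assert_allclose(trace.samples, 77.0)

    def test_painted_ramp_recovered(self):
        roi = ROIDefinition(1, "medial forehead", (0, 1, 2, 3))
        mesh_frame = self._square_frame()
        mesh = [mesh_frame] * 3
        mask = polygon_mask(mesh_frame, roi, 20, 20).mask
        frames = []
        for red in (100.0, 110.0, 120.0):
            img = np.random.default_rng(1).uniform(0, 255, (20, 20, 3))
            img[mask, 0] = red
            frames.append(img)
        trace = extract_rgb_trace(frames, mesh, roi, 30.0)
        np.testing.assert_allclose(trace.samples[:, 0], [100.0, 110.0, 120.0])

    def test_permutation_of_masked_pixels_preserves_trace(self):
        roi = ROIDefinition(1, "medial forehead", (0, 1, 2, 3))
        mesh_frame = self._square_frame()
        mask = polygon_mask(mesh_frame, roi, 20, 20).mask
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 255, (20, 20, 3))
        shuffled = img.copy()
        idx = np.flatnonzero(mask.ravel())
        perm = rng.permutation(idx)
        shuffled.reshape(-1, 3)[idx] = img.reshape(-1, 3)[perm]
        t1 = extract_rgb_trace([img], [mesh_frame], roi, 30.0)
        t2 = extract_rgb_trace([shuffled], [mesh_frame], roi, 30.0)
        np.testing.assert_allclose(t1.samples, t2.samples)

    def test_offframe_landmarks_marked_invalid(self):
        roi = ROIDefinition(1, "medial forehead", (0, 1, 2, 3))
        good = self._square_frame()
        bad = _frame_with({0: (200.0, 200.0), 1: (214.0, 200.0),
                           2: (214.0, 214.0), 3: (200.0, 214.0)})
        mesh = [good] * 10
        mesh[5] = bad
        frames = [np.full((20, 20, 3), 50.0)] * 10
        trace = extract_rgb_trace(frames, mesh, roi, 30.0)
        assert not trace.valid_mask[5]
        assert trace.valid_mask.sum() == 9

    def test_count_mismatch_raises(self):
        roi = ROIDefinition(1, "medial forehead", (0, 1, 2, 3))
        mesh = [self._square_frame()] * 2
        frames = [np.zeros((20, 20, 3))] * 3
        with pytest.raises(InputError):
            extract_rgb_trace(frames, mesh, roi, 30.0)
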