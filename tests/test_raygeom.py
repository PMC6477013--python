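import numpy as np
import pytest

from kneeseg.raygeom import (
    build_il2di,
    contour_normals,
    extract_contours,
    extract_slice_contours,
    svd_normal,
)
from kneeseg.types import PlanarContour, VoxelGrid


def _disk(shape, center, radius):
    yy, xx = np.indices(shape)
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestContours:
    def test_disk_circumference(self):
        mask = _disk((40, 40), (20, 20), 10)
        contours = extract_slice_contours(mask)
        assert len(contours) == 1
        pts = contours[0]
        closed = np.vstack([pts, pts[:1]])
        length = np.linalg.norm(np.diff(closed, axis=0), axis=1).sum()
        assert length == pytest.approx(2 * np.pi * 10, rel=0.05)

    def test_two_blobs_largest_first(self):
        mask = _disk((60, 60), (18, 18), 12) | _disk((60, 60), (45, 45), 5)
        contours = extract_slice_contours(mask)
        assert len(contours) == 2
        assert len(contours[0]) > len(contours[1])

    def test_single_voxel_blob(self):
        mask = np.zeros((10, 10), bool)
        mask[4, 6] = True
        contours = extract_slice_contours(mask)
        assert len(contours) == 1
        assert len(contours[0]) >= 4
        assert np.allclose(contours[0].mean(axis=0), (4, 6), atol=0.5)

    def test_counterclockwise_and_3d_collection(self):
        mask3d = np.zeros((5, 30, 30), bool)
        mask3d[2] = _disk((30, 30), (15, 15), 8)
        contours = extract_contours(mask3d)
        assert len(contours) == 1 and contours[0].slice_index == 2
        pts = contours[0].points
        area = 0.5 * np.sum(pts[:, 0] * np.roll(pts[:, 1], -1)
                            - np.roll(pts[:, 0], -1) * pts[:, 1])
        assert area > 0


class TestSvdNormals:
    def test_circle_point_normal_is_radial(self):
        theta = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        pts = np.column_stack([5 * np.cos(theta), 5 * np.sin(theta)])
        n = svd_normal(pts, 0, n_neighbors=4)
        assert np.allclose(n, (1.0, 0.0), atol=1e-6)

    def test_straight_segment_normal_perpendicular(self):
        # horizontal run within a closed rectangle-ish contour
        pts = np.array([[0.0, k] for k in range(10)]
                       + [[3.0, k] for k in range(9, -1, -1)])
        n = svd_normal(pts, 5, n_neighbors=2)
        assert abs(n[1]) < 1e-10 and abs(abs(n[0]) - 1.0) < 1e-10
        # outward: away from the centroid (centroid row = 1.5, point row = 0)
        assert n[0] < 0

    def test_ellipse_normals_match_analytic_within_2_degrees(self):
        a, b = 9.0, 5.0
        theta = np.linspace(0, 2 * np.pi, 240, endpoint=False)
        pts = np.column_stack([a * np.cos(theta), b * np.sin(theta)])
        normals = contour_normals(pts, n_neighbors=4)
        analytic = np.column_stack([np.cos(theta) / a, np.sin(theta) / b])
        analytic /= np.linalg.norm(analytic, axis=1, keepdims=True)
        ang = np.degrees(np.arccos(np.clip(np.sum(normals * analytic, axis=1), -1, 1)))
        assert ang.max() < 2.0

    def test_tangent_normal_orthogonal(self):
        theta = np.linspace(0, 2 * np.pi, 80, endpoint=False)
        pts = np.column_stack([7 * np.cos(theta), 4 * np.sin(theta)])
        idx = (np.arange(17 - 4, 17 + 5)) % len(pts)
        m = pts[idx].T - pts[idx].T.mean(axis=1, keepdims=True)
        u, _, _ = np.linalg.svd(m)
        assert abs(np.dot(u[:, 0], u[:, 1])) < 1e-10

    def test_degenerate_neighborhood_raises(self):
        pts = np.tile([[1.0, 1.0]], (10, 1))
        with pytest.raises(ValueError, match="degenerate"):
            svd_normal(pts, 0, 2)

    def test_adjacent_normals_smooth(self):
        mask = _disk((64, 64), (32, 32), 14)
        pts = extract_slice_contours(mask)[0]
        normals = contour_normals(pts, 4)
        cosang = np.sum(normals * np.roll(normals, -1, axis=0), axis=1)
        assert np.degrees(np.arccos(np.clip(cosang, -1, 1))).max() < 30


class TestIl2di:
    def _volume_with_disk(self, radius_vox=12, value=200.0, bg=20.0, n=64, spacing=1.0):
        data = np.full((3, n, n), bg)
        data[:, _disk((n, n), (n // 2, n // 2), radius_vox)] = value
        return VoxelGrid(data, (spacing, spacing, spacing))

    def test_constant_volume_constant_rows(self):
        vol = VoxelGrid(np.full((3, 50, 50), 7.0))
        mask = _disk((50, 50), (25, 25), 10)
        contour = PlanarContour(1, extract_slice_contours(mask)[0])
        il = build_il2di(vol, contour, inward_mm=5, outward_mm=10, step_mm=1.0)
        assert np.allclose(il.rows, 7.0)

    def test_sample_count_and_origin_follow_step_rule(self):
        vol = VoxelGrid(np.zeros((3, 96, 96)), (0.9, 0.9, 0.9))
        mask = _disk((96, 96), (48, 48), 20)
        contour = PlanarContour(1, extract_slice_contours(mask)[0])
        il = build_il2di(vol, contour, inward_mm=15, outward_mm=30, step_mm=0.9)
        # oracle: enumerate the t grid of the stated rule
        n_in = len([t for t in range(1, 1000) if t * 0.9 <= 15])
        n_out = len([t for t in range(1, 1000) if t * 0.9 <= 30])
        assert il.samples_per_row == n_in + n_out + 1
        assert il.origin_column == n_in

    def test_disk_edge_at_expected_column(self):
        vol = self._volume_with_disk(radius_vox=12)
        rough = _disk((64, 64), (32, 32), 9)  # rough contour inside the disk
        contour = PlanarContour(1, extract_slice_contours(rough)[0])
        il = build_il2di(vol, contour, inward_mm=5, outward_mm=10, step_mm=1.0)
        r_contour = np.linalg.norm(contour.points - 32, axis=1).mean()
        expected = il.origin_column + (12 - r_contour)
        drops = [np.argmin(np.diff(row)) for row in il.rows]
        assert np.all(np.abs(np.asarray(drops) - expected) <= 1.5)

    def test_round_trip_row_column_mapping(self):
        vol = self._volume_with_disk()
        mask = _disk((64, 64), (32, 32), 10)
        contour = PlanarContour(1, extract_slice_contours(mask)[0])
        il = build_il2di(vol, contour, inward_mm=5, outward_mm=10, step_mm=1.0)
        for row in range(0, il.n_rays, 7):
            for col in (2, il.origin_column, il.samples_per_row - 2):
                p = il.to_slice_coords(row, col)
                r2, c2 = il.nearest_cell(p)
                assert r2 == row and abs(c2 - col) < 0.5

    def test_out_of_bounds_flagged_nearest_filled(self):
        vol = VoxelGrid(np.full((3, 30, 30), 5.0))
        mask = _disk((30, 30), (15, 15), 10)
        contour = PlanarContour(1, extract_slice_contours(mask)[0])
        il = build_il2di(vol, contour, inward_mm=5, outward_mm=20, step_mm=1.0)
        assert il.oob.any()
        assert np.allclose(il.rows, 5.0)

    def test_rotation_equivariance(self):
        # rotating the slice by 90 degrees rotates all normals by 90 degrees
        mask = np.zeros((64, 64), bool)
        yy, xx = np.indices((64, 64))
        mask[((yy - 32) / 14.0) ** 2 + ((xx - 30) / 8.0) ** 2 <= 1] = True
        pts = extract_slice_contours(mask)[0]
        normals = contour_normals(pts, 4)
        rot_mask = np.rot90(mask).copy()
        rot_pts = extract_slice_contours(rot_mask)[0]
        rot_normals = contour_normals(rot_pts, 4)
        # map original points into the rotated frame: (r, c) -> (N-1-c, r)
        mapped_pts = np.column_stack([63 - pts[:, 1], pts[:, 0]])
        mapped_normals = np.column_stack([-normals[:, 1], normals[:, 0]])
        for i in range(0, len(pts), 11):
            j = np.argmin(np.linalg.norm(rot_pts - mapped_pts[i], axis=1))
            cos = abs(np.dot(rot_normals[j], mapped_normals[i]))
            assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 5
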