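"""Geometric fits, landmark detection, frame construction and measurement."""

import numpy as np
import pytest

from bonessm.anatomy import (
    ARTICULAR_LANDMARK_NAMES,
    CoordinateFrame,
    FitError,
    LandmarkSet,
    articular_face_mask,
    build_frame,
    detect_landmarks,
    fit_circle,
    fit_cylinder,
    measure,
    read_landmarks,
    shaft_direction,
    write_landmarks,
)

from conftest import random_rotation


def cylinder_points(rng, radius=9.0, length=40.0, n=400, noise=0.0):
    axis_dir = rng.normal(size=3)
    axis_dir /= np.linalg.norm(axis_dir)
    u = np.cross(axis_dir, [0.0, 0.0, 1.0])
    if np.linalg.norm(u) < 1e-6:
        u = np.cross(axis_dir, [0.0, 1.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(axis_dir, u)
    t = rng.uniform(-length / 2, length / 2, n)
    theta = rng.uniform(0, 2 * np.pi, n)
    r = radius + rng.normal(scale=noise * radius, size=n)
    center = rng.normal(scale=10, size=3)
    pts = center + np.outer(t, axis_dir) + np.outer(r * np.cos(theta), u) + np.outer(r * np.sin(theta), v)
    return pts, axis_dir, radius, center


class TestFitCylinder:
    def test_exact_recovery(self, rng):
        pts, axis_dir, radius, _ = cylinder_points(rng)
        fit = fit_cylinder(pts)
        assert fit.radius == pytest.approx(radius, abs=1e-6)
        angle = np.arccos(np.clip(abs(fit.direction @ axis_dir), -1, 1))
        assert angle < 1e-6

    def test_radius_within_one_percent_under_radial_noise(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts, _, radius, _ = cylinder_points(rng, noise=0.01)
            fit = fit_cylinder(pts)
            assert abs(fit.radius - radius) / radius < 0.01

    def test_rigid_covariance(self, rng):
        pts, _, _, _ = cylinder_points(rng)
        fit0 = fit_cylinder(pts)
        R = random_rotation(rng)
        t = rng.normal(size=3) * 5
        fit1 = fit_cylinder(pts @ R.T + t)
        assert fit1.radius == pytest.approx(fit0.radius, abs=1e-9)
        assert abs(fit1.direction @ (R @ fit0.direction)) == pytest.approx(1.0, abs=1e-9)

    def test_matches_grid_search_oracle(self, rng):
        # coarse direction grid (5 deg) + analytic radius per direction
        pts, axis_dir, radius, _ = cylinder_points(rng, n=300)
        best = (np.inf, None)
        for az in np.arange(0, np.pi, np.radians(5)):
            for el in np.arange(-np.pi / 2, np.pi / 2, np.radians(5)):
                d = np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])
                c = pts.mean(axis=0)
                rel = pts - c
                radial = np.linalg.norm(rel - np.outer(rel @ d, d), axis=1)
                resid = np.sqrt(np.mean((radial - radial.mean()) ** 2))
                if resid < best[0]:
                    best = (resid, d)
        fit = fit_cylinder(pts)
        assert fit.rms_residual <= best[0] + 1e-9
        assert np.degrees(np.arccos(abs(fit.direction @ best[1]))) < 5.0

    def test_planar_points_rejected(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 100)
        circle = np.column_stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        with pytest.raises(FitError):
            fit_cylinder(circle)

    def test_collinear_points_rejected(self):
        line = np.outer(np.linspace(0, 1, 20), [1.0, 1.0, 0.0])
        with pytest.raises(FitError):
            fit_cylinder(line)


class TestFitCircle:
    def test_three_points_give_the_analytic_circumcircle(self, rng):
        pts = rng.normal(scale=4, size=(3, 2))
        center, radius = fit_circle(pts)
        # closed-form circumcenter
        (ax, ay), (bx, by), (cx, cy) = pts
        d = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
        uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
        assert np.abs(center - [ux, uy]).max() < 1e-12
        assert radius == pytest.approx(np.hypot(ax - ux, ay - uy), abs=1e-12)

    def test_exact_samples_recovered(self):
        theta = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        pts = np.column_stack([1 + 7 * np.cos(theta), 2 + 7 * np.sin(theta)])
        center, radius = fit_circle(pts)
        assert np.abs(center - [1.0, 2.0]).max() < 1e-9
        assert radius == pytest.approx(7.0, abs=1e-9)

    def test_partial_arc_recovered(self):
        theta = np.linspace(0.3, 2.0, 30)
        pts = np.column_stack([5 * np.cos(theta) - 3, 5 * np.sin(theta) + 4])
        center, radius = fit_circle(pts)
        assert radius == pytest.approx(5.0, abs=1e-9)

    def test_collinear_points_rejected(self):
        with pytest.raises(FitError):
            fit_circle(np.column_stack([np.arange(10.0), 2 * np.arange(10.0)]))


class TestDetectLandmarks:
    def test_phantom_ground_truth_within_one_mm(self, template):
        detected = detect_landmarks(template.mesh)
        truth = template.landmarks.all_points()
        for name, p in detected.all_points().items():
            assert np.linalg.norm(p - truth[name]) < 1.0, name

    def test_rigid_equivariance(self, template, rng):
        R = random_rotation(rng)
        t = rng.normal(size=3) * 20
        moved = template.mesh.transformed(R, t)
        lm0 = detect_landmarks(template.mesh).transformed(R, t)
        lm1 = detect_landmarks(moved)
        for name, p in lm1.all_points().items():
            assert np.linalg.norm(p - lm0.all_points()[name]) < 1e-3, name

    def test_detection_on_mirrored_right_side_bone(self, template):
        from bonessm.mesh import Plane, mirror_to_left, reflection_matrix

        plane = Plane(template.mesh.centroid, np.array([1.0, 0.0, 0.0]))
        right = mirror_to_left(template.mesh, plane)  # make a right-sided bone
        lm = detect_landmarks(right, side="right")
        refl = reflection_matrix(plane.normal)
        t = plane.point - refl @ plane.point
        truth = template.landmarks.transformed(refl, t)
        for name, p in lm.all_points().items():
            assert np.linalg.norm(p - truth.all_points()[name]) < 1.0, name

    def test_unlabeled_mesh_rejected(self, template):
        from bonessm.mesh import MeshError, TriangleMesh

        bare = TriangleMesh(template.mesh.vertices, template.mesh.faces)
        with pytest.raises(MeshError):
            detect_landmarks(bare)


class TestBuildFrame:
    def test_orthonormal_right_handed(self, template):
        frame = build_frame(template.landmarks, np.array([0.0, 1.0, 0.0]))
        M = np.stack([frame.x_axis, frame.y_axis, frame.z_axis])
        assert np.abs(M @ M.T - np.eye(3)).max() < 1e-9
        assert np.cross(frame.x_axis, frame.y_axis) @ frame.z_axis > 0

    def test_detected_frame_matches_designed_axes(self, template):
        lm = detect_landmarks(template.mesh)
        frame = build_frame(lm, shaft_direction(template.mesh))
        designed = build_frame(template.landmarks, np.array([0.0, 1.0, 0.0]))
        for name in ("x_axis", "y_axis", "z_axis"):
            cosang = abs(getattr(frame, name) @ getattr(designed, name))
            assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 0.5, name

    def test_rigid_covariance(self, template, rng):
        R = random_rotation(rng)
        t = rng.normal(size=3) * 10
        f0 = build_frame(template.landmarks, np.array([0.0, 1.0, 0.0]))
        f1 = build_frame(template.landmarks.transformed(R, t), R @ np.array([0.0, 1.0, 0.0]))
        assert np.abs(f1.origin - (R @ f0.origin + t)).max() < 1e-9
        for name in ("x_axis", "y_axis", "z_axis"):
            assert np.abs(getattr(f1, name) - R @ getattr(f0, name)).max() < 1e-9

    def test_near_parallel_shaft_rejected(self, template):
        tel = template.landmarks.lateral_epicondyle - template.landmarks.medial_epicondyle
        with pytest.raises(ValueError):
            build_frame(template.landmarks, tel)


@pytest.fixture(scope="module")
def template_measurement(template):
    lm = detect_landmarks(template.mesh)
    frame = build_frame(lm, shaft_direction(template.mesh))
    fmask = articular_face_mask(template.mesh)
    vmask = np.zeros(template.mesh.n_vertices, bool)
    vmask[np.unique(template.mesh.faces[fmask])] = True
    axis = fit_cylinder(template.mesh.vertices[vmask])
    return lm, frame, axis, measure(template.mesh, lm, frame, axis)


class TestMeasure:
    def test_articular_cylinder_axis_matches_design(self, template):
        fmask = articular_face_mask(template.mesh)
        vmask = np.zeros(template.mesh.n_vertices, bool)
        vmask[np.unique(template.mesh.faces[fmask])] = True
        axis = fit_cylinder(template.mesh.vertices[vmask])
        angle = np.degrees(np.arccos(abs(axis.direction @ template.true_axis.direction)))
        assert angle < 0.5

    def test_wtel_recovered_within_half_mm(self, template, template_measurement):
        *_, ms = template_measurement
        assert abs(ms.Wtel - template.designed["Wtel"]) < 0.5

    def test_station_radii_recovered_within_two_percent(self, template, template_measurement):
        *_, ms = template_measurement
        for name in ("R1", "R2", "R3", "R4", "R5", "R6"):
            designed = template.designed[name]
            assert abs(getattr(ms, name) - designed) / designed < 0.02, name

    def test_widths_recovered_within_one_mm(self, template, template_measurement):
        # discretization bias on steep profile flanks dominates these errors
        *_, ms = template_measurement
        for name in ("Wcline", "Wcap", "MT_width", "LT_width", "Wtro"):
            assert abs(getattr(ms, name) - template.designed[name]) < 1.0, name

    def test_angles_recovered(self, template, template_measurement):
        *_, ms = template_measurement
        assert abs(ms.ATC - template.designed["ATC"]) < 1.0
        # Agro is ill-conditioned (short origin-to-groove lever), so looser
        assert abs(ms.Agro - template.designed["Agro"]) < 5.0

    def test_ratios_equal_quotients_of_components(self, template_measurement):
        *_, ms = template_measurement
        assert ms.RT == ms.MT_width / ms.LT_width
        assert ms.RTC == ms.Wtro / ms.Wcap

    def test_stations_ordered_along_axis(self, template):
        from bonessm.anatomy import articular_stations

        fmask = articular_face_mask(template.mesh)
        st, sr, _ = articular_stations(template.mesh, template.true_axis, fmask)
        assert (np.diff(st) > 0).all()

    def test_rigid_invariance(self, template, template_measurement, rng):
        lm, frame, axis, ms0 = template_measurement
        R = random_rotation(rng)
        t = rng.normal(size=3) * 15
        moved_mesh = template.mesh.transformed(R, t)
        moved_lm = lm.transformed(R, t)
        moved_frame = CoordinateFrame(R @ frame.origin + t, R @ frame.x_axis, R @ frame.y_axis, R @ frame.z_axis)
        from bonessm.anatomy import ArticularAxis

        moved_axis = ArticularAxis(R @ axis.point + t, R @ axis.direction, axis.radius)
        ms1 = measure(moved_mesh, moved_lm, moved_frame, moved_axis)
        for name, v0 in ms0.as_dict().items():
            assert getattr(ms1, name) == pytest.approx(v0, abs=1e-6), name


class TestLandmarkIO:
    def test_round_trip(self, template, tmp_path):
        p = tmp_path / "lm.txt"
        write_landmarks(template.landmarks, p)
        back = read_landmarks(p)
        for name, v in template.landmarks.all_points().items():
            assert np.abs(back.all_points()[name] - v).max() < 1e-5

    def test_missing_landmark_rejected(self, tmp_path):
        (tmp_path / "bad.txt").write_text("medial_epicondyle 0 0 0\n")
        with pytest.raises(ValueError):
            read_landmarks(tmp_path / "bad.txt")

    def test_coincident_epicondyles_rejected(self):
        with pytest.raises(ValueError):
            LandmarkSet(np.zeros(3), np.zeros(3), np.ones(3), np.ones(3), {})
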