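"""Articular patch extraction, landmark registration and distance summaries."""

import numpy as np
import pytest

from bonessm.articular import (
    DistanceSummary,
    distance_summary,
    extract_articular,
    mode_difference_report,
    register_articular,
)
from bonessm.correspondence import correspondence_from_population
from bonessm.mesh import MeshError, TriangleMesh
from bonessm.model import StatisticalShapeModel
from bonessm.phantom import PopulationModel, sample_population

from conftest import random_rotation


def planar_patch(nx, ny, spacing=1.0, z=0.0):
    xs, ys = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing)
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.full(nx * ny, z)])
    faces = []
    for j in range(ny - 1):
        for i in range(nx - 1):
            a = j * nx + i
            faces.append([a, a + 1, a + nx])
            faces.append([a + 1, a + nx + 1, a + nx])
    return TriangleMesh(verts, np.array(faces))


class TestExtract:
    def test_fully_labeled_mesh_is_returned_whole(self, small_template):
        mesh = small_template.mesh
        labeled = TriangleMesh(mesh.vertices, mesh.faces, np.full(mesh.n_vertices, "articular"))
        patch = extract_articular(labeled)
        assert patch.n_faces == mesh.n_faces

    def test_patch_vertices_subset_of_source(self, small_template):
        patch = extract_articular(small_template.mesh)
        src = {tuple(v) for v in np.round(small_template.mesh.vertices, 9)}
        assert all(tuple(v) in src for v in np.round(patch.vertices, 9))

    def test_no_labels_raises(self, small_template):
        bare = TriangleMesh(small_template.mesh.vertices, small_template.mesh.faces)
        with pytest.raises(MeshError):
            extract_articular(bare)

    def test_patch_is_connected(self, small_template):
        import trimesh.graph

        patch = extract_articular(small_template.mesh)
        comps = trimesh.graph.connected_components(patch.to_trimesh().edges, min_len=1)
        assert len(comps) == 1

    def test_patch_area_matches_analytic_quadrature(self, template):
        # the exposed articular surface area by direct quadrature of the
        # designed solid of revolution under the same labeling rule
        from bonessm.phantom import _Geometry

        geom = _Geometry(template.spec)
        L = geom.half
        xs = np.linspace(-L, L, 800)
        thetas = np.linspace(-np.pi, np.pi, 720, endpoint=False)
        X, TH = np.meshgrid(xs, thetas, indexing="ij")
        rho = geom.profile(X.ravel() + L).reshape(X.shape)
        drho = np.gradient(geom.profile(xs + L), xs)
        pts = np.column_stack([X.ravel(), (rho * np.cos(TH)).ravel(), (rho * np.sin(TH)).ravel()])
        exposed = (geom.union_fields(pts).argmax(axis=0) == 0).reshape(X.shape)
        dA = rho * np.sqrt(1 + drho[:, None] ** 2) * (xs[1] - xs[0]) * (thetas[1] - thetas[0])
        analytic = float((dA * exposed).sum())
        mesh_area = extract_articular(template.mesh).area
        assert abs(mesh_area - analytic) / analytic < 0.05


class TestRegister:
    def test_identity_for_identical_landmarks(self, small_template):
        patch = extract_articular(small_template.mesh)
        lms = small_template.landmarks.registration_points()
        out = register_articular(patch, lms, lms)
        assert np.abs(out.vertices - patch.vertices).max() < 1e-12

    def test_exact_recovery_of_rigid_motion(self, small_template, rng):
        patch = extract_articular(small_template.mesh)
        lms = small_template.landmarks.registration_points()
        R = random_rotation(rng)
        t = rng.normal(size=3) * 8
        moved = patch.transformed(R, t)
        out = register_articular(moved, lms @ R.T + t, lms)
        assert np.abs(out.vertices - patch.vertices).max() < 1e-9

    def test_scaling_is_not_removed(self, small_template):
        patch = extract_articular(small_template.mesh)
        lms = small_template.landmarks.registration_points()
        scaled = TriangleMesh(patch.vertices * 1.1, patch.faces)
        out = register_articular(scaled, lms * 1.1, lms)
        summary = distance_summary(patch, out)
        assert summary.rms > 0.1  # the size difference survives registration


class TestDistanceSummary:
    def test_identical_patches_are_all_zero(self, small_template):
        patch = extract_articular(small_template.mesh)
        s = distance_summary(patch, patch)
        assert s.d_min == s.d_max == s.median == s.mean == s.sd == s.rms == 0.0

    def test_planar_offset_gives_exactly_one_mm(self):
        source = planar_patch(5, 5, spacing=2.0, z=1.0)  # interior of a larger target
        target = planar_patch(11, 11, spacing=2.0, z=0.0)
        target = TriangleMesh(target.vertices - [6.0, 6.0, 0.0], target.faces)
        s = distance_summary(source, target)
        assert s.d_min == pytest.approx(1.0, abs=1e-12)
        assert s.d_max == pytest.approx(1.0, abs=1e-12)
        assert s.mean == s.median == s.rms == pytest.approx(1.0, abs=1e-12)
        assert s.sd == pytest.approx(0.0, abs=1e-12)

    def test_rms_at_least_mean(self, rng):
        a = planar_patch(6, 6)
        b = TriangleMesh(a.vertices + rng.normal(scale=0.5, size=a.vertices.shape), a.faces)
        s = distance_summary(a, b)
        assert s.rms >= s.mean
        # sample-SD identity: rms^2 = mean^2 + sd^2 (n-1)/n
        assert s.rms**2 == pytest.approx(s.mean**2 + s.sd**2 * (s.n_points - 1) / s.n_points, rel=1e-9)

    def test_invariant_under_common_rigid_motion(self, small_template, rng):
        patch = extract_articular(small_template.mesh)
        other = TriangleMesh(patch.vertices * 1.02, patch.faces)
        s0 = distance_summary(patch, other)
        R = random_rotation(rng)
        t = rng.normal(size=3) * 5
        s1 = distance_summary(patch.transformed(R, t), other.transformed(R, t))
        assert s1.rms == pytest.approx(s0.rms, abs=1e-9)
        assert s1.d_max == pytest.approx(s0.d_max, abs=1e-9)

    def test_pure_rigid_motion_fully_explained_by_registration(self, small_template, rng):
        patch = extract_articular(small_template.mesh)
        lms = small_template.landmarks.registration_points()
        R = random_rotation(rng)
        t = rng.normal(size=3) * 10
        moved = patch.transformed(R, t)
        registered = register_articular(moved, lms @ R.T + t, lms)
        assert distance_summary(patch, registered).rms < 1e-9

    def test_ordering_invariant_enforced(self):
        with pytest.raises(ValueError):
            DistanceSummary(d_min=1.0, d_max=0.5, median=0.7, mean=0.7, sd=0.1, rms=0.8, n_points=5)


class TestModeDifferenceReport:
    @pytest.fixture(scope="class")
    def fitted_single_mode(self, small_template):
        # population whose only latent mode is uniform scaling
        model = PopulationModel(small_template, mode_names=("size",), mode_sds=(2.3,), noise_sd=0.05)
        bundles = sample_population(model, 12, seed=3)
        cs = correspondence_from_population(bundles, small_template)
        return StatisticalShapeModel.from_correspondence(cs).fit()

    def test_zero_multiplier_gives_all_zero_rows(self, fitted_single_mode):
        report = mode_difference_report(fitted_single_mode, k_max=2, c=0.0)
        assert (report["RMS (mm)"] == 0.0).all()
        assert (report["Mean (mm)"] == 0.0).all()

    def test_schema(self, fitted_single_mode):
        report = mode_difference_report(fitted_single_mode, k_max=3, c=3.0)
        assert len(report) == 6
        assert list(report.columns) == ["Range (mm)", "Median (mm)", "Mean (mm)", "Std Deviation (mm)", "RMS (mm)"]
        assert report.index[0] == "PC1 + 3SD"
        assert report.index[1] == "PC1 - 3SD"

    def test_size_mode_dominates_articular_differences(self, fitted_single_mode):
        report = mode_difference_report(fitted_single_mode, k_max=3, c=3.0)
        rms = report["RMS (mm)"].to_numpy()
        pc1 = rms[:2].min()
        others = rms[2:].max()
        assert pc1 > 3 * others  # the size mode dwarfs the noise modes

    def test_missing_labels_rejected(self, rng):
        shapes = rng.normal(size=(4, 30))
        res = StatisticalShapeModel(shapes).fit()
        with pytest.raises(MeshError):
            mode_difference_report(res, k_max=1)
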