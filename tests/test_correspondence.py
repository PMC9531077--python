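"""Rigid/non-rigid registration and correspondence building."""

import numpy as np
import pytest

from bonessm.anatomy import ARTICULAR_LANDMARK_NAMES
from bonessm.correspondence import (
    ICPConfig,
    MorphConfig,
    RegistrationError,
    RigidTransform,
    build_correspondence_set,
    icp_refine,
    nonrigid_morph,
    procrustes_rigid,
)
from bonessm.mesh import TriangleMesh

from conftest import random_rotation


def landmark_arrays(template):
    names = list(template.landmark_vertex_indices.keys())
    idx = np.array([template.landmark_vertex_indices[n] for n in names])
    init_rows = [names.index(n) for n in list(ARTICULAR_LANDMARK_NAMES) + ["fossa_vertex"]]
    return names, idx, init_rows


class TestProcrustes:
    def test_identity_when_already_aligned(self, rng):
        pts = rng.normal(size=(8, 3))
        tr = procrustes_rigid(pts, pts)
        assert np.abs(tr.rotation - np.eye(3)).max() < 1e-12
        assert np.abs(tr.translation).max() < 1e-12

    def test_exact_recovery_of_known_rigid_motion(self, rng):
        pts = rng.normal(size=(10, 3)) * 5
        R = random_rotation(rng)
        t = np.array([3.0, -2.0, 7.0])
        tr = procrustes_rigid(pts, pts @ R.T + t)
        rmsd = np.sqrt(((tr.apply(pts) - (pts @ R.T + t)) ** 2).sum(axis=1).mean())
        assert rmsd < 1e-9

    def test_mirror_image_gets_best_proper_rotation(self, rng):
        # reflections are excluded by construction, so the residual is > 0
        # and strictly worse than the unconstrained orthogonal fit
        from scipy.linalg import orthogonal_procrustes

        pts = rng.normal(size=(12, 3)) * 4
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        tr = procrustes_rigid(pts, mirrored)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0, abs=1e-9)
        resid = np.linalg.norm(tr.apply(pts) - mirrored)
        c0 = pts - pts.mean(axis=0)
        c1 = mirrored - mirrored.mean(axis=0)
        R_any, _ = orthogonal_procrustes(c0, c1)
        resid_any = np.linalg.norm(c0 @ R_any - c1)
        assert resid > resid_any  # the oracle may reflect; we must not
        assert resid > 1e-6

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(RegistrationError):
            procrustes_rigid(line, line)

    def test_reflection_rejected_in_transform_constructor(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))


class TestICP:
    def test_identical_meshes_give_identity(self, small_template):
        mesh = small_template.mesh
        tr = icp_refine(mesh, mesh, config=ICPConfig(max_iter=5))
        assert np.abs(tr.rotation - np.eye(3)).max() < 1e-6
        assert np.abs(tr.translation).max() < 1e-6

    def test_recovers_small_rigid_perturbation(self, small_template, rng):
        mesh = small_template.mesh
        angle = np.radians(5.0)
        R = np.array(
            [[np.cos(angle), -np.sin(angle), 0], [np.sin(angle), np.cos(angle), 0], [0, 0, 1]]
        )
        t = np.array([2.0, 0.5, -1.0])
        target = mesh.transformed(R, t)
        tr = icp_refine(mesh, target, config=ICPConfig(max_iter=60))
        moved = tr.apply(mesh.vertices)
        assert np.linalg.norm(moved - target.vertices, axis=1).mean() < 1e-3

    def test_max_iter_zero_returns_init(self, small_template):
        init = RigidTransform(np.eye(3), np.array([1.0, 2.0, 3.0]))
        tr = icp_refine(small_template.mesh, small_template.mesh, init, ICPConfig(max_iter=0))
        assert tr is init

    def test_no_pairs_under_gate_raises(self, small_template):
        far = small_template.mesh.transformed(np.eye(3), [500.0, 0.0, 0.0])
        with pytest.raises(RegistrationError):
            icp_refine(small_template.mesh, far, config=ICPConfig(max_pair_dist_mm=1.0))


class TestNonrigidMorph:
    def test_self_morph_is_identity(self, small_template):
        mesh = small_template.mesh
        morphed, resid = nonrigid_morph(mesh, mesh)
        assert np.abs(morphed.vertices - mesh.vertices).max() < 1e-6
        assert resid < 1e-6

    def test_topology_is_preserved_bitwise(self, small_template):
        mesh = small_template.mesh
        morphed, _ = nonrigid_morph(mesh, mesh)
        assert np.array_equal(morphed.faces, mesh.faces)

    def test_recovers_known_affine_deformation(self, small_template):
        mesh = small_template.mesh
        _, lm_idx, _ = landmark_arrays(small_template)
        A = np.array([[1.06, 0.02, 0.0], [0.0, 0.97, 0.03], [0.01, 0.0, 1.04]])
        gt = mesh.vertices @ A.T + [1.0, -2.0, 0.5]
        target = TriangleMesh(gt, mesh.faces)
        morphed, resid = nonrigid_morph(mesh, target, landmark_pairs=(lm_idx, gt[lm_idx]))
        err = np.linalg.norm(morphed.vertices - gt, axis=1)
        assert resid < 0.05
        assert err.mean() < 0.5

    def test_phantom_correspondence_error(self, noise_free_population):
        # recovery of known smooth deformation fields (noise-free ground truth)
        model, bundles = noise_free_population
        tmpl = model.template
        names, lm_idx, init_rows = landmark_arrays(tmpl)
        errs = []
        for b in bundles[:5]:
            target = TriangleMesh(b.left_vertices, tmpl.mesh.faces)
            morphed, _ = nonrigid_morph(
                tmpl.mesh,
                target,
                landmark_pairs=(lm_idx, b.left_vertices[lm_idx]),
                init_landmark_pairs=(lm_idx[init_rows], b.left_vertices[lm_idx[init_rows]]),
            )
            errs.append(np.linalg.norm(morphed.vertices - b.left_vertices, axis=1).mean())
        assert np.mean(errs) < 0.5

    def test_rigid_equivariance(self, small_template, rng):
        # morphing to a rotated target gives the rotated morph
        model_mesh = small_template.mesh
        _, lm_idx, _ = landmark_arrays(small_template)
        scale = 1.04
        gt = model_mesh.vertices * scale
        target = TriangleMesh(gt, model_mesh.faces)
        m0, _ = nonrigid_morph(model_mesh, target, landmark_pairs=(lm_idx, gt[lm_idx]))
        R = random_rotation(rng)
        t = np.array([4.0, -1.0, 2.0])
        target_moved = TriangleMesh(gt @ R.T + t, model_mesh.faces)
        tmpl_moved = model_mesh.transformed(R, t)
        m1, _ = nonrigid_morph(tmpl_moved, target_moved, landmark_pairs=(lm_idx, gt[lm_idx] @ R.T + t))
        assert np.abs(m1.vertices - (m0.vertices @ R.T + t)).max() < 1e-3


class TestBuildCorrespondenceSet:
    def test_identical_targets_give_identical_rows(self, small_template):
        mesh = small_template.mesh
        cs = build_correspondence_set(mesh, [mesh, mesh])
        assert cs.n_shapes == 2
        assert np.abs(cs.shapes[0] - cs.shapes[1]).max() < 1e-6
        assert (cs.residuals < 1e-6).all()
        assert np.abs(cs.shapes[0] - mesh.vertices.ravel()).max() < 1e-6

    def test_phantom_population_residuals(self, small_population):
        model, bundles = small_population
        tmpl = model.template
        names = list(tmpl.landmark_vertex_indices.keys())
        faces = tmpl.mesh.faces
        targets = [TriangleMesh(b.left_vertices, faces, tmpl.mesh.vertex_labels) for b in bundles]
        t_lms = [
            np.array([w @ b.left_vertices[faces[f]] for (f, w) in (b.landmark_barycentric[n] for n in names)])
            for b in bundles
        ]
        tmpl_lms = np.array(
            [w @ tmpl.mesh.vertices[faces[f]] for (f, w) in (tmpl.landmark_barycentric[n] for n in names)]
        )
        init_rows = [names.index(n) for n in list(ARTICULAR_LANDMARK_NAMES) + ["fossa_vertex"]]
        cs = build_correspondence_set(
            tmpl.mesh,
            targets,
            template_landmarks=tmpl_lms,
            target_landmarks=t_lms,
            init_landmark_rows=init_rows,
        )
        assert cs.n_shapes == len(bundles)
        assert (cs.residuals < 0.3).all()
        assert cs.sample_ids == [f"shape_{i:03d}" for i in range(len(bundles))]

    def test_lenient_mode_records_failures(self, small_template):
        mesh = small_template.mesh
        broken = TriangleMesh(np.eye(3) * 1e4, np.array([[0, 1, 2]]))
        cs = build_correspondence_set(mesh, [mesh, broken, mesh], strict=False)
        assert cs.n_shapes == 2
        assert len(cs.excluded) == 1
        assert cs.excluded[0]["sample_id"] == "shape_001"

    def test_strict_mode_raises_with_specimen_name(self, small_template):
        mesh = small_template.mesh
        broken = TriangleMesh(np.eye(3) * 1e4, np.array([[0, 1, 2]]))
        with pytest.raises(RegistrationError, match="shape_001"):
            build_correspondence_set(mesh, [mesh, broken], strict=True)

    def test_save_load_round_trip(self, small_template, tmp_path):
        mesh = small_template.mesh
        cs = build_correspondence_set(mesh, [mesh, mesh])
        cs.save(tmp_path / "cs")
        from bonessm.correspondence import CorrespondenceSet

        back = CorrespondenceSet.load(tmp_path / "cs")
        assert np.allclose(back.shapes, cs.shapes)
        assert np.array_equal(back.template_faces, cs.template_faces)
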