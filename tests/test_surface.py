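import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cardiotwin import contours as ct
from cardiotwin import core_io as cio
from cardiotwin import phantom as ph
from cardiotwin import surface as sf
from cardiotwin.core_io import CineView
from cardiotwin.meshes import SurfaceMesh, point_surface_distance


def _sample_contours_from_surface(mesh, rng, structures=None, n=400):
    """Pseudo-contours: surface vertex samples tagged by region."""
    structures = structures or {ct.LV_ENDO: sf.LV_ENDO_S,
                                ct.LV_EPI: sf.LV_EPI_S,
                                ct.RV_SEPTUM: sf.RV_SEPTUM_S,
                                ct.RV_FW: sf.RV_FW_S}
    out = []
    for tag, region in structures.items():
        ids = mesh.region_vertex_ids(region)
        pick = rng.choice(ids, size=min(n, len(ids)), replace=False)
        out.append(ct.Contour(structure=tag, points=mesh.vertices[pick],
                              points_px=np.zeros((len(pick), 2)),
                              view=CineView.SAX, frame=0))
    return out


class TestUmeyama:
    def test_identity(self, template):
        s, R, t, rms = sf.umeyama(template.vertices, template.vertices)
        assert s == pytest.approx(1.0)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        assert rms < 1e-9

    def test_known_similarity_recovered(self, template):
        rng = np.random.default_rng(0)
        R0 = Rotation.from_euler("xyz", [30, -10, 55], degrees=True).as_matrix()
        src = template.vertices
        dst = 1.3 * src @ R0.T + np.array([5.0, -8.0, 2.0])
        s, R, t, rms = sf.umeyama(src, dst)
        assert s == pytest.approx(1.3, abs=1e-9)
        np.testing.assert_allclose(R, R0, atol=1e-9)
        assert rms < 1e-8


class TestAlignTemplate:
    def _landmark_sets(self, template, transform=None):
        sets = {}
        for key, vid in template.landmarks.items():
            view, name = key.split(":")
            p = template.vertices[vid]
            if transform is not None:
                p = transform(p)
            sets.setdefault(view, {})[name] = p
        return {CineView(v): ct.LandmarkSet(points=pts, view=CineView(v),
                                            frame=0)
                for v, pts in sets.items()}

    def test_identity_when_landmarks_match(self, template):
        s, R, t, rms = sf.align_template(template,
                                         self._landmark_sets(template))
        assert rms < 1e-9
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)

    def test_rotation_translation_recovered(self, template):
        R0 = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        t0 = np.array([10.0, -4.0, 3.0])
        sets = self._landmark_sets(template, lambda p: R0 @ p + t0)
        s, R, t, rms = sf.align_template(template, sets)
        np.testing.assert_allclose(R, R0, atol=1e-9)
        np.testing.assert_allclose(t, t0, atol=1e-8)
        assert rms < 1e-9

    def test_too_few_landmarks_rejected(self, template):
        lone = ct.LandmarkSet(points={"MV_1": np.zeros(3),
                                      "MV_2": np.ones(3)},
                              view=CineView.LAX2CH, frame=0)
        with pytest.raises(ValueError):
            sf.align_template(template, {CineView.LAX2CH: lone})


class TestFit:
    def test_self_fit_reaches_data(self, template):
        rng = np.random.default_rng(1)
        contours = _sample_contours_from_surface(template, rng)
        res = sf.fit_surface(template, contours, {},
                             sf.FitConfig(smooth_weight=0.05,
                                          n_iterations=20, tol=1e-9))
        pts = np.concatenate([c.points for c in contours])
        d = point_surface_distance(pts, res.mesh.vertices, res.mesh.faces)
        assert d.mean() < 0.1

    def test_objective_non_increasing(self, template):
        rng = np.random.default_rng(2)
        contours = _sample_contours_from_surface(template, rng)
        for c in contours:
            c.points = c.points * 1.1 + rng.normal(0, 0.5, c.points.shape)
        res = sf.fit_surface(template, contours, {},
                             sf.FitConfig(n_iterations=12))
        trace = np.array(res.objective_trace)
        assert np.all(np.diff(trace) <= 1e-6 * np.maximum(trace[:-1], 1))

    def test_scaled_template_volume_recovered(self, template):
        """Contours from a 1.2x template drive the volume to ~1.2^3."""
        rng = np.random.default_rng(3)
        scaled = template.copy()
        scaled.vertices = scaled.vertices * 1.2
        contours = _sample_contours_from_surface(scaled, rng, n=600)
        res = sf.fit_surface_multiscale(template, contours, {},
                                        correct_slices=False)
        v_fit = res.mesh.enclosed_volume(sf.LV_ENDO_S, sf.MV_RING, sf.AO_RING)
        v_tmpl = template.enclosed_volume(sf.LV_ENDO_S, sf.MV_RING, sf.AO_RING)
        assert v_fit / v_tmpl == pytest.approx(1.2 ** 3, rel=0.05)

    def test_infinite_smoothness_freezes_shape(self, template):
        rng = np.random.default_rng(4)
        contours = _sample_contours_from_surface(template, rng)
        for c in contours:
            c.points = c.points + np.array([3.0, 0, 0])
        res = sf.fit_surface(template, contours, {},
                            sf.FitConfig(smooth_weight=1e9, n_iterations=5))
        d = np.linalg.norm(res.mesh.vertices - template.vertices, axis=1)
        # displacement field collapses toward rigid-like (here: tiny) motion
        assert d.std() < 0.1

    def test_missing_lv_contours_rejected(self, template):
        with pytest.raises(ValueError):
            sf.fit_surface(template, [], {})

    def test_rigid_equivariance(self, template):
        """Fits of rigidly transformed data differ by that transform."""
        rng = np.random.default_rng(5)
        contours = _sample_contours_from_surface(template, rng, n=500)
        for c in contours:
            c.points = c.points * 1.1
        res_a = sf.fit_surface_multiscale(template, contours, {},
                                          correct_slices=False)
        R0 = Rotation.from_euler("xyz", [20, 35, -10], degrees=True).as_matrix()
        t0 = np.array([8.0, 3.0, -5.0])
        moved = []
        for c in contours:
            moved.append(ct.Contour(structure=c.structure,
                                    points=c.points @ R0.T + t0,
                                    points_px=c.points_px, view=c.view,
                                    frame=0))
        tmpl_moved = template.copy()
        tmpl_moved.vertices = template.vertices @ R0.T + t0
        res_b = sf.fit_surface_multiscale(tmpl_moved, moved, {},
                                          correct_slices=False)
        back = (res_b.mesh.vertices - t0) @ R0
        disc = np.linalg.norm(back - res_a.mesh.vertices, axis=1)
        assert disc.max() < 0.5


class TestMisalignmentCorrection:
    def _phantom_contours(self, sd, seed):
        params = ph.PhantomParams(n_frames=2, es_frame=1,
                                  misalignment_sd=sd, seed=seed)
        st = ph.make_phantom(params)
        contours = []
        for view in CineView:
            cs, _, _ = ct.extract_view(st.bundle.get(view), 0)
            contours.extend(cs)
        return st, contours

    def test_zero_misalignment_small_shifts(self, template):
        st, contours = self._phantom_contours(0.0, 0)
        groups = sf.group_contours_by_slice(contours)
        shifts = sf.correct_misalignment(groups, template)
        for v in shifts.values():
            assert np.linalg.norm(v) < 0.9  # below half an in-plane voxel

    def test_known_shift_recovered(self, template):
        st, contours = self._phantom_contours(2.0, 3)
        groups = sf.group_contours_by_slice(contours)
        shifts = sf.correct_misalignment(groups, template)
        # pick the SAX slice with the largest applied shift
        applied = {k: v for k, v in st.shifts.items()
                   if k[0] == "SAX" and k in shifts}
        worst = max(applied, key=lambda k: np.hypot(*applied[k]))
        drow, dcol = applied[worst]
        # applied (row, col) displacements map to world (y, x) in-plane
        rec = shifts[(worst[0], worst[1])]
        np.testing.assert_allclose(rec[:2], (-dcol, -drow), atol=1.0)

    def test_shift_cap_respected(self, template):
        st, contours = self._phantom_contours(0.0, 0)
        for c in contours:
            c.points = c.points + np.array([40.0, 0, 0])
        groups = sf.group_contours_by_slice(contours)
        shifts = sf.correct_misalignment(groups, template, shift_cap=10.0)
        for v in shifts.values():
            assert np.linalg.norm(v) <= 10.0 + 1e-9


class TestRVEpicardium:
    def _hemi_patch(self, a=35.0, b=25.0, c=50.0, n_long=24, n_circ=48):
        phis = np.linspace(0.05, np.pi / 2, n_long)
        ths = 2 * np.pi * np.arange(n_circ) / n_circ
        verts = [np.array([0.0, 0.0, -c])]
        rings = []
        for phi in phis:
            ring = []
            for th in ths:
                ring.append(len(verts))
                verts.append(np.array([a * np.sin(phi) * np.cos(th),
                                       b * np.sin(phi) * np.sin(th),
                                       -c * np.cos(phi)]))
            rings.append(ring)
        faces = [[0, rings[0][j], rings[0][(j + 1) % n_circ]]
                 for j in range(n_circ)]
        for i in range(n_long - 2):
            for j in range(n_circ):
                j2 = (j + 1) % n_circ
                faces += [[rings[i][j], rings[i][j2], rings[i + 1][j2]],
                          [rings[i][j], rings[i + 1][j2], rings[i + 1][j]]]
        faces = np.array(faces)
        return SurfaceMesh(np.array(verts), faces,
                           np.full(len(faces), sf.RV_FW_S))

    def test_hemi_ellipsoid_offset_distance(self):
        patch = self._hemi_patch()
        out = sf.generate_rv_epicardium(patch, thickness=3.0)
        ids = out.region_vertex_ids(sf.RV_EPI_S)
        d = point_surface_distance(out.vertices[ids], out.vertices,
                                   out.region_faces(sf.RV_FW_S))
        assert d.mean() == pytest.approx(3.0, abs=0.1)

    def test_zero_thickness_coincides(self, template):
        out = sf.generate_rv_epicardium(template, thickness=0.0)
        remap = out.provenance["rv_epi_map"]
        src = np.array(sorted(remap))
        dst = np.array([remap[i] for i in sorted(remap)])
        np.testing.assert_allclose(out.vertices[dst], out.vertices[src],
                                   atol=1e-12)

    def test_sphere_offset_exact(self):
        import trimesh
        ico = trimesh.creation.icosphere(3, radius=10.0)
        mesh = SurfaceMesh(ico.vertices, ico.faces,
                           np.full(len(ico.faces), sf.RV_FW_S))
        out = sf.generate_rv_epicardium(mesh, thickness=3.0)
        ids = out.region_vertex_ids(sf.RV_EPI_S)
        r = np.linalg.norm(out.vertices[ids], axis=1)
        # averaged vertex normals of an icosphere are radial to ~1e-4
        np.testing.assert_allclose(r, 13.0, atol=1e-3)

    def test_missing_rv_rejected(self):
        import trimesh
        ico = trimesh.creation.icosphere(1, radius=5.0)
        mesh = SurfaceMesh(ico.vertices, ico.faces,
                           np.full(len(ico.faces), sf.LV_ENDO_S))
        with pytest.raises(ValueError):
            sf.generate_rv_epicardium(mesh)
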