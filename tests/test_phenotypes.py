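import numpy as np
import pytest
import trimesh

from cardiotwin import core_io as cio
from cardiotwin import phenotypes as phe
from cardiotwin import surface as sf
from cardiotwin.core_io import CineView, DEFAULT_SCHEMES, SegmentationSeries
from cardiotwin.meshes import SurfaceMesh


class TestSegVolumes:
    def test_count_times_voxel_volume(self):
        data = np.zeros((2, 10, 10, 1), dtype=np.int16)
        data[0, :5, :10, 0] = 1  # 50 voxels
        data[1, :5, :10, 0] = 1  # 50 voxels
        aff = np.diag([8.0, 1.8, 1.8, 1.0])
        series = SegmentationSeries(data, aff, DEFAULT_SCHEMES[CineView.SAX],
                                    CineView.SAX)
        assert phe.seg_volumes(series, 0, cio.LV_CAVITY) == \
            pytest.approx(100 * 25.92 / 1000)

    def test_empty_structure_zero(self):
        data = np.zeros((1, 4, 4, 1), dtype=np.int16)
        series = SegmentationSeries(data, np.eye(4),
                                    DEFAULT_SCHEMES[CineView.SAX],
                                    CineView.SAX)
        assert phe.seg_volumes(series, 0, cio.LV_CAVITY) == 0.0

    def test_additive_over_disjoint_sets(self, phantom_study):
        sax = phantom_study.bundle.get(CineView.SAX)
        whole = phe.seg_volumes(sax, 0, cio.LV_CAVITY)
        parts = 0.0
        for label, struct in ((1, cio.LV_CAVITY),):
            half_a = SegmentationSeries(
                np.where(np.arange(sax.data.shape[0])[:, None, None, None]
                         < 5, sax.data, 0), sax.affine, sax.scheme,
                CineView.SAX)
            half_b = SegmentationSeries(
                np.where(np.arange(sax.data.shape[0])[:, None, None, None]
                         >= 5, sax.data, 0), sax.affine, sax.scheme,
                CineView.SAX)
            parts = (phe.seg_volumes(half_a, 0, struct)
                     + phe.seg_volumes(half_b, 0, struct))
        assert parts == pytest.approx(whole)

    def test_phantom_lv_near_truth(self, phantom_study):
        sax = phantom_study.bundle.get(CineView.SAX)
        seg = phe.seg_volumes(sax, 0, cio.LV_CAVITY)
        assert seg == pytest.approx(phantom_study.lv_cavity_ml[0], rel=0.12)

    def test_frame_out_of_range(self, phantom_study):
        sax = phantom_study.bundle.get(CineView.SAX)
        with pytest.raises(IndexError):
            phe.seg_volumes(sax, 99, cio.LV_CAVITY)


class TestLVMass:
    def test_reference_value(self):
        assert phe.lv_mass(88.0) == pytest.approx(92.4)

    def test_zero(self):
        assert phe.lv_mass(0.0) == 0.0

    def test_density_ratio_constant(self):
        for v in (10.0, 55.5, 200.0):
            assert phe.lv_mass(v) / v == pytest.approx(1.05)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            phe.lv_mass(-1.0)


class TestMeshVolumes:
    def test_cube_cavity_exact(self):
        box = trimesh.creation.box(extents=(10, 10, 10))
        mesh = SurfaceMesh(box.vertices, box.faces,
                           np.full(len(box.faces), sf.LV_ENDO_S))
        assert mesh.enclosed_volume(sf.LV_ENDO_S) == pytest.approx(1000.0)

    def test_sphere_within_two_percent(self):
        ico = trimesh.creation.icosphere(3, radius=10.0)
        mesh = SurfaceMesh(ico.vertices, ico.faces,
                           np.full(len(ico.faces), sf.LV_ENDO_S))
        assert mesh.enclosed_volume(sf.LV_ENDO_S) == \
            pytest.approx(4 / 3 * np.pi * 1000, rel=0.02)

    def test_rigid_invariance(self, template):
        from scipy.spatial.transform import Rotation
        v0 = phe.mesh_volumes(sf.generate_rv_epicardium(template))
        moved = template.copy()
        R = Rotation.from_euler("xyz", [9, 77, -13], degrees=True).as_matrix()
        moved.vertices = moved.vertices @ R.T + np.array([10.0, 2.0, 3.0])
        v1 = phe.mesh_volumes(sf.generate_rv_epicardium(moved))
        for k in v0:
            assert v1[k] == pytest.approx(v0[k], rel=1e-6)

    def test_open_cavity_rejected(self, template):
        broken = template.copy()
        keep = broken.face_region != sf.MV_RING
        broken.faces = broken.faces[keep]
        broken.face_region = broken.face_region[keep]
        with pytest.raises(ValueError, match="not closed"):
            phe.mesh_volumes(broken)


class TestEjectionFraction:
    def test_examples(self):
        assert phe.ejection_fraction(100, 40) == pytest.approx(60.0)
        assert phe.ejection_fraction(150, 150) == 0.0

    def test_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert phe.ejection_fraction(100, 120) == 0.0

    def test_zero_edv_rejected(self):
        with pytest.raises(ValueError):
            phe.ejection_fraction(0, 0)

    def test_phantom_ef_matches_transient(self, phantom_study):
        from cardiotwin import frames as fr
        es = fr.pick_es(phantom_study.bundle)
        seg = phe.seg_phenotypes(phantom_study.bundle, 0, es)
        true_ef = 100 * (1 - phantom_study.params.es_volume_fraction)
        assert seg.lvef == pytest.approx(true_ef, abs=4.0)


class TestAtrialVolumes:
    def test_biplane_formula_hand_check(self):
        """Identical LA disks in both views reproduce (8/3pi) A^2 / L."""
        shape = (1, 40, 40, 1)
        aff = np.eye(4)
        series = {}
        for view in (CineView.LAX2CH, CineView.LAX4CH):
            data = np.zeros(shape, dtype=np.int16)
            scheme = DEFAULT_SCHEMES[view]
            data[0, 10:20, 10:30, 0] = scheme.label(cio.LV_CAVITY)
            la = scheme.label(cio.LA_CAVITY)
            data[0, 20:30, 10:30, 0] = la  # 10x20 atrium below the LV
            if view is CineView.LAX4CH:
                data[0, 5:9, 5:9, 0] = scheme.label(cio.RV_CAVITY)
                data[0, 9:13, 5:9, 0] = scheme.label(cio.RA_CAVITY)
            series[view] = SegmentationSeries(data, aff, scheme, view)
        bundle = cio.StudyBundle("x", series)
        out = phe.atrial_volumes(bundle)
        area = 200.0  # pixels at unit spacing
        # interface midpoint (19.5, 19.5); farthest LA pixel corner region
        rr, cc = np.mgrid[20:30, 10:30]
        length = np.max(np.hypot(rr - 19.5, cc - 19.5))
        expected = (8 / (3 * np.pi)) * area * area / length / 1000
        assert out["la_min"] == pytest.approx(expected, rel=1e-9)
        assert out["la_max"] == pytest.approx(expected, rel=1e-9)

    def test_phantom_atrial_max_at_es(self, phantom_study):
        out_all = []
        two = phantom_study.bundle.get(CineView.LAX2CH)
        four = phantom_study.bundle.get(CineView.LAX4CH)
        for t in range(two.n_frames):
            a2 = phe._area_length(two, cio.LA_CAVITY, cio.LV_CAVITY, t)
            a4 = phe._area_length(four, cio.LA_CAVITY, cio.LV_CAVITY, t)
            out_all.append((8 / (3 * np.pi)) * a2[0] * a4[0]
                           / min(a2[1], a4[1]))
        assert int(np.argmax(out_all)) == phantom_study.es_frame

    def test_missing_views_rejected(self, phantom_study):
        bundle = cio.StudyBundle(
            "x", {CineView.SAX: phantom_study.bundle.get(CineView.SAX)})
        with pytest.raises(ValueError):
            phe.atrial_volumes(bundle)


class TestDice:
    @pytest.mark.parametrize("a,b,label,expected", [
        (np.ones((4, 4), int), np.ones((4, 4), int), 1, 1.0),
        (np.eye(4, dtype=int), 1 - np.eye(4, dtype=int), 1, 0.0),
        (np.zeros((4, 4), int), np.zeros((4, 4), int), 1, 1.0),
    ])
    def test_examples(self, a, b, label, expected):
        assert phe.dice(a, b, label) == expected

    def test_subset_counts(self):
        a = np.zeros((4, 4), int)
        b = np.zeros((4, 4), int)
        a[0, :4] = 1  # 4 px
        b[0:2, :4] = 1  # 8 px, superset
        assert phe.dice(a, b, 1) == pytest.approx(2 * 4 / (4 + 8))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            phe.dice(np.zeros((2, 2), int), np.zeros((3, 3), int), 1)


class TestAgreementBetweenRoutes:
    def test_mesh_vs_seg_edv_within_ten_percent(self, fitted_phantom):
        st, surf_ed, surf_es, es = fitted_phantom
        seg = phe.seg_phenotypes(st.bundle, 0, es)
        mesh = phe.mesh_phenotypes("x", surf_ed, surf_es)
        assert abs(mesh.lvedv - seg.lvedv) / seg.lvedv < 0.15
        assert abs(mesh.lvedv - st.lv_cavity_ml[0]) / st.lv_cavity_ml[0] < 0.10

    def test_ef_agreement_within_five_points(self, fitted_phantom):
        st, surf_ed, surf_es, es = fitted_phantom
        seg = phe.seg_phenotypes(st.bundle, 0, es)
        mesh = phe.mesh_phenotypes("x", surf_ed, surf_es)
        assert abs(mesh.lvef - seg.lvef) <= 5.0
        assert abs(mesh.rvef - seg.rvef) <= 5.0
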