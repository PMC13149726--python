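import numpy as np
import pytest
import trimesh as tms
from scipy.spatial.transform import Rotation

from vaultshape.geometry import RadialCurve, axial_radial_contour, mirror_shape
from vaultshape.indices import (
    IndexConfig,
    IndexError_,
    cephalometrics,
    compute_all_indices,
    contour_curve_difference,
    cva_cvai,
    cva_cvai_from_curve,
    dice_asymmetry,
    dice_coefficient,
    hemisphere_ratios,
    ucsq_measures,
    vertexwise_asymmetry,
)
from vaultshape.mesh import TriangleMesh
from vaultshape.synthetic import CohortConfig, SubjectSpec, synthesize_cohort, synthesize_subject


def _make_curve(radius_fn, n=720, plane=20.0):
    angles = np.arange(n) * (2 * np.pi / n)
    return RadialCurve(angles=angles, radii=radius_fn(angles),
                       plane_height=plane, centroid=np.zeros(2))


class TestSymmetricFixedPoints:
    """Every asymmetry index must sit at its symmetric value on the
    noise-free bilaterally symmetric template."""

    def test_cva_cvai_zero(self, template_fine):
        res = cva_cvai(template_fine)
        assert res["CVA"] == pytest.approx(0.0, abs=1e-9)
        assert res["CVAI"] == pytest.approx(0.0, abs=1e-9)

    def test_vertexwise_zero(self, template_fine):
        res = vertexwise_asymmetry(template_fine.vertices, template_fine.pairing)
        assert res["max_asymmetry"] < 1e-9

    def test_contour_auc_zero(self, template_fine):
        curve = axial_radial_contour(template_fine, 20.0)
        assert contour_curve_difference(curve) == pytest.approx(0.0, abs=1e-9)

    def test_hemisphere_ratios_one(self, template_fine):
        res = hemisphere_ratios(template_fine)
        assert res["volume_ratio"] == pytest.approx(1.0, abs=1e-3)
        assert res["surface_ratio"] == pytest.approx(1.0, abs=1e-3)

    def test_ucsq_ratios_one(self, template_fine):
        curve = axial_radial_contour(template_fine, 20.0)
        res = ucsq_measures(curve)
        assert res["forehead_asymmetry_ratio"] == pytest.approx(1.0, abs=1e-9)
        assert res["gradient_ratio"] == pytest.approx(1.0, rel=1e-6)
        assert res["peak_position_left"] == pytest.approx(
            res["peak_position_right"]
        )

    def test_dice_near_100(self, template_fine):
        assert dice_asymmetry(template_fine, resolution=1.0) >= 99.0


class TestCephalometrics:
    def test_ellipsoid_cephalic_index(self, template_fine):
        """Template axial sections are 140:180 scaled ellipses → CI 77.78."""
        res = cephalometrics(template_fine, plane_height=5.0)
        assert res["cephalic_index"] == pytest.approx(100 * 140 / 180, abs=0.2)

    def test_sphere_ci_100(self):
        sph = tms.creation.icosphere(subdivisions=4, radius=10)
        mesh = TriangleMesh(np.asarray(sph.vertices), np.asarray(sph.faces))
        res = cephalometrics(mesh, plane_height=0.0)
        assert res["cephalic_index"] == pytest.approx(100.0, abs=0.2)

    def test_own_frame_rotation_contract(self, template_fine):
        """Measured in its own anatomical frame, a rotated-then-restored
        mesh gives identical values."""
        r = Rotation.from_euler("z", 0.3).as_matrix()
        rotated = template_fine.with_vertices(template_fine.vertices @ r)
        restored = rotated.with_vertices(rotated.vertices @ r.T)
        a = cephalometrics(template_fine, 10.0)
        b = cephalometrics(restored, 10.0)
        assert a["AP_length"] == pytest.approx(b["AP_length"], abs=1e-9)
        assert a["LL_width"] == pytest.approx(b["LL_width"], abs=1e-9)


class TestCvaCvai:
    def test_hand_case_d1_100_d2_90(self):
        """Constructed contour with diagonals 100 and 90 mm → CVA 10,
        CVAI 10.0."""
        a = np.deg2rad(30.0)

        def radius(th):
            r = np.full_like(th, 45.0)
            r[np.isclose(th, a)] = 55.0          # anterior-left
            r[np.isclose(th, np.pi + a)] = 45.0  # posterior-right
            r[np.isclose(th, np.pi - a)] = 44.0  # posterior-left
            r[np.isclose(th, 2 * np.pi - a)] = 46.0  # anterior-right
            return r

        curve = _make_curve(radius, n=720)
        res = cva_cvai_from_curve(curve, 30.0)
        assert res["d1"] == pytest.approx(100.0)
        assert res["d2"] == pytest.approx(90.0)
        assert res["CVA"] == pytest.approx(10.0)
        assert res["CVAI"] == pytest.approx(10.0)

    def test_scale_invariance_of_cvai(self, deformed_subject):
        res1 = cva_cvai(deformed_subject, plane_height=30.0)
        scaled = deformed_subject.with_vertices(deformed_subject.vertices * 1.7)
        res2 = cva_cvai(scaled, plane_height=30.0 * 1.7)
        assert res2["CVAI"] == pytest.approx(res1["CVAI"], rel=1e-6)
        assert res2["CVA"] == pytest.approx(1.7 * res1["CVA"], rel=1e-6)


class TestUcsq:
    def test_constructed_ratio(self):
        """Left anterior max 95, right anterior max 100 → ratio 0.95."""

        def radius(th):
            base = 80.0 + 0 * th
            left = np.exp(-((th - np.deg2rad(40)) ** 2) / (2 * 0.2**2))
            right = np.exp(-((th - np.deg2rad(320)) ** 2) / (2 * 0.2**2))
            return base + 15.0 * left + 20.0 * right

        curve = _make_curve(radius)
        res = ucsq_measures(curve)
        assert res["forehead_asymmetry_ratio"] == pytest.approx(0.95, abs=1e-3)
        assert res["peak_position_left"] == pytest.approx(40.0, abs=1.0)
        assert res["peak_position_right"] == pytest.approx(40.0, abs=1.0)

    def test_scale_invariance(self):
        def radius(th):
            return 80 + 5 * np.sin(th) + 3 * np.cos(2 * th)

        r1 = ucsq_measures(_make_curve(radius))
        r2 = ucsq_measures(
            _make_curve(lambda th: 3.0 * radius(th))
        )
        assert r1["forehead_asymmetry_ratio"] == pytest.approx(
            r2["forehead_asymmetry_ratio"]
        )
        assert r1["gradient_ratio"] == pytest.approx(r2["gradient_ratio"])

    def test_flat_curve_rejected(self):
        with pytest.raises(IndexError_):
            ucsq_measures(_make_curve(lambda th: np.full_like(th, 80.0)))


class TestHemispheres:
    def test_box_one_third(self):
        box = tms.creation.box(extents=[4, 2, 2])
        mesh = TriangleMesh(
            np.asarray(box.vertices) + np.array([1.0, 0, 0]),
            np.asarray(box.faces),
        )  # spans x ∈ [−1, 3]
        res = hemisphere_ratios(mesh)
        assert res["volume_ratio"] == pytest.approx(1 / 3)

    def test_mirroring_inverts_ratios(self, deformed_subject):
        res = hemisphere_ratios(deformed_subject)
        mirrored = deformed_subject.with_vertices(
            mirror_shape(deformed_subject.vertices, deformed_subject.pairing)
        )
        res_m = hemisphere_ratios(mirrored)
        # plane-splitting tolerance in the slicer leaves ~1e-4 residual
        assert res_m["volume_ratio"] == pytest.approx(1 / res["volume_ratio"],
                                                      rel=1e-3)
        assert res_m["surface_ratio"] == pytest.approx(1 / res["surface_ratio"],
                                                       rel=1e-3)


class TestVertexwise:
    def test_localised_bump(self, template_fine):
        """A 2 mm outward bump on one lateral vertex puts the largest
        asymmetry on that vertex and its partner."""
        verts = template_fine.vertices.copy()
        lateral = int(np.argmax(np.abs(verts[:, 0])))
        direction = verts[lateral] / np.linalg.norm(verts[lateral])
        verts[lateral] += 2.0 * direction
        res = vertexwise_asymmetry(verts, template_fine.pairing)
        top2 = np.argsort(res["distances"])[-2:]
        partner = template_fine.pairing.partner[lateral]
        assert set(top2) == {lateral, partner}
        assert res["max_asymmetry"] == pytest.approx(2.0, rel=0.1)

    def test_rigid_invariance(self, deformed_subject):
        base = vertexwise_asymmetry(
            deformed_subject.vertices, deformed_subject.pairing
        )
        r = Rotation.from_euler("xyz", [0.2, -0.1, 0.4]).as_matrix()
        moved = deformed_subject.vertices @ r + np.array([5.0, -3.0, 2.0])
        res = vertexwise_asymmetry(moved, deformed_subject.pairing)
        assert res["mean_asymmetry"] == pytest.approx(
            base["mean_asymmetry"], rel=1e-9
        )


class TestContourDifference:
    def test_sinusoidal_analytic(self):
        """r = 100 + 5 sin θ → AUC = ∫₀^π 10 sin θ dθ = 20."""
        curve = _make_curve(lambda th: 100.0 + 5.0 * np.sin(th), n=3600)
        assert contour_curve_difference(curve) == pytest.approx(20.0, rel=1e-4)

    def test_linearity_in_amplitude(self):
        for amp in (1.0, 2.0, 4.0):
            curve = _make_curve(lambda th: 100.0 + amp * np.sin(th), n=720)
            assert contour_curve_difference(curve) == pytest.approx(
                4.0 * amp, rel=1e-3
            )


class TestDice:
    def test_disjoint_masks_zero(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[:2] = True
        b[2:] = True
        assert dice_coefficient(a, b) == 0.0

    def test_offset_boxes_50(self):
        """Two 10 mm boxes offset by 5 mm along x overlap in half their
        volume → Dice 50%."""
        a = np.zeros((15, 10, 10), dtype=bool)
        b = np.zeros((15, 10, 10), dtype=bool)
        a[:10] = True
        b[5:] = True
        assert dice_coefficient(a, b) == pytest.approx(50.0)

    def test_scale_invariance(self, deformed_subject):
        d1 = dice_asymmetry(deformed_subject, resolution=2.0)
        scaled = deformed_subject.with_vertices(deformed_subject.vertices * 2.0)
        d2 = dice_asymmetry(scaled, resolution=4.0)
        assert d2 == pytest.approx(d1, abs=1.0)  # voxel discretization


class TestBattery:
    def test_symmetric_controls(self):
        config = CohortConfig(n_ucs=0, n_controls=3, template_subdivisions=4,
                              noise_scale=0.0, master_seed=0)
        shape_set, _ = synthesize_cohort(config)
        table = compute_all_indices(
            shape_set, IndexConfig(dice_resolution=2.0)
        )
        assert len(table) == 3
        assert (table["failures"] == "").all()
        assert np.allclose(table["CVA"], 0.0, atol=1e-9)
        assert np.allclose(table["vertex_asymmetry_mean"], 0.0, atol=1e-9)
        assert np.allclose(table["volume_ratio"], 1.0, atol=1e-3)
        assert (table["dice_symmetry"] >= 99.0).all()

    def test_full_column_set(self, small_cohort):
        shape_set, _ = small_cohort
        table = compute_all_indices(
            shape_set.subset(np.arange(6)),
            IndexConfig(include_dice=False),
        )
        assert len(table) == 6
        for col in ("cephalic_index", "CVA", "CVAI", "forehead_asymmetry_ratio",
                    "volume_ratio", "vertex_asymmetry_mean", "contour_auc"):
            assert col in table.columns
            assert table[col].notna().all()

    def test_monotone_severity_trend(self, template_fine):
        """Noise-free: vertex-wise asymmetry strictly tracks severity."""
        severities = np.linspace(0.1, 1.0, 8)
        means = []
        for k, sev in enumerate(severities):
            spec = SubjectSpec(f"s{k}", "UCS", "right", float(sev),
                               1.0, 0.0, k)
            mesh = synthesize_subject(template_fine, spec)
            means.append(
                vertexwise_asymmetry(mesh.vertices, template_fine.pairing)[
                    "mean_asymmetry"
                ]
            )
        from scipy.stats import spearmanr

        assert spearmanr(severities, means).statistic >= 0.9
        assert np.all(np.diff(means) > 0)
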