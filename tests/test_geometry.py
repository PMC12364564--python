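"""Tool-property metrics: circle fits, centerlines, sharpness, curvature,
volume and morphotype classification."""

import numpy as np
import pytest
import trimesh

from spinemech import geometry, synth
from spinemech.errors import DegenerateGeometryError, MeshError
from spinemech.geometry import (
    CircleFit,
    MorphotypeThresholds,
    SpineProfile,
    classify_morphotype,
    extract_centerline,
    fit_circle,
    measure_profile,
    measure_structural_curvature,
    measure_tip_angle,
    measure_tip_roc,
    measure_volume,
)

from conftest import column_parity_volume


# ---------------------------------------------------------------------------
# circle fitting
# ---------------------------------------------------------------------------


class TestFitCircle:
    def test_exact_circle(self):
        t = np.linspace(0, 2 * np.pi, 32, endpoint=False)
        pts = np.column_stack([np.cos(t), np.sin(t)])
        fit = fit_circle(pts)
        assert abs(fit.radius - 1.0) < 1e-9
        assert fit.rmse < 1e-9
        assert np.allclose(fit.center, [0, 0], atol=1e-9)

    def test_circumcircle_three_points(self):
        fit = fit_circle([(0.0, 0.0), (2.0, 0.0), (1.0, 1.0)])
        assert np.allclose(fit.center, [1.0, 0.0], atol=1e-9)
        assert abs(fit.radius - 1.0) < 1e-9

    def test_matches_grid_search_oracle_on_noisy_points(self):
        rng = np.random.default_rng(42)
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        pts = 5.0 * np.column_stack([np.cos(t), np.sin(t)])
        pts += rng.normal(0, 0.05, pts.shape)
        fit = fit_circle(pts)

        # brute-force least-squares over a parameter grid
        cxs = np.linspace(-0.15, 0.15, 31)
        cys = np.linspace(-0.15, 0.15, 31)
        rs = np.linspace(4.85, 5.15, 31)
        best = (np.inf, None)
        for cx in cxs:
            for cy in cys:
                d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
                for r in rs:
                    sse = ((d - r) ** 2).sum()
                    if sse < best[0]:
                        best = (sse, (cx, cy, r))
        _, (gx, gy, gr) = best
        assert abs(fit.radius - gr) < 0.02
        assert np.hypot(fit.center[0] - gx, fit.center[1] - gy) < 0.02

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 2, 10)])
        with pytest.raises(DegenerateGeometryError):
            fit_circle(pts)


# ---------------------------------------------------------------------------
# centerline
# ---------------------------------------------------------------------------


class TestCenterline:
    def test_straight_cone_centerline_collinear(self, straight_cone):
        profile, truth = straight_cone
        cl = extract_centerline(profile, n_stations=64)
        # generated cone's axis is x = 0
        assert np.abs(cl.points[:, 0]).max() < 1e-6 * truth.length_mm

    def test_arc_spine_centerline_on_generative_arc(self, arc_spine):
        profile, truth = arc_spine
        cl = extract_centerline(profile, n_stations=80)
        dev = np.abs(
            np.linalg.norm(cl.points - truth.arc_center, axis=1) - truth.arc_radius
        )
        assert dev.max() < 0.02 * truth.length_mm

    def test_two_stations_returns_endpoints(self, straight_cone):
        profile, truth = straight_cone
        cl = extract_centerline(profile, n_stations=2)
        assert cl.points.shape == (2, 2)
        apex = profile.vertices[profile.tip_index]
        # ordered base -> tip
        assert np.allclose(cl.points[-1], apex, atol=1e-9)

    def test_ordering_is_base_to_tip(self, arc_spine):
        profile, _ = arc_spine
        cl = extract_centerline(profile, n_stations=40)
        apex = profile.vertices[profile.tip_index]
        d_first = np.linalg.norm(cl.points[0] - apex)
        d_last = np.linalg.norm(cl.points[-1] - apex)
        assert d_last < d_first
        assert cl.halfwidth[-1] == 0.0


# ---------------------------------------------------------------------------
# tip angle
# ---------------------------------------------------------------------------


class TestTipAngle:
    def test_isoceles_wedge(self):
        # apex angle 30 degrees, apex at origin pointing -y
        half = np.radians(15.0)
        tip = np.array([0.0, 0.0])
        left = np.array([-np.sin(half), np.cos(half)]) * 3.0
        right = np.array([np.sin(half), np.cos(half)]) * 3.0
        profile = SpineProfile(
            vertices=np.array([tip, right, left]), tip_index=0
        )
        angle = measure_tip_angle(profile, cap_exclusion=0.01)
        assert abs(angle - 30.0) < 0.5

    @pytest.mark.parametrize("tip_angle", [12.8, 45.0, 89.1])
    def test_generated_profile_recovery(self, tip_angle):
        params = synth.SpineGenParams(
            length=3.22, tip_angle=tip_angle, structural_curvature=20.0,
            tip_roc=0.06, base_width=0.5,
        )
        profile, truth = synth.generate_spine_profile(params)
        angle = measure_tip_angle(profile)
        assert abs(angle - truth.tip_angle_deg) < 2.0

    def test_stable_across_flank_windows_on_hooked_spine(self):
        params = synth.SpineGenParams(
            length=3.22, tip_angle=45.0, structural_curvature=100.0,
            tip_roc=0.08, base_width=0.8,
        )
        profile, _ = synth.generate_spine_profile(params)
        values = [
            measure_tip_angle(profile, flank_window=w) for w in (0.10, 0.15, 0.20)
        ]
        assert max(values) - min(values) < 3.0


# ---------------------------------------------------------------------------
# tip radius of curvature
# ---------------------------------------------------------------------------


class TestTipRoc:
    def test_semicircular_capped_rod(self):
        # rectangle of half-width r topped by an exact semicircular cap
        r = 0.25
        t = np.linspace(0, np.pi, 61)
        cap = np.column_stack([r * np.cos(t), -r * np.sin(t)])  # (r,0) .. (-r,0)
        verts = np.vstack([[r, 3.0], cap, [-r, 3.0]])
        tip_index = 1 + int(np.argmin(cap[:, 1]))
        profile = SpineProfile(vertices=verts, tip_index=tip_index)
        roc, _ = measure_tip_roc(profile)
        assert abs(roc - r) < 1e-3 * r

    @pytest.mark.parametrize(
        "roc_norm,tip_angle,base_width",
        [(0.025, 30.0, 0.64), (0.08, 45.0, 0.8), (0.60, 110.0, 2.6)],
    )
    def test_generated_profile_recovery_across_observed_range(
        self, roc_norm, tip_angle, base_width
    ):
        params = synth.SpineGenParams(
            length=3.22, tip_angle=tip_angle, structural_curvature=0.0,
            tip_roc=roc_norm * 3.22, base_width=base_width,
        )
        profile, truth = synth.generate_spine_profile(params)
        _, norm = measure_tip_roc(profile)
        assert abs(norm - truth.tip_roc_norm) < 0.01

    def test_wide_window_on_wedge_flagged_unreliable(self, straight_cone):
        profile, _ = straight_cone
        with pytest.warns(UserWarning, match="unreliable"):
            measure_tip_roc(profile, cap_window=0.5, adaptive=False)


# ---------------------------------------------------------------------------
# structural curvature
# ---------------------------------------------------------------------------


class TestStructuralCurvature:
    def test_straight_cone_reads_zero(self, straight_cone):
        profile, _ = straight_cone
        assert measure_structural_curvature(profile) <= 5.0

    def test_arc_spine_recovers_arc_angle(self, arc_spine):
        profile, truth = arc_spine
        sc = measure_structural_curvature(profile)
        assert abs(sc - truth.structural_curvature_deg) < 5.0

    @pytest.mark.parametrize("sc_true", [16.89, 109.69])
    def test_observed_extremes(self, sc_true):
        params = synth.SpineGenParams(
            length=3.22, tip_angle=40.0, structural_curvature=sc_true,
            tip_roc=0.08, base_width=0.7,
        )
        profile, _ = synth.generate_spine_profile(params)
        sc = measure_structural_curvature(profile)
        assert abs(sc - sc_true) < 5.0


# ---------------------------------------------------------------------------
# volume
# ---------------------------------------------------------------------------


class TestVolume:
    def test_unit_cube(self):
        assert measure_volume(trimesh.creation.box(extents=(1, 1, 1))) == pytest.approx(
            1.0
        )

    def test_icosphere_approaches_analytic_ball(self):
        mesh = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        assert abs(measure_volume(mesh) - 4 * np.pi / 3) < 0.01 * 4 * np.pi / 3

    def test_open_mesh_rejected_naming_edge_count(self):
        mesh = trimesh.creation.box(extents=(1, 1, 1))
        broken = trimesh.Trimesh(
            vertices=mesh.vertices, faces=mesh.faces[:-1], process=False
        )
        with pytest.raises(MeshError, match=r"\d+ boundary"):
            measure_volume(broken)

    def test_generated_mesh_matches_voxel_parity_oracle(self, arc_spine):
        profile, _ = arc_spine
        mesh = synth.generate_spine_mesh(profile, lateral_compression=1.0)
        oracle = column_parity_volume(mesh, pitch=0.015)
        assert abs(measure_volume(mesh) - oracle) < 0.02 * oracle


# ---------------------------------------------------------------------------
# morphotype
# ---------------------------------------------------------------------------


class TestMorphotype:
    def _metrics(self, **kw):
        base = dict(
            tip_angle_deg=45.0, tip_roc_mm=0.08, tip_roc_norm=0.02,
            structural_curvature_deg=10.0, aspect_ratio=0.3, length_mm=3.22,
        )
        base.update(kw)
        return geometry.ToolMetrics(**base)

    def test_aspect_ratio_above_half_is_short(self, straight_cone):
        profile, _ = straight_cone
        _, cl = measure_profile(profile)
        m = self._metrics(aspect_ratio=0.6)
        assert classify_morphotype(m, cl).elongate is False
        assert classify_morphotype(self._metrics(aspect_ratio=0.3), cl).elongate

    def test_high_structural_curvature_is_hooked(self, straight_cone):
        profile, _ = straight_cone
        _, cl = measure_profile(profile)
        m = self._metrics(structural_curvature_deg=109.7)
        assert classify_morphotype(m, cl).hooked is True

    def test_straight_cone_not_wavy_not_hooked(self, straight_cone):
        profile, truth = straight_cone
        metrics, cl = measure_profile(profile)
        mt = classify_morphotype(metrics, cl)
        assert mt.wavy is False
        assert mt.hooked is False

    def test_wavy_centerline_flagged(self):
        params = synth.SpineGenParams(
            length=3.22, tip_angle=30.0, structural_curvature=0.0,
            tip_roc=0.06, base_width=0.6, waviness=0.02,
        )
        profile, _ = synth.generate_spine_profile(params)
        metrics, cl = measure_profile(profile)
        assert classify_morphotype(metrics, cl).wavy is True

    def test_lateral_compression_controls_conical(self, straight_cone):
        profile, _ = straight_cone
        metrics, cl = measure_profile(profile)
        assert classify_morphotype(metrics, cl, lateral_compression=1.0).conical
        assert not classify_morphotype(metrics, cl, lateral_compression=0.5).conical


# ---------------------------------------------------------------------------
# invariances
# ---------------------------------------------------------------------------


class TestSimilarityInvariance:
    @pytest.mark.parametrize("angle_deg,shift", [(37.0, (1.3, -2.1)), (120.0, (0.0, 5.0))])
    def test_metrics_invariant_under_rigid_motion(self, arc_spine, angle_deg, shift):
        profile, _ = arc_spine
        m0, _ = measure_profile(profile)
        a = np.radians(angle_deg)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        verts = profile.vertices @ rot.T + np.asarray(shift)
        moved = SpineProfile(vertices=verts, tip_index=profile.tip_index)
        m1, _ = measure_profile(moved)
        assert m1.tip_angle_deg == pytest.approx(m0.tip_angle_deg, abs=1e-5)
        assert m1.tip_roc_norm == pytest.approx(m0.tip_roc_norm, rel=1e-6)
        assert m1.structural_curvature_deg == pytest.approx(
            m0.structural_curvature_deg, abs=1e-4
        )
        assert m1.aspect_ratio == pytest.approx(m0.aspect_ratio, rel=1e-6)

    def test_scaling_equivariance(self, arc_spine):
        profile, _ = arc_spine
        m0, _ = measure_profile(profile)
        scaled = SpineProfile(
            vertices=profile.vertices * 2.5, tip_index=profile.tip_index
        )
        m1, _ = measure_profile(scaled)
        assert m1.tip_roc_mm == pytest.approx(2.5 * m0.tip_roc_mm, rel=1e-6)
        assert m1.tip_roc_norm == pytest.approx(m0.tip_roc_norm, rel=1e-6)
        assert m1.tip_angle_deg == pytest.approx(m0.tip_angle_deg, abs=1e-5)
        assert m1.structural_curvature_deg == pytest.approx(
            m0.structural_curvature_deg, abs=1e-4
        )


# ---------------------------------------------------------------------------
# profile IO
# ---------------------------------------------------------------------------


def test_profile_csv_round_trip(tmp_path, arc_spine):
    profile, _ = arc_spine
    path = tmp_path / "spine.csv"
    geometry.write_profile_csv(profile, path)
    back = geometry.read_profile_csv(path, spine_id="X")
    assert np.allclose(back.vertices, profile.vertices)
    m0, _ = measure_profile(profile)
    m1, _ = measure_profile(back)
    assert m1.tip_angle_deg == pytest.approx(m0.tip_angle_deg, abs=0.5)
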