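import numpy as np
import pytest

from archmorph import (
    ArchParams,
    DeformationScenario,
    DeviationField,
    EmptyResultError,
    Plane,
    TriangleMesh,
    ValidationError,
    apply_deformation,
    classify_deviation,
    cross_section_deviation,
    deformation_summary,
    export_color_map,
    signed_deviation_field,
)
from archmorph.deviation import deviation_to_rgb, load_deviation_csv
from archmorph.register import closest_point_on_triangles
from conftest import make_grid_patch, random_smooth_field


def offset_patch(patch, dz):
    return TriangleMesh(patch.vertices + [0.0, 0.0, dz], patch.faces)


class TestSignedField:
    def test_identical_meshes_zero(self, patch):
        fld = signed_deviation_field(patch, patch)
        np.testing.assert_allclose(fld.values, 0.0, atol=1e-12)

    def test_uniform_positive_offset(self, patch):
        fld = signed_deviation_field(offset_patch(patch, 0.1), patch)
        np.testing.assert_allclose(fld.values, 0.100, atol=1e-9)

    def test_uniform_negative_offset(self, patch):
        fld = signed_deviation_field(offset_patch(patch, -0.07), patch)
        np.testing.assert_allclose(fld.values, -0.070, atol=1e-9)

    def test_brute_force_distance_oracle(self, base_arch, arch_params):
        test = apply_deformation(
            base_arch, DeformationScenario(0.05, 0.08, 0.06), arch_params
        )
        fld = signed_deviation_field(test, base_arch)
        tri = base_arch.triangles()
        rng = np.random.default_rng(9)
        for i in rng.choice(test.n_vertices, 100, replace=False):
            q = test.vertices[i]
            cps = closest_point_on_triangles(np.broadcast_to(q, (len(tri), 3)), tri)
            brute = np.linalg.norm(cps - q, axis=1).min()
            assert abs(abs(fld.values[i]) - brute) < 1e-12

    def test_length_mismatch_rejected(self, patch):
        with pytest.raises(ValidationError):
            DeviationField(np.zeros(3), patch)


class TestClassification:
    def test_strict_cutoff_rule(self):
        mesh = TriangleMesh(np.arange(12.0).reshape(4, 3), np.array([[0, 1, 2], [1, 2, 3]]))
        fld = DeviationField(np.array([0.05, -0.05, 0.039, -0.040]), mesh)
        cls = classify_deviation(fld, 0.040)
        np.testing.assert_array_equal(cls.labels, [1, -1, 0, 0])

    def test_all_zero_neutral(self, patch):
        fld = DeviationField(np.zeros(patch.n_vertices), patch)
        assert classify_deviation(fld, 0.04).neutral.all()

    def test_zero_cutoff_forbidden(self, patch):
        fld = DeviationField(np.zeros(patch.n_vertices), patch)
        with pytest.raises(ValidationError):
            classify_deviation(fld, 0.0)


class TestSummary:
    def test_uniform_offset_closed_form(self, patch):
        fld = signed_deviation_field(offset_patch(patch, 0.1), patch)
        s = deformation_summary(fld, classify_deviation(fld, 0.04))
        assert s.max_plus == pytest.approx(0.1, abs=1e-9)
        assert s.area_plus == pytest.approx(100.0, abs=1e-9)
        assert s.volume_plus == pytest.approx(10.0, abs=1e-9)
        assert s.max_minus == s.area_minus == s.volume_minus == 0.0

    def test_all_neutral_zero_outcomes(self, patch):
        fld = DeviationField(np.full(patch.n_vertices, 0.01), patch)
        s = deformation_summary(fld, classify_deviation(fld, 0.04))
        assert (
            s.max_plus == s.max_minus == s.area_plus == s.area_minus
            == s.volume_plus == s.volume_minus == 0.0
        )

    def test_half_offset_boundary_bracket(self, patch):
        # rows y >= 5 offset by +0.1: fully offset cells cover 50 mm2, the
        # boundary row (10 mm2) is split by the mean-of-vertices rule
        v = patch.vertices.copy()
        v[v[:, 1] > 5.0 - 1e-9, 2] += 0.1
        test = TriangleMesh(v, patch.faces)
        fld = signed_deviation_field(test, patch)
        s = deformation_summary(fld, classify_deviation(fld, 0.04))
        assert 50.0 - 1e-6 <= s.area_plus <= 61.0  # 50 + boundary row (tilted)
        assert 0.1 * (s.area_plus - 10.1) <= s.volume_plus <= 0.1 * s.area_plus + 1e-9

    def test_sign_flip_swaps_outcomes(self, base_arch):
        rng = np.random.default_rng(3)
        vals = random_smooth_field(base_arch, rng)
        fld = DeviationField(vals, base_arch)
        s = deformation_summary(fld, classify_deviation(fld, 0.04))
        neg = DeviationField(-vals, base_arch)
        sn = deformation_summary(neg, classify_deviation(neg, 0.04))
        assert sn.max_plus == s.max_minus and sn.max_minus == s.max_plus
        assert sn.area_plus == s.area_minus and sn.area_minus == s.area_plus
        assert sn.volume_plus == s.volume_minus and sn.volume_minus == s.volume_plus

    def test_cutoff_monotonicity(self, base_arch):
        rng = np.random.default_rng(14)
        for _ in range(10):
            fld = DeviationField(random_smooth_field(base_arch, rng), base_arch)
            prev = None
            for cutoff in (0.02, 0.04, 0.06, 0.09):
                s = deformation_summary(fld, classify_deviation(fld, cutoff))
                if prev is not None:
                    assert s.area_plus <= prev.area_plus + 1e-12
                    assert s.area_minus <= prev.area_minus + 1e-12
                    assert s.volume_plus <= prev.volume_plus + 1e-12
                    assert s.volume_minus <= prev.volume_minus + 1e-12
                    # max +- unchanged while any vertex stays beyond cutoff
                    if s.area_plus > 0:
                        assert s.max_plus == prev.max_plus
                    if s.area_minus > 0:
                        assert s.max_minus == prev.max_minus
                prev = s

    def test_volume_bounds(self, base_arch):
        rng = np.random.default_rng(7)
        for _ in range(20):
            fld = DeviationField(random_smooth_field(base_arch, rng), base_arch)
            s = deformation_summary(fld, classify_deviation(fld, 0.04))
            for mx, ar, vol in (
                (s.max_plus, s.area_plus, s.volume_plus),
                (s.max_minus, s.area_minus, s.volume_minus),
            ):
                if ar > 0:
                    assert 0.04 * ar <= vol <= mx * ar + 1e-9

    def test_projected_area_mode(self, patch):
        # flat patch in z=0: projected and surface areas coincide
        fld = signed_deviation_field(offset_patch(patch, 0.1), patch)
        cls = classify_deviation(fld, 0.04)
        s_surf = deformation_summary(fld, cls, area_mode="surface")
        s_proj = deformation_summary(fld, cls, area_mode="projected_z")
        assert s_proj.area_plus == pytest.approx(s_surf.area_plus, abs=1e-9)
        with pytest.raises(ValidationError):
            deformation_summary(fld, cls, area_mode="bogus")


class TestCrossSection:
    def test_constant_profile_on_offset_patch(self, patch):
        test = offset_patch(patch, 0.1)
        cs = cross_section_deviation(test, patch, Plane((5, 5, 0), (1, 0, 0)))
        poly = cs.longest
        np.testing.assert_allclose(poly["deviation"], 0.1, atol=1e-9)
        assert poly["arc_length"][-1] == pytest.approx(10.0, abs=1e-6)
        assert np.all(np.diff(poly["arc_length"]) > 0)

    def test_plane_missing_mesh(self, patch):
        test = offset_patch(patch, 0.1)
        with pytest.raises(EmptyResultError):
            cross_section_deviation(test, patch, Plane((50, 0, 0), (1, 0, 0)))

    def test_frontal_section_through_lift_zone(self, base_arch, arch_params):
        lifted = apply_deformation(
            base_arch, DeformationScenario(palatal_lift=0.08), arch_params
        )
        fld = signed_deviation_field(lifted, base_arch)
        y_cut = base_arch.vertices[:, 1].max() - 3.0
        cs = cross_section_deviation(
            lifted, base_arch, Plane((0, y_cut, 0), (0, 1, 0)), field=fld
        )
        dev_max = max(p["deviation"].max() for p in cs.polylines)
        assert dev_max == pytest.approx(0.080, abs=2 * arch_params.resolution * 0.01)
        # the lifted maximum sits on the inner (palatal) side: x closer to 0
        assert len(cs.polylines) >= 2  # the plane cuts both posterior arms

    def test_longest_polyline_first(self, base_arch):
        fld = DeviationField(np.zeros(base_arch.n_vertices), base_arch)
        cs = cross_section_deviation(
            base_arch, base_arch, Plane((0, 10.0, 0), (0, 1, 0)), field=fld
        )
        lengths = [p["arc_length"][-1] for p in cs.polylines]
        assert lengths == sorted(lengths, reverse=True)


class TestColorMap:
    def test_scale_endpoints(self):
        rgb = deviation_to_rgb(np.array([0.0, 0.15, -0.15, 0.075]), 0.15)
        np.testing.assert_array_equal(rgb[0], [0, 255, 0])
        np.testing.assert_array_equal(rgb[1], [255, 0, 0])
        np.testing.assert_array_equal(rgb[2], [0, 0, 255])
        np.testing.assert_array_equal(rgb[3], [128, 128, 0])

    def test_ply_and_csv_round_trip(self, patch, tmp_path):
        test = offset_patch(patch, 0.1)
        fld = signed_deviation_field(test, patch)
        ply, csvp = export_color_map(test, fld, 0.04, tmp_path / "map.ply")
        header = ply.read_text().split("end_header")[0]
        for prop in ("property uchar red", "property float deviation", "element face"):
            assert prop in header
        reloaded = load_deviation_csv(csvp)
        assert np.array_equal(reloaded, fld.values)

    def test_all_zero_field_green(self, patch, tmp_path):
        fld = DeviationField(np.zeros(patch.n_vertices), patch)
        ply, _ = export_color_map(patch, fld, 0.04, tmp_path / "g.ply")
        body = ply.read_text().split("end_header\n")[1].splitlines()[: patch.n_vertices]
        for line in body:
            assert line.split()[3:6] == ["0", "255", "0"]
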