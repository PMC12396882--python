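"""Exposure metrics: line casting, surgical freedom, exposure angle,
angle of attack, presigmoid measures, and their invariances."""

import contextlib
import dataclasses
import warnings

import numpy as np
import numpy.testing as npt
import pytest
from scipy.spatial.transform import Rotation

from presigmoid import (GeometryError, RetractionConfig, angle_of_attack,
                        apply_retraction, cast_lines_of_sight, compute_exposure,
                        exposure_angle, presigmoid_measures, surgical_freedom)
from presigmoid.landmarks import Disc3
from presigmoid.metrics import anatomical_frame, sf_triangle_areas


class TestAnatomicalFrame:
    def test_reference_frame_is_canonical(self, reference_specimen):
        fr = anatomical_frame(reference_specimen)
        npt.assert_allclose(fr.anterior, [1, 0, 0], atol=1e-12)
        npt.assert_allclose(fr.superior, [0, 1, 0], atol=1e-12)
        npt.assert_allclose(fr.lateral, [0, 0, 1], atol=1e-12)

    def test_frame_rotates_with_specimen(self, reference_specimen):
        R = Rotation.from_euler("xyz", [0.4, -0.2, 0.7]).as_matrix()
        fr = anatomical_frame(reference_specimen.transformed(R, [3.0, -1.0, 2.0]))
        fr0 = anatomical_frame(reference_specimen)
        npt.assert_allclose(fr.anterior, R @ fr0.anterior, atol=1e-9)
        npt.assert_allclose(fr.superior, R @ fr0.superior, atol=1e-9)


class TestCastLines:
    def test_reference_winners_and_labels(self, reference_specimen):
        """On the axis-aligned fixture every rule has one unambiguous
        winner, placed by construction."""
        lm = reference_specimen
        lines = cast_lines_of_sight(lm)
        assert lines.labels == ("sigmoid sinus", "sinodural angle", "craniotomy",
                                "facial nerve", "facial nerve", "sigmoid sinus")
        npt.assert_allclose(lines.endpoints[0], lm.ss_anterior_above_iac)
        npt.assert_allclose(lines.endpoints[1], lm.sinodural_angle)
        # L3: the rim vertex angularly closest to the superior-anterior direction
        d3 = np.array([1.0, 1.0, 0]) / np.sqrt(2)
        rel = lm.craniotomy_rim / np.linalg.norm(lm.craniotomy_rim, axis=1,
                                                 keepdims=True)
        npt.assert_allclose(lines.endpoints[2],
                            lm.craniotomy_rim[int(np.argmax(rel @ d3))])
        # L4 and L5 terminate on the facial-nerve tube surface (vertical
        # axis at (5, ., 9) with radius 1 on this fixture)
        for idx in (3, 4):
            fn_axis_dist = np.linalg.norm(
                lines.endpoints[idx][[0, 2]] - lm.fn_cross_iac.center[[0, 2]])
            assert fn_axis_dist == pytest.approx(lm.fn_cross_iac.radius, abs=1e-6)

    def test_tegmen_clips_superior_posterior_line(self, reference_specimen):
        lm = dataclasses.replace(reference_specimen,
                                 sinodural_angle=np.array([-15.0, 15.0, 17.0]))
        lines = cast_lines_of_sight(lm)
        assert lines.labels[1] == "tegmen"
        assert lines.endpoints[1][1] == pytest.approx(12.0, abs=1e-9)

    def test_far_anterior_facial_nerve_falls_back_to_rim(self, reference_specimen):
        lm = reference_specimen
        shift = np.array([40.0, 0.0, 0.0])
        lm2 = dataclasses.replace(
            lm,
            fn_cross_iac=Disc3(lm.fn_cross_iac.center + shift, lm.fn_cross_iac.radius),
            fn_cross_bulb=Disc3(lm.fn_cross_bulb.center + shift,
                                lm.fn_cross_bulb.radius))
        lines = cast_lines_of_sight(lm2)
        assert lines.labels[3] == "craniotomy"
        assert lines.labels[4] == "craniotomy"

    def test_retraction_moves_only_sinus_limited_lines(self, reference_specimen):
        lm = reference_specimen
        before = cast_lines_of_sight(lm)
        after_lm, _ = apply_retraction(lm, RetractionConfig(), 2)
        after = cast_lines_of_sight(after_lm)
        moved = [i for i in range(6)
                 if np.linalg.norm(before.endpoints[i] - after.endpoints[i]) > 1e-9]
        assert moved == [0, 5]  # L1 and L6
        # and they moved posteriorly (toward -x in the canonical fixture)
        assert after.endpoints[0][0] < before.endpoints[0][0]
        assert after.endpoints[5][0] < before.endpoints[5][0]

    def test_sinus_enclosing_p_raises(self, reference_specimen):
        lm = dataclasses.replace(reference_specimen,
                                 ss_cross_iac=Disc3(np.array([-2.0, 0, 1.0]), 8.0),
                                 ss_cross_bulb=Disc3(np.array([-2.0, -7.0, 1.0]), 8.0))
        with pytest.raises(GeometryError, match="line 1"):
            cast_lines_of_sight(lm)


class TestSurgicalFreedom:
    def test_triangulation_matches_hand_shoelace_hexagon(self):
        """The four-triangle sum over the worked hexagon equals its
        shoelace area (6.0) because triangles A, B tile quad 1-2-3-4 and
        C, D tile quad 4-5-6-1."""
        hexa2 = np.array([[0, 0], [2, 0], [3, 1], [2, 2], [0, 2], [-1, 1]], float)
        pts = np.column_stack([hexa2, np.full(6, 5.0)])
        assert sum(sf_triangle_areas(pts)) == pytest.approx(6.0, abs=1e-9)

    def test_intersections_lie_on_craniotomy_plane(self, reference_specimen):
        sf = surgical_freedom(reference_specimen)
        for p in sf.points:
            assert abs(sf.plane.signed_distance(p)) < 1e-9

    def test_total_is_triangle_sum_and_convex_case_matches_polygon(
            self, reference_specimen):
        from presigmoid import polygon_area_in_plane
        sf = surgical_freedom(reference_specimen)
        assert sf.total == pytest.approx(sf.tri_a + sf.tri_b + sf.tri_c + sf.tri_d)
        if sf.convex:
            assert sf.total == pytest.approx(
                polygon_area_in_plane(sf.points), rel=1e-6)

    def test_degenerate_lines_give_zero_and_flag(self, reference_specimen):
        from presigmoid.metrics import LineOfSightSet
        lm = reference_specimen
        same = np.tile(np.array([5.0, 5.0, 24.0]), (6, 1))
        lines = LineOfSightSet(origin=lm.P, endpoints=same,
                               labels=("x",) * 6)
        sf = surgical_freedom(lm, lines)
        assert sf.total == pytest.approx(0.0, abs=1e-12)
        assert sf.degenerate

    def test_rigid_motion_invariance(self, reference_specimen):
        rng = np.random.default_rng(17)
        R = Rotation.from_euler("xyz", rng.uniform(-np.pi, np.pi, 3)).as_matrix()
        t = rng.uniform(-40, 40, 3)
        sf0 = surgical_freedom(reference_specimen)
        sf1 = surgical_freedom(reference_specimen.transformed(R, t))
        assert sf1.total == pytest.approx(sf0.total, rel=1e-6)

    def test_uniform_scaling_scales_area_quadratically(self, reference_specimen):
        sf0 = surgical_freedom(reference_specimen)
        sf2 = surgical_freedom(reference_specimen.scaled(2.0))
        assert sf2.total == pytest.approx(4.0 * sf0.total, rel=1e-9)


def _ea_point_fixture(reference_specimen, f2d, a2d):
    """Reference specimen with point structures (radius ~0) at prescribed
    2D [anterior, lateral] offsets from the sinus point at (-10, 16)."""
    s = np.array([-10.0, 0.0, 16.0])
    lm = dataclasses.replace(
        reference_specimen,
        ss_cross_iac=Disc3(s, 0.0),
        fn_cross_iac=Disc3(np.array([s[0] + f2d[0], 0.0, s[2] + f2d[1]]), 0.0),
        anterior_rim_point=np.array([s[0] + a2d[0], 1.0, s[2] + a2d[1]]),
        dura_posterior_ss=np.array([-40.0, 1.0, 16.0 + a2d[1]]),
    )
    # keep the intrinsic anterior axis exactly +x
    lm = dataclasses.replace(
        lm, dura_posterior_ss=lm.anterior_rim_point - np.array([30.0, 0.0, 0.0]))
    return lm


class TestExposureAngle:
    def test_point_limit_perpendicular_is_90(self, reference_specimen):
        lm = _ea_point_fixture(reference_specimen, f2d=(10.0, 0.0), a2d=(0.0, 10.0))
        assert exposure_angle(lm, "iac") == pytest.approx(90.0, abs=1e-9)

    def test_point_limit_collinear_is_0(self, reference_specimen):
        """Sinus between the nerve and the rim anchor on one line: the
        corridor wedge closes completely."""
        lm = _ea_point_fixture(reference_specimen, f2d=(10.0, 0.0), a2d=(-10.0, 0.0))
        assert exposure_angle(lm, "iac") == pytest.approx(0.0, abs=1e-9)

    def test_overlapping_discs_raise(self, reference_specimen):
        lm = dataclasses.replace(
            reference_specimen,
            fn_cross_iac=Disc3(np.array([-18.0, 0.0, 15.0]), 2.0))
        with pytest.raises(GeometryError, match="tangent"):
            exposure_angle(lm, "iac")

    def test_matches_brute_force_tangent_sampling(self, small_cohort):
        """The closed-form common tangents agree with a dense angular
        sampling of candidate tangent lines to within 0.1 degree."""
        for sp in small_cohort[:6]:
            lm = sp.landmarks
            fr = anatomical_frame(lm)
            for level in ("iac", "bulb"):
                origin = lm.P if level == "iac" else lm.jugular_bulb_top
                ss = lm.ss_cross_iac if level == "iac" else lm.ss_cross_bulb
                fn = lm.fn_cross_iac if level == "iac" else lm.fn_cross_bulb

                def to2(p):
                    rel = p - origin
                    return np.array([rel @ fr.anterior, rel @ fr.lateral])

                got = exposure_angle(lm, level)
                want = _ea_sampling_oracle(to2(ss.center), ss.radius,
                                           to2(fn.center), fn.radius,
                                           to2(lm.anterior_rim_point))
                assert got == pytest.approx(want, abs=0.1)

    def test_monotone_under_posterior_sinus_translation(self, property_cohort):
        """Translating the sinus cross-sections and its anterior border
        posteriorly never decreases either exposure angle (or the SF)."""
        for sp in property_cohort:
            lm = sp.landmarks
            post = -anatomical_frame(lm).anterior
            prev = (-np.inf, -np.inf, -np.inf)
            for step in range(5):
                d = 1.0 * step * post
                lmt = dataclasses.replace(
                    lm,
                    ss_anterior_above_iac=lm.ss_anterior_above_iac + d,
                    ss_cross_iac=Disc3(lm.ss_cross_iac.center + d,
                                       lm.ss_cross_iac.radius),
                    ss_cross_bulb=Disc3(lm.ss_cross_bulb.center + d,
                                        lm.ss_cross_bulb.radius))
                with _suppress_warnings():
                    cur = (surgical_freedom(lmt).total,
                           exposure_angle(lmt, "iac"), exposure_angle(lmt, "bulb"))
                assert cur[0] >= prev[0] - 1e-9
                assert cur[1] >= prev[1] - 1e-9
                assert cur[2] >= prev[2] - 1e-9
                prev = cur


@contextlib.contextmanager
def _suppress_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


def _ea_sampling_oracle(s2, rs, f2, rf, a2, n=720_000):
    """Dense angular sampling of candidate tangent normals, feasibility-
    checked, refined by linear interpolation at the sign changes."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    N = np.column_stack([np.cos(th), np.sin(th)])

    def roots(g):
        s = np.sign(g)
        idx = np.nonzero(s != np.roll(s, -1))[0]
        out = []
        for i in idx:
            j = (i + 1) % n
            t2 = th[j] if j != 0 else 2 * np.pi
            g1, g2 = g[i], g[j]
            out.append((th[i] + (t2 - th[i]) * (-g1) / (g2 - g1)) % (2 * np.pi))
        return out

    def pick(ts):
        ns = [np.array([np.cos(t), np.sin(t)]) for t in ts]
        lat = [m for m in ns if m[1] > 1e-9]
        pool = lat if len(lat) == 1 else (lat or ns)
        return max(pool, key=lambda m: abs(m[1]))

    nA = pick(roots(N @ (s2 - f2) + rs + rf))
    nB = pick(roots(N @ (s2 - a2) - rs))
    d_a = (f2 - rf * nA) - (s2 + rs * nA)
    d_b = a2 - (s2 - rs * nB)
    cosv = np.dot(d_a, d_b) / np.linalg.norm(d_a) / np.linalg.norm(d_b)
    return 180.0 - np.degrees(np.arccos(np.clip(cosv, -1, 1)))


class TestAngleOfAttack:
    def test_perpendicular_construction_is_90(self, reference_specimen):
        """Sinus anterior border directly posterior of P, IAC axis purely
        lateral: the two rays are perpendicular."""
        lm = dataclasses.replace(
            reference_specimen,
            ss_cross_iac=Disc3(np.array([-15.0, 0.0, 0.0]), 5.0),
            iac_mid=np.array([0.0, 0.0, 5.0]),
            iac_anterolateral=np.array([0.0, 0.0, 10.0]))
        assert angle_of_attack(lm) == pytest.approx(90.0, abs=1e-9)

    def test_45_degree_construction(self, reference_specimen):
        lm = dataclasses.replace(
            reference_specimen,
            ss_cross_iac=Disc3(np.array([-15.0, 0.0, 10.0]), 5.0),
            iac_mid=np.array([0.0, 0.0, 5.0]),
            iac_anterolateral=np.array([0.0, 0.0, 10.0]))
        # ray P -> (-10, 10) is 45 deg posterior of the lateral IAC axis
        assert angle_of_attack(lm) == pytest.approx(45.0, abs=1e-9)

    def test_matches_arccos_oracle_on_random_fixtures(self, small_cohort):
        for sp in small_cohort[:8]:
            lm = sp.landmarks
            fr = anatomical_frame(lm)

            def to2(p):
                rel = p - lm.P
                return np.array([rel @ fr.anterior, rel @ fr.lateral])

            v1 = to2(lm.ss_cross_iac.center) + np.array([lm.ss_cross_iac.radius, 0.0])
            v2 = to2(lm.iac_anterolateral) - to2(lm.iac_mid)
            want = np.degrees(np.arccos(np.clip(
                v1 @ v2 / np.linalg.norm(v1) / np.linalg.norm(v2), -1, 1)))
            assert angle_of_attack(lm) == pytest.approx(want, abs=1e-9)

    def test_degenerate_iac_axis_raises(self, reference_specimen):
        lm = dataclasses.replace(reference_specimen,
                                 iac_anterolateral=reference_specimen.iac_mid)
        with pytest.raises(GeometryError, match="IAC"):
            angle_of_attack(lm)


class TestPresigmoid:
    def test_trapezoid_formula(self, reference_specimen):
        """Fixture bases 19 (bulb to tegmen) and 16 (stored dural pair),
        depth |c| - r."""
        depth, area = presigmoid_measures(reference_specimen)
        want_depth = np.linalg.norm([-22.0, 0.0, 16.0]) - 6.0
        assert depth == pytest.approx(want_depth, abs=1e-9)
        assert area == pytest.approx(0.5 * (19.0 + 16.0) * want_depth, abs=1e-9)

    def test_equal_bases_reduce_to_rectangle(self, reference_specimen):
        lm = dataclasses.replace(
            reference_specimen,
            jugular_bulb_top=np.array([-20.0, -4.0, 14.0]),  # base 16 = lateral base
            presigmoid_dura_sup=reference_specimen.ss_medial_border + [0, 8.0, 0],
            presigmoid_dura_inf=reference_specimen.ss_medial_border - [0, 8.0, 0])
        depth, area = presigmoid_measures(lm)
        assert area == pytest.approx(16.0 * depth, rel=1e-12)

    def test_exposure_measures_invariant_under_rigid_motion(self, reference_specimen):
        R = Rotation.from_euler("zyx", [0.9, -0.3, 0.5]).as_matrix()
        em0 = compute_exposure(reference_specimen)
        em1 = compute_exposure(reference_specimen.transformed(R, [10.0, 5.0, -7.0]))
        for f in ("ea_iac", "ea_bulb", "aa", "presigmoid_depth", "presigmoid_area"):
            assert getattr(em1, f) == pytest.approx(getattr(em0, f), rel=1e-6)

    def test_angles_scale_invariant_areas_quadratic(self, reference_specimen):
        em0 = compute_exposure(reference_specimen)
        em3 = compute_exposure(reference_specimen.scaled(3.0))
        assert em3.ea_iac == pytest.approx(em0.ea_iac, abs=1e-9)
        assert em3.aa == pytest.approx(em0.aa, abs=1e-9)
        assert em3.presigmoid_depth == pytest.approx(3.0 * em0.presigmoid_depth)
        assert em3.presigmoid_area == pytest.approx(9.0 * em0.presigmoid_area)
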