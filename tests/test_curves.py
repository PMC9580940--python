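"""Curve families, natural-spline interpolation and loop scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from navdiagram.curves import (
    CurveError,
    CurveParams,
    LoopScaleSpec,
    Point,
    arc_length,
    control_points,
    loop_extent,
    natural_spline,
    pore_control_points,
    solve_extent_for_arclength,
    terminal_control_points,
)

A1, A2 = Point(100, 300), Point(140, 300)


class TestControlPoints:
    def test_simple_apex_at_midpoint(self):
        pts = control_points(CurveParams("simple", delta_y=40), A1, A2, +1)
        assert pts == [A1, Point(120, 340), A2]

    def test_simple_direction_up(self):
        pts = control_points(CurveParams("simple", delta_y=40), A1, A2, -1)
        assert pts[1] == Point(120, 260)

    def test_bulb_flanks_outward(self):
        pts = control_points(
            CurveParams("bulb", delta_y=40, p_y=0.5, delta_x=10), A1, A2, +1
        )
        assert pts == [A1, Point(90, 320), Point(120, 340), Point(150, 320), A2]

    def test_swirl_flanks_toward_centroid(self):
        pts = control_points(
            CurveParams("swirl", delta_y=40, p_y=0.5, delta_cx=0.5), A1, A2, +1
        )
        assert pts[1] == Point(110, 320)
        assert pts[3] == Point(130, 320)

    def test_swirl_crosses_past_centroid(self):
        pts = control_points(
            CurveParams("swirl", delta_y=40, p_y=0.5, delta_cx=3.0), A1, A2, +1
        )
        # delta_cx > 2 pushes each flank beyond the far anchor: flanks cross
        assert pts[1].x > pts[3].x

    def test_mushroom_low_points_flank_bulb(self):
        pts = control_points(
            CurveParams("mushroom", delta_y=40, p_y=0.5, delta_x=10,
                        delta_cx=0.5, p_y2=0.25),
            A1, A2, +1,
        )
        assert pts[1] == Point(110, 310)
        assert pts[5] == Point(130, 310)
        assert len(pts) == 7

    def test_anchor_order_and_extent_validated(self):
        with pytest.raises(CurveError, match="anchors"):
            control_points(CurveParams("simple"), A2, A1, +1)
        with pytest.raises(CurveError, match="delta_y"):
            control_points(CurveParams("simple", delta_y=-5), A1, A2, +1)

    def test_mushroom_requires_p_y2_below_p_y(self):
        with pytest.raises(CurveError, match="p_y2"):
            CurveParams("mushroom", p_y=0.3, p_y2=0.5)

    @pytest.mark.parametrize("kind", ["bulb", "swirl"])
    def test_degenerate_flanks_reduce_to_simple(self, kind):
        params = CurveParams(kind, delta_y=40, p_y=1.0, delta_x=0, delta_cx=0)
        got = natural_spline(control_points(params, A1, A2, +1), 65)
        ref = natural_spline(control_points(CurveParams("simple", delta_y=40), A1, A2, +1), 65)
        assert np.allclose(got.as_array(), ref.as_array(), atol=1e-6)


class TestPoreCurve:
    def test_deepest_control_at_requested_depth(self):
        pts = pore_control_points(Point(200, 200), Point(240, 200), 200, 280, 0.6)
        assert max(p.y for p in pts) == pytest.approx(248.0)
        assert pts[0] == Point(200, 200) and pts[-1] == Point(240, 200)

    def test_symmetric_anchors_mirror_symmetric_controls(self):
        pts = pore_control_points(Point(200, 200), Point(240, 200), 200, 280, 0.6)
        mirrored = sorted((round(440 - p.x, 9), round(p.y, 9)) for p in pts)
        assert mirrored == sorted((round(p.x, 9), round(p.y, 9)) for p in pts)

    def test_depth_fraction_validated(self):
        with pytest.raises(CurveError):
            pore_control_points(Point(200, 200), Point(240, 200), 200, 280, 0.0)
        with pytest.raises(CurveError, match="extracellular"):
            pore_control_points(Point(200, 250), Point(240, 250), 200, 280, 0.5)


class TestTerminalCurve:
    def test_free_end_at_offsets(self):
        pts = terminal_control_points(
            Point(80, 320), CurveParams("n_curve", delta_y=60, delta_x=40), +1, "left"
        )
        assert pts[0] == Point(80, 320)
        assert pts[-1] == Point(40, 380)
        assert len(pts) >= 3

    def test_mirrored_side_flips_x(self):
        left = terminal_control_points(
            Point(80, 320), CurveParams("n_curve", delta_y=60, delta_x=40), +1, "left"
        )
        right = terminal_control_points(
            Point(80, 320), CurveParams("n_curve", delta_y=60, delta_x=40), +1, "right"
        )
        for pl, pr in zip(left, right):
            assert pr.x - 80 == pytest.approx(-(pl.x - 80))
            assert pr.y == pl.y

    def test_zero_extent_rejected(self):
        with pytest.raises(CurveError):
            terminal_control_points(
                Point(80, 320), CurveParams("n_curve", delta_y=0), +1, "left"
            )


class TestNaturalSpline:
    def test_two_points_degenerate_to_segment(self):
        pl = natural_spline([Point(0, 0), Point(10, 5)], 16)
        arr = pl.as_array()
        assert np.allclose(arr[:, 1], arr[:, 0] * 0.5, atol=1e-12)

    def test_collinear_controls_stay_collinear(self):
        pl = natural_spline([Point(0, 0), Point(5, 5), Point(10, 10), Point(20, 20)], 97)
        arr = pl.as_array()
        assert np.max(np.abs(arr[:, 1] - arr[:, 0])) < 1e-9

    def test_passes_through_every_control_point(self):
        controls = [Point(0, 0), Point(10, 40), Point(30, 10), Point(50, 50)]
        # knots coincide with samples when n_samples-1 is a multiple of n-1
        pl = natural_spline(controls, 3 * 16 + 1)
        arr = pl.as_array()
        for i, c in enumerate(controls):
            s = arr[i * 16]
            assert abs(s[0] - c.x) < 1e-9 and abs(s[1] - c.y) < 1e-9

    def test_mirror_symmetric_controls_give_symmetric_samples(self):
        controls = [Point(0, 0), Point(10, 30), Point(20, 45), Point(30, 30), Point(40, 0)]
        arr = natural_spline(controls, 101).as_array()
        mirrored = arr[::-1].copy()
        mirrored[:, 0] = 40 - mirrored[:, 0]
        assert np.allclose(arr, mirrored, atol=1e-9)

    def test_duplicate_consecutive_controls_rejected(self):
        with pytest.raises(CurveError, match="duplicate"):
            natural_spline([Point(0, 0), Point(0, 0), Point(1, 1)])

    def test_endpoints_exact(self):
        pl = natural_spline([A1, Point(120, 340), A2])
        assert pl.points[0] == A1 and pl.points[-1] == A2


class TestArcLength:
    def test_pythagorean_segment(self):
        assert arc_length([Point(0, 0), Point(3, 4)]) == pytest.approx(5.0)

    def test_closed_square(self):
        sq = [Point(0, 0), Point(10, 0), Point(10, 10), Point(0, 10), Point(0, 0)]
        assert arc_length(sq) == pytest.approx(40.0)

    def test_refinement_convergence(self):
        controls = control_points(CurveParams("bulb", delta_y=60), A1, A2, +1)
        l1 = arc_length(natural_spline(controls, 128))
        l2 = arc_length(natural_spline(controls, 256))
        assert abs(l2 - l1) / l2 < 0.01


class TestLoopExtent:
    def test_scaled_linear(self):
        spec = LoopScaleSpec(mode="scaled", scale_law="linear", max_height=60)
        assert loop_extent(spec, 20, [10, 20, 30], "x").delta_y == pytest.approx(40.0)

    def test_fixed_ignores_residue_count(self):
        spec = LoopScaleSpec(mode="fixed", fixed_height=35)
        for n in (1, 10, 500):
            assert loop_extent(spec, n, [n], "x").delta_y == 35

    def test_custom_lookup_and_missing_id(self):
        spec = LoopScaleSpec(mode="custom", custom_heights={"idloop_1": 77})
        assert loop_extent(spec, 10, [10], "idloop_1").delta_y == 77
        with pytest.raises(CurveError, match="idloop_2"):
            loop_extent(spec, 10, [10], "idloop_2")

    @pytest.mark.parametrize("law", ["linear", "power", "log"])
    def test_monotone_in_residue_count(self, law):
        spec = LoopScaleSpec(mode="scaled", scale_law=law, max_height=100,
                             power_exponent=0.5)
        peers = [5, 400]
        heights = [loop_extent(spec, n, peers, "x").delta_y
                   for n in (5, 10, 50, 100, 200, 400)]
        assert all(a <= b for a, b in zip(heights, heights[1:]))
        assert heights[-1] == pytest.approx(100.0)

    def test_reslen_arc_length_matches(self):
        spec = LoopScaleSpec(mode="reslen", px_per_residue=2.0)
        params = loop_extent(spec, 50, [50], "x",
                             params=CurveParams("simple"), a1=A1, a2=A2, direction=+1)
        pl = natural_spline(control_points(params, A1, A2, +1))
        assert arc_length(pl) == pytest.approx(100.0, abs=0.5)


class TestSolveExtent:
    def test_self_consistency(self):
        dy = solve_extent_for_arclength(100.0, CurveParams("simple"), A1, A2, +1)
        pl = natural_spline(control_points(CurveParams("simple", delta_y=dy), A1, A2, +1))
        assert arc_length(pl) == pytest.approx(100.0, abs=0.5)

    def test_target_at_chord_gives_flat_curve(self):
        dy = solve_extent_for_arclength(40.0, CurveParams("simple"), A1, A2, +1)
        assert dy < 5.0

    def test_target_below_chord_rejected(self):
        with pytest.raises(CurveError, match="chord"):
            solve_extent_for_arclength(10.0, CurveParams("simple"), A1, A2, +1)

    def test_unreachable_target_with_fixed_horizontals_rejected(self):
        # the flattest mushroom is already longer than this target
        with pytest.raises(CurveError, match="not bracketed"):
            solve_extent_for_arclength(
                60.0, CurveParams("mushroom", delta_x=20, delta_cx=0.5), A1, A2, +1
            )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        kind=st.sampled_from(["simple", "bulb", "swirl", "mushroom"]),
        dy1=st.floats(5, 100),
        dy2=st.floats(5, 100),
    )
    def test_arc_length_monotone_in_extent(self, kind, dy1, dy2):
        """The bisection's premise: arc length grows with delta_y."""
        lo, hi = sorted((dy1, dy2))
        if hi - lo < 1e-6:
            return
        def length(dy):
            pl = natural_spline(control_points(CurveParams(kind, delta_y=dy), A1, A2, +1), 200)
            return arc_length(pl)
        assert length(lo) <= length(hi) + 1e-9
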