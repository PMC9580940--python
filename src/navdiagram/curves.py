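"""Loop-curve geometry: control-point families, natural splines, scaling modes.

Every loop in the diagram is a natural cubic spline through a small set of
control points.  Four families cover short and long loops — *simple* (anchor,
apex, anchor), *bulb* (two flank points pushed outward by Δx), *swirl* (flanks
placed toward or past the anchor centroid by Δcx, crossing when Δcx > 2) and
*mushroom* (two extra low points between anchors and bulb flanks).  Pore
loops use a reentrant hairpin dipping into the membrane band and termini an
open S-shaped tail.

Loop vertical extent Δy comes from one of four scaling modes: a fixed height,
a height scaled by residue count (linear / power / log law, normalized per
loop class), a residue-length mode in which the curve's arc length is a fixed
number of pixels per residue (solved by bisection on Δy), or explicit
per-loop custom heights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "Point",
    "CurveParams",
    "LoopScaleSpec",
    "Polyline",
    "CurveError",
    "control_points",
    "pore_control_points",
    "terminal_control_points",
    "natural_spline",
    "arc_length",
    "loop_extent",
    "solve_extent_for_arclength",
    "default_samples",
]

CURVE_TYPES = ("simple", "bulb", "swirl", "mushroom", "pore", "n_curve")
SCALE_MODES = ("fixed", "scaled", "reslen", "custom")
SCALE_LAWS = ("linear", "power", "log")


class CurveError(ValueError):
    """Invalid curve parameters or anchors."""


class Point(NamedTuple):
    """Canvas coordinate; SVG convention, y grows downward."""

    x: float
    y: float


@dataclass(frozen=True)
class CurveParams:
    """Parameter set of the curve families.

    delta_y   — total vertical extent of the loop, px (> 0)
    p_y       — vertical proportion of delta_y for the bulb/swirl flank points
    delta_x   — outward horizontal flank offset for bulb, px
    delta_cx  — horizontal proportion toward the anchor centroid (swirl and
                mushroom); > 2 makes swirl flanks cross
    p_y2      — vertical proportion for the mushroom's low points; must be
                below p_y so they sit between anchors and bulb flanks
    """

    curve_type: str = "simple"
    delta_y: float = 60.0
    p_y: float = 0.5
    delta_x: float = 12.0
    delta_cx: float = 0.5
    p_y2: float = 0.25

    def __post_init__(self) -> None:
        if self.curve_type not in CURVE_TYPES:
            raise CurveError(f"unknown curve type {self.curve_type!r}")
        if not (0 < self.p_y <= 1):
            raise CurveError(f"p_y must be in (0, 1], got {self.p_y}")
        if not (0 < self.p_y2 < 1):
            raise CurveError(f"p_y2 must be in (0, 1), got {self.p_y2}")
        if self.delta_cx < 0:
            raise CurveError(f"delta_cx must be >= 0, got {self.delta_cx}")
        if self.curve_type == "mushroom" and self.p_y2 >= self.p_y:
            raise CurveError(
                f"mushroom requires p_y2 < p_y, got p_y2={self.p_y2} p_y={self.p_y}"
            )


@dataclass(frozen=True)
class LoopScaleSpec:
    """One of the four loop-length scaling modes."""

    mode: str = "fixed"
    fixed_height: float = 60.0
    scale_law: str = "linear"
    power_exponent: float = 0.5
    max_height: float = 120.0
    px_per_residue: float = 2.0
    custom_heights: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in SCALE_MODES:
            raise CurveError(f"unknown scale mode {self.mode!r}")
        if self.scale_law not in SCALE_LAWS:
            raise CurveError(f"unknown scale law {self.scale_law!r}")
        if self.mode == "reslen" and self.px_per_residue <= 0:
            raise CurveError("px_per_residue must be > 0 in reslen mode")


@dataclass(frozen=True)
class Polyline:
    """Densely sampled curve plus the control points that generated it."""

    points: tuple[Point, ...]
    control: tuple[Point, ...]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)

    @property
    def length(self) -> float:
        return arc_length(self)


def default_samples(n_controls: int) -> int:
    return max(64, 8 * n_controls)


# --------------------------------------------------------------------------
# Control-point families (Fig-style constructions)

def control_points(
    params: CurveParams, a1: Point, a2: Point, direction: int
) -> list[Point]:
    """Control points for the simple / bulb / swirl / mushroom families.

    ``a1`` and ``a2`` are the flanking helix anchors on one membrane face
    (a1.x < a2.x, equal y); ``direction`` is +1 for loops extending downward
    (intracellular face) and -1 for upward (extracellular).
    """
    if a1.x >= a2.x:
        raise CurveError(f"anchors out of order: a1.x={a1.x} >= a2.x={a2.x}")
    if a1.y != a2.y:
        raise CurveError("anchors must lie on one membrane face (equal y)")
    if params.delta_y <= 0:
        raise CurveError(f"delta_y must be > 0, got {params.delta_y}")
    if direction not in (+1, -1):
        raise CurveError("direction must be +1 or -1")

    cx = (a1.x + a2.x) / 2.0
    apex = Point(cx, a1.y + direction * params.delta_y)
    kind = params.curve_type

    if kind == "simple":
        return [a1, apex, a2]

    flank_y = a1.y + direction * params.p_y * params.delta_y
    if kind == "bulb":
        if params.delta_x == 0 and params.p_y == 1:
            return [a1, apex, a2]  # flanks carry no information: simple curve
        # flanks pushed outward, away from their closest anchor
        p_b1 = Point(a1.x - params.delta_x, flank_y)
        p_b2 = Point(a2.x + params.delta_x, flank_y)
        return [a1, p_b1, apex, p_b2, a2]

    if kind == "swirl":
        if params.delta_cx == 0 and params.p_y == 1:
            return [a1, apex, a2]
        # flanks placed toward (or past, when delta_cx > 2) the centroid
        p_w1 = Point(a1.x + params.delta_cx * (cx - a1.x), flank_y)
        p_w2 = Point(a2.x + params.delta_cx * (cx - a2.x), flank_y)
        return [a1, p_w1, apex, p_w2, a2]

    if kind == "mushroom":
        p_b1 = Point(a1.x - params.delta_x, flank_y)
        p_b2 = Point(a2.x + params.delta_x, flank_y)
        low_y = a1.y + direction * params.p_y2 * params.delta_y
        p_m1 = Point(a1.x + params.delta_cx * (cx - a1.x), low_y)
        p_m2 = Point(a2.x + params.delta_cx * (cx - a2.x), low_y)
        return [a1, p_m1, p_b1, apex, p_b2, p_m2, a2]

    raise CurveError(f"{kind!r} has no anchored-pair construction; "
                     "use pore_control_points / terminal_control_points")


def pore_control_points(
    a1: Point,
    a2: Point,
    membrane_top: float,
    membrane_bottom: float,
    depth_fraction: float,
    *,
    arch_fraction: float = 0.2,
    dip_inset: float = 0.25,
) -> list[Point]:
    """Reentrant pore-loop hairpin between two extracellular anchors.

    The chain descends from ``a1`` into the membrane band to
    ``depth_fraction`` of its thickness, turns, ascends to a small
    extracellular arch at the anchor midpoint, dips again and rejoins ``a2``
    — mirror-symmetric about the anchor midline.
    """
    if a1.x >= a2.x:
        raise CurveError(f"anchors out of order: a1.x={a1.x} >= a2.x={a2.x}")
    if not (0 < depth_fraction <= 1):
        raise CurveError(f"depth_fraction must be in (0, 1], got {depth_fraction}")
    if membrane_bottom <= membrane_top:
        raise CurveError("membrane_bottom must be below membrane_top")
    if a1.y > membrane_top or a2.y > membrane_top:
        raise CurveError("pore anchors must sit on or above the extracellular face")

    thickness = membrane_bottom - membrane_top
    deep_y = membrane_top + depth_fraction * thickness
    arch_y = membrane_top - arch_fraction * thickness
    w = a2.x - a1.x
    cx = (a1.x + a2.x) / 2.0
    return [
        a1,
        Point(a1.x + dip_inset * w, deep_y),
        Point(cx, arch_y),
        Point(a2.x - dip_inset * w, deep_y),
        a2,
    ]


def terminal_control_points(
    anchor: Point, params: CurveParams, direction: int, side: str
) -> list[Point]:
    """Open S-shaped tail for the N- or C-terminal loop.

    Extends ``delta_y`` away from the membrane face and ``delta_x``
    horizontally toward ``side`` ('left' or 'right'); the last control point
    is the free terminus.
    """
    if params.delta_y <= 0:
        raise CurveError(f"delta_y must be > 0, got {params.delta_y}")
    if direction not in (+1, -1):
        raise CurveError("direction must be +1 or -1")
    if side not in ("left", "right"):
        raise CurveError(f"side must be 'left' or 'right', got {side!r}")
    sx = -1.0 if side == "left" else 1.0
    dy = direction * params.delta_y
    dx = sx * params.delta_x
    return [
        anchor,
        Point(anchor.x - 0.30 * dx, anchor.y + 0.35 * dy),  # counter-bend
        Point(anchor.x + 0.45 * dx, anchor.y + 0.70 * dy),
        Point(anchor.x + dx, anchor.y + dy),  # free terminus
    ]


# --------------------------------------------------------------------------
# Spline interpolation and arc length

def natural_spline(control: Sequence[Point], n_samples: int | None = None) -> Polyline:
    """Natural cubic spline through the control points.

    Uniform parameterization over control indices; zero second derivative at
    both ends.  With two control points the spline degenerates to the
    straight segment.
    """
    control = [Point(float(p[0]), float(p[1])) for p in control]
    if len(control) < 2:
        raise CurveError("need at least 2 control points")
    for p, q in zip(control, control[1:]):
        if p == q:
            raise CurveError(f"duplicate consecutive control point {p}")
    if n_samples is None:
        n_samples = default_samples(len(control))
    if n_samples < len(control):
        raise CurveError("n_samples must be >= number of control points")

    t = np.arange(len(control), dtype=float)
    ts = np.linspace(0.0, float(len(control) - 1), n_samples)
    arr = np.asarray(control, dtype=float)
    if len(control) == 2:
        xs = np.interp(ts, t, arr[:, 0])
        ys = np.interp(ts, t, arr[:, 1])
    else:
        cs = CubicSpline(t, arr, bc_type="natural", axis=0)
        out = cs(ts)
        xs, ys = out[:, 0], out[:, 1]
    pts = [Point(float(x), float(y)) for x, y in zip(xs, ys)]
    # endpoints exact regardless of float noise
    pts[0], pts[-1] = control[0], control[-1]
    return Polyline(points=tuple(pts), control=tuple(control))


def arc_length(p: Polyline | Sequence[Point]) -> float:
    """Total Euclidean length of the sampled polyline."""
    arr = p.as_array() if isinstance(p, Polyline) else np.asarray(p, dtype=float)
    if len(arr) < 2:
        raise CurveError("need at least 2 samples")
    return float(np.sum(np.linalg.norm(np.diff(arr, axis=0), axis=1)))


# --------------------------------------------------------------------------
# Scaling modes

def _scale_law(law: str, exponent: float) -> Callable[[float], float]:
    if law == "linear":
        return lambda n: n
    if law == "power":
        return lambda n: n ** exponent
    return lambda n: math.log(n + 1.0)


def loop_extent(
    spec: LoopScaleSpec,
    n_residues: int,
    class_peers: Sequence[int],
    loop_id: str,
    *,
    params: CurveParams | None = None,
    a1: Point | None = None,
    a2: Point | None = None,
    direction: int = +1,
) -> CurveParams:
    """Resolve a loop's vertical extent under the configured scaling mode.

    Returns ``params`` with ``delta_y`` overridden.  ``class_peers`` are the
    residue counts of all loops of the same class (short/long/pore/terminal),
    used to normalize the scaled mode per class.  Reslen mode additionally
    needs the curve parameters and anchors so the arc length can be solved.
    """
    if n_residues < 1:
        raise CurveError("n_residues must be >= 1")
    base = params if params is not None else CurveParams()

    if spec.mode == "fixed":
        return replace(base, delta_y=spec.fixed_height)

    if spec.mode == "scaled":
        if not class_peers:
            raise CurveError("scaled mode needs nonempty class_peers")
        f = _scale_law(spec.scale_law, spec.power_exponent)
        n_max = max(class_peers)
        dy = spec.max_height * f(float(n_residues)) / f(float(n_max))
        return replace(base, delta_y=dy)

    if spec.mode == "custom":
        if loop_id not in spec.custom_heights:
            raise CurveError(f"custom mode: no height for loop {loop_id!r}")
        return replace(base, delta_y=float(spec.custom_heights[loop_id]))

    # reslen: total curve arc length = px_per_residue * n_residues
    if a1 is None or a2 is None:
        raise CurveError("reslen mode needs anchors a1 and a2")
    target = spec.px_per_residue * n_residues
    dy = solve_extent_for_arclength(target, base, a1, a2, direction)
    return replace(base, delta_y=dy)


def _bisect_arclength(
    target: float,
    make_controls: Callable[[float], list[Point]],
    chord: float,
    *,
    max_iter: int = 200,
) -> float:
    """Bisection on the vertical extent until arc length matches ``target``.

    Arc length is monotone increasing in the extent for every curve family
    (with the other parameters fixed), so plain bisection converges.
    """
    if target < chord:
        raise CurveError(
            f"target arc length {target:.3g} shorter than the anchor chord {chord:.3g}"
        )
    tol = max(0.5, 1e-3 * target)

    def length_at(dy: float) -> float:
        controls = make_controls(dy)
        return arc_length(natural_spline(controls))

    lo, hi = 1e-9, 20.0 * max(target, 1.0)
    floor_len = length_at(lo)
    if floor_len > target + tol:
        # fixed horizontal parameters already make the flat curve too long
        raise CurveError(
            f"target arc length {target:.3g} not bracketed: the flattest curve "
            f"of this family is already {floor_len:.3g} px long"
        )
    if floor_len >= target - tol:
        return lo  # target is (near) the flat-curve length
    if length_at(hi) < target:
        raise CurveError(f"target arc length {target:.3g} not bracketed")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        err = length_at(mid) - target
        if abs(err) <= tol:
            return mid
        if err < 0:
            lo = mid
        else:
            hi = mid
    raise CurveError(f"arc-length bisection did not converge for target {target:.3g}")


def solve_extent_for_arclength(
    target: float, params: CurveParams, a1: Point, a2: Point, direction: int
) -> float:
    """Solve for the delta_y giving the requested total arc length."""
    chord = math.hypot(a2.x - a1.x, a2.y - a1.y)
    return _bisect_arclength(
        target,
        lambda dy: control_points(replace(params, delta_y=dy), a1, a2, direction),
        chord,
    )
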