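"""Canvas partitioning, helix placement, loop anchoring and per-residue coordinates.

The layout proceeds in a fixed order: the membrane band and helix slots are
computed from the style, helices are placed in their slots with anchor points
on the two band faces, loops are drawn class by class (short, pore, long,
termini) between their flanking anchors, and finally every residue of the
chain receives one canvas coordinate — evenly spaced along helix axes and by
arc length along loop polylines.  The extracellular face is at the top of the
canvas (SVG y grows downward) and the whole layout is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .curves import (
    CurveError,
    CurveParams,
    LoopScaleSpec,
    Point,
    Polyline,
    _bisect_arclength,
    control_points,
    loop_extent,
    natural_spline,
    pore_control_points,
    terminal_control_points,
)
from .style import StyleConfig
from .topology import TopologyElement, TopologyModel

__all__ = [
    "LayoutError",
    "Regions",
    "AnchorPoint",
    "LayoutResult",
    "compute_regions",
    "place_membrane",
    "place_helices",
    "place_loops",
    "assign_residue_coordinates",
    "layout",
]


log = logging.getLogger(__name__)


class LayoutError(ValueError):
    """Canvas cannot accommodate the topology, or internal inconsistency."""


#: Minimal vertical extent used when a reslen target is unreachable (the
#: flattest curve of the family is already at least as long as the target).
_FLAT_EXTENT = 1e-9


@dataclass
class Regions:
    canvas_width: float
    canvas_height: float
    border: float
    membrane_top: float
    membrane_bottom: float
    helix_slots: list[tuple[float, float]]  # (x_start, x_end) per helix, in order

    @property
    def drawable_width(self) -> float:
        return self.canvas_width - 2 * self.border


@dataclass(frozen=True)
class AnchorPoint:
    position: Point
    domain_index: int
    helix_index: int
    end: str  # top|bottom


@dataclass
class LayoutResult:
    regions: Regions
    membrane_geometry: dict
    helix_geometries: list[dict]
    anchors: list[AnchorPoint]
    loop_polylines: dict[int, Polyline]  # element index in topology.elements
    residue_coordinates: dict[int, Point] = field(default_factory=dict)

    def anchor(self, domain_index: int, helix_index: int, end: str) -> AnchorPoint:
        for a in self.anchors:
            if (a.domain_index, a.helix_index, a.end) == (domain_index, helix_index, end):
                return a
        raise LayoutError(f"no anchor for D{domain_index} S{helix_index} {end}")


def compute_regions(style: StyleConfig, topology: TopologyModel) -> Regions:
    """Partition the canvas into membrane band and ordered helix slots."""
    canvas = style["canvas"]
    hel = style["helices"]
    mem = style["membrane"]
    W, H, border = canvas["width"], canvas["height"], canvas["border"]

    helices = topology.helices()
    n = len(helices)
    w, g, G = hel["width"], hel["intra_gap"], hel["inter_gap"]

    # slot positions: domains separated by G, helices inside a domain by g
    slots: list[tuple[float, float]] = []
    x = float(border)
    prev_domain = None
    for e in helices:
        if prev_domain is not None:
            x += G if e.domain_index != prev_domain else g
        slots.append((x, x + w))
        x += w
        prev_domain = e.domain_index
    needed = x + border
    if needed > W:
        raise LayoutError(
            f"canvas width {W} too small for {n} helices; minimum width {needed:.0f}"
        )

    centre = H * mem["band_fraction"]
    top = centre - mem["thickness"] / 2.0
    bottom = centre + mem["thickness"] / 2.0
    if top <= 0 or bottom >= H:
        raise LayoutError("membrane band falls outside the canvas")
    return Regions(W, H, border, top, bottom, slots)


def place_membrane(regions: Regions, style: StyleConfig) -> dict:
    """Membrane geometry: a box, or a two-leaflet bilayer of lipid heads."""
    mem = style["membrane"]
    geo: dict = {
        "draw_type": mem["draw_type"],
        "x": regions.border,
        "width": regions.drawable_width,
        "top": regions.membrane_top,
        "bottom": regions.membrane_bottom,
        "fill": mem["fill"],
        "opacity": mem["opacity"],
    }
    if mem["draw_type"] == "bilayer":
        r = mem["head_radius"]
        per_row = int(regions.drawable_width // (2 * r))
        heads = []
        for row_y, tail_dir in ((regions.membrane_top + r, +1),
                                (regions.membrane_bottom - r, -1)):
            for i in range(per_row):
                heads.append({
                    "cx": regions.border + r + 2 * r * i,
                    "cy": row_y,
                    "r": r,
                    "tail_dir": tail_dir,
                })
        geo["heads"] = heads
        geo["head_fill"] = mem["head_fill"]
        geo["tail_stroke"] = mem["tail_stroke"]
    return geo


def place_helices(
    topology: TopologyModel, regions: Regions, style: StyleConfig
) -> tuple[list[dict], list[AnchorPoint]]:
    """Helix rectangles spanning the band plus top/bottom anchor points.

    The chain's crossing direction alternates helix by helix, starting from
    the N-terminal face: with an intracellular N-terminus, S1 crosses
    bottom-to-top.
    """
    helices = topology.helices()
    if len(regions.helix_slots) != len(helices):
        raise LayoutError("slot count does not match helix count")

    # face the chain is on before each helix
    first_loop = topology.elements[0]
    entry_side = first_loop.side if first_loop.kind != "helix" else "intracellular"

    geometries: list[dict] = []
    anchors: list[AnchorPoint] = []
    side = entry_side
    for e, (x0, x1) in zip(helices, regions.helix_slots):
        cx = (x0 + x1) / 2.0
        geometries.append({
            "domain_index": e.domain_index,
            "helix_index": e.helix_index,
            "x": x0,
            "width": x1 - x0,
            "top": regions.membrane_top,
            "bottom": regions.membrane_bottom,
            "draw_type": style.get("helices.draw_type"),
            "fill": style.helix_fill(e.domain_index, e.helix_index),
            "stroke": style.get("helices.stroke"),
            "entry": "bottom" if side == "intracellular" else "top",
        })
        anchors.append(AnchorPoint(Point(cx, regions.membrane_top),
                                   e.domain_index, e.helix_index, "top"))
        anchors.append(AnchorPoint(Point(cx, regions.membrane_bottom),
                                   e.domain_index, e.helix_index, "bottom"))
        side = "extracellular" if side == "intracellular" else "intracellular"
    return geometries, anchors


def _reslen_unreachable(spec: LoopScaleSpec, exc: CurveError) -> bool:
    return spec.mode == "reslen" and (
        "not bracketed" in str(exc) or "chord" in str(exc)
    )


def _loop_class(kind: str) -> str:
    return {
        "short_loop": "short",
        "pore_loop": "pore",
        "long_loop": "long",
        "n_term": "terminal",
        "c_term": "terminal",
    }[kind]


def _loop_id(e: TopologyElement) -> str:
    if e.kind == "short_loop":
        return f"sloop_D{e.domain_index}_{e.range.start}"
    if e.kind == "pore_loop":
        return f"ploop_D{e.domain_index}"
    if e.kind == "long_loop":
        return f"idloop_{e.interdomain_index}"
    return "nterm" if e.kind == "n_term" else "cterm"


def place_loops(
    topology: TopologyModel,
    regions: Regions,
    anchors: list[AnchorPoint],
    style: StyleConfig,
) -> dict[int, Polyline]:
    """Draw every loop in order (short, pore, long, termini) between its anchors.

    Polylines are stored in chain order: from the preceding helix toward the
    following one (the N-terminal tail therefore runs free-end → anchor).
    """
    def anchor_for(e: TopologyElement, end: str) -> Point:
        for a in anchors:
            if (a.domain_index, a.helix_index, a.end) == (e.domain_index, e.helix_index, end):
                return a.position
        raise LayoutError(
            f"missing anchor for helix D{e.domain_index} S{e.helix_index} ({end})"
        )

    elements = topology.elements
    # residue counts per class for the scaled mode, normalized per class
    peers: dict[str, list[int]] = {}
    for e in elements:
        if e.kind != "helix":
            peers.setdefault(_loop_class(e.kind), []).append(e.n_residues)

    polylines: dict[int, Polyline] = {}
    order = ("short_loop", "pore_loop", "long_loop", "n_term", "c_term")
    for kind in order:
        for idx, e in enumerate(elements):
            if e.kind != kind:
                continue
            cls = _loop_class(kind)
            spec = style.scale_spec(cls)
            if kind in ("short_loop", "long_loop"):
                prev_h = next(x for x in reversed(elements[:idx]) if x.kind == "helix")
                next_h = next(x for x in elements[idx + 1:] if x.kind == "helix")
                end = "top" if e.side == "extracellular" else "bottom"
                direction = -1 if e.side == "extracellular" else +1
                a1 = anchor_for(prev_h, end)
                a2 = anchor_for(next_h, end)
                params = style.curve_params(cls)
                try:
                    params = loop_extent(
                        spec, e.n_residues, peers[cls], _loop_id(e),
                        params=params, a1=a1, a2=a2, direction=direction,
                    )
                except CurveError as exc:
                    if not _reslen_unreachable(spec, exc):
                        raise
                    # target unreachable: draw the flattest curve instead
                    log.warning("loop %s: %s; drawing flat", _loop_id(e), exc)
                    params = replace(params, delta_y=_FLAT_EXTENT)
                controls = control_points(params, a1, a2, direction)
                polylines[idx] = natural_spline(controls)
            elif kind == "pore_loop":
                prev_h = next(x for x in reversed(elements[:idx]) if x.kind == "helix")
                next_h = next(x for x in elements[idx + 1:] if x.kind == "helix")
                a1 = anchor_for(prev_h, "top")
                a2 = anchor_for(next_h, "top")
                pore = style.get("loops.pore")
                depth = pore["depth_fraction"]
                thickness = regions.membrane_bottom - regions.membrane_top
                if spec.mode == "reslen":
                    target = spec.px_per_residue * e.n_residues
                    chord = abs(a2.x - a1.x)
                    try:
                        deep = _bisect_arclength(
                            target,
                            lambda dyy: _pore_controls_by_extent(
                                a1, a2, regions, pore["arch_fraction"], dyy, thickness
                            ),
                            chord,
                        )
                    except CurveError as exc:
                        if not _reslen_unreachable(spec, exc):
                            raise
                        log.warning("loop %s: %s; drawing flat", _loop_id(e), exc)
                        deep = _FLAT_EXTENT
                    controls = _pore_controls_by_extent(
                        a1, a2, regions, pore["arch_fraction"], deep, thickness
                    )
                else:
                    if spec.mode == "fixed":
                        depth = min(1.0, spec.fixed_height / thickness)
                    elif spec.mode == "scaled":
                        ext = loop_extent(spec, e.n_residues, peers[cls], _loop_id(e))
                        depth = min(1.0, ext.delta_y / thickness)
                    elif spec.mode == "custom":
                        ext = loop_extent(spec, e.n_residues, peers[cls], _loop_id(e))
                        depth = min(1.0, ext.delta_y / thickness)
                    controls = pore_control_points(
                        a1, a2, regions.membrane_top, regions.membrane_bottom,
                        depth, arch_fraction=pore["arch_fraction"],
                    )
                polylines[idx] = natural_spline(controls)
            else:  # termini
                if kind == "n_term":
                    h = next(x for x in elements if x.kind == "helix")
                    side = "left"
                else:
                    h = next(x for x in reversed(elements) if x.kind == "helix")
                    side = "right"
                end = "top" if e.side == "extracellular" else "bottom"
                direction = -1 if e.side == "extracellular" else +1
                anchor = anchor_for(h, end)
                params = style.curve_params("terminal")
                if spec.mode == "reslen":
                    target = spec.px_per_residue * e.n_residues
                    try:
                        dy = _bisect_arclength(
                            target,
                            lambda dyy: terminal_control_points(
                                anchor, _with_dy(params, dyy), direction, side
                            ),
                            0.0,
                        )
                    except CurveError as exc:
                        if not _reslen_unreachable(spec, exc):
                            raise
                        log.warning("loop %s: %s; drawing flat", _loop_id(e), exc)
                        dy = _FLAT_EXTENT
                    params = _with_dy(params, dy)
                else:
                    params = loop_extent(spec, e.n_residues, peers[cls], _loop_id(e),
                                         params=params)
                controls = terminal_control_points(anchor, params, direction, side)
                pl = natural_spline(controls)
                if kind == "n_term":
                    # chain order: free terminus first, anchor last
                    pl = Polyline(points=tuple(reversed(pl.points)),
                                  control=tuple(reversed(pl.control)))
                polylines[idx] = pl
    return polylines


def _with_dy(params: CurveParams, dy: float) -> CurveParams:
    return replace(params, delta_y=dy)


def _pore_controls_by_extent(
    a1: Point, a2: Point, regions: Regions, arch_fraction: float,
    deep_extent: float, thickness: float,
) -> list[Point]:
    depth = min(1.0, max(deep_extent / thickness, 1e-9))
    return pore_control_points(
        a1, a2, regions.membrane_top, regions.membrane_bottom, depth,
        arch_fraction=arch_fraction,
    )


def assign_residue_coordinates(
    result: LayoutResult, topology: TopologyModel
) -> dict[int, Point]:
    """Map every residue of the chain to exactly one canvas coordinate.

    Helix residues are evenly spaced along the helix axis from entry face to
    exit face; loop residues are evenly spaced by arc length along the loop
    polyline, leaving room at both ends so they sit strictly between the
    flanking helix ends.
    """
    coords: dict[int, Point] = {}
    helix_geo = {(g["domain_index"], g["helix_index"]): g for g in result.helix_geometries}

    for idx, e in enumerate(topology.elements):
        n = e.n_residues
        residues = range(e.range.start, e.range.end + 1)
        if e.kind == "helix":
            g = helix_geo[(e.domain_index, e.helix_index)]
            cx = g["x"] + g["width"] / 2.0
            y_entry = g["bottom"] if g["entry"] == "bottom" else g["top"]
            y_exit = g["top"] if g["entry"] == "bottom" else g["bottom"]
            ys = np.linspace(y_entry, y_exit, n) if n > 1 else [
                (y_entry + y_exit) / 2.0
            ]
            for r, y in zip(residues, ys):
                coords[r] = Point(cx, float(y))
        else:
            pl = result.loop_polylines[idx]
            arr = pl.as_array()
            seg = np.linalg.norm(np.diff(arr, axis=0), axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            total = cum[-1]
            # fractions i/(n+1): a 1-residue loop sits at the arc midpoint
            targets = total * np.arange(1, n + 1) / (n + 1)
            xs = np.interp(targets, cum, arr[:, 0])
            ys = np.interp(targets, cum, arr[:, 1])
            for r, x, y in zip(residues, xs, ys):
                coords[r] = Point(float(x), float(y))
    if len(coords) != topology.length:
        raise LayoutError(
            f"mapped {len(coords)} residues for a chain of {topology.length}"
        )
    return coords


def layout(topology: TopologyModel, style: StyleConfig) -> LayoutResult:
    """Run the full staged layout: membrane, helices, loops, residue coordinates."""
    regions = compute_regions(style, topology)
    membrane = place_membrane(regions, style)
    helix_geo, anchors = place_helices(topology, regions, style)
    loops = place_loops(topology, regions, anchors, style)
    result = LayoutResult(
        regions=regions,
        membrane_geometry=membrane,
        helix_geometries=helix_geo,
        anchors=anchors,
        loop_polylines=loops,
    )
    result.residue_coordinates = assign_residue_coordinates(result, topology)
    return result
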