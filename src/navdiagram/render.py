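"""Assemble the layout, fills, edges and text into an SVG document.

Draw order follows the layout stages: membrane, helices, loops, relationship
edges, residue fill markers, then text — later fragments paint on top.
Every topology element gets exactly one ``<g>`` with a stable id
(``helix_D1_S4``, ``ploop_D2``, ``idloop_1``, ``nterm`` ...), so figures can
be post-edited or asserted on at fragment level.  Serialization is
deterministic: identical inputs re-render byte-identically.
"""

from __future__ import annotations

from lxml import etree

from .curves import Point, Polyline
from .layout import LayoutResult
from .style import StyleConfig
from .topology import TopologyElement, TopologyModel

__all__ = ["SvgDocument", "RenderError", "CapabilityError", "render_svg", "render_png"]

SVG_NS = "http://www.w3.org/2000/svg"


class RenderError(ValueError):
    pass


class CapabilityError(RuntimeError):
    """A requested output capability is not available in this installation."""


class SvgDocument:
    """Rendered SVG: the XML text plus an id → fragment index."""

    def __init__(self, root: etree._Element):
        self._root = root
        self.xml = etree.tostring(
            root, xml_declaration=True, encoding="UTF-8", pretty_print=True
        ).decode("utf-8")
        self.index = {
            el.get("id"): el for el in root.iter() if el.get("id") is not None
        }

    def __contains__(self, element_id: str) -> bool:
        return element_id in self.index

    def fragment(self, element_id: str) -> str:
        return etree.tostring(self.index[element_id], pretty_print=True).decode("utf-8")


def _fmt(v: float) -> str:
    """Fixed-precision coordinate formatting keeps serialization deterministic."""
    s = f"{v:.3f}".rstrip("0").rstrip(".")
    return s if s not in ("-0", "") else "0"


def _path_d(points: tuple[Point, ...]) -> str:
    cmds = [f"M {_fmt(points[0].x)} {_fmt(points[0].y)}"]
    cmds += [f"L {_fmt(p.x)} {_fmt(p.y)}" for p in points[1:]]
    return " ".join(cmds)


def element_id(e: TopologyElement) -> str:
    if e.kind == "helix":
        return f"helix_D{e.domain_index}_S{e.helix_index}"
    if e.kind == "short_loop":
        return f"sloop_D{e.domain_index}_{e.range.start}"
    if e.kind == "pore_loop":
        return f"ploop_D{e.domain_index}"
    if e.kind == "long_loop":
        return f"idloop_{e.interdomain_index}"
    return "nterm" if e.kind == "n_term" else "cterm"


def _sub(parent, tag, **attrs):
    el = etree.SubElement(parent, f"{{{SVG_NS}}}{tag}")
    for k, v in attrs.items():
        el.set(k.replace("_", "-") if k != "id" else k, str(v))
    return el


def _draw_membrane(parent, geo: dict) -> None:
    g = _sub(parent, "g", id="membrane")
    if geo["draw_type"] == "box":
        _sub(g, "rect", x=_fmt(geo["x"]), y=_fmt(geo["top"]),
             width=_fmt(geo["width"]), height=_fmt(geo["bottom"] - geo["top"]),
             fill=geo["fill"], opacity=_fmt(geo["opacity"]))
        return
    for head in geo["heads"]:
        r = head["r"]
        tail_y0 = head["cy"] + head["tail_dir"] * r
        tail_len = (geo["bottom"] - geo["top"]) / 2.0 - 2 * r
        for dx in (-r / 2.5, r / 2.5):
            _sub(g, "line",
                 x1=_fmt(head["cx"] + dx), y1=_fmt(tail_y0),
                 x2=_fmt(head["cx"] + dx),
                 y2=_fmt(tail_y0 + head["tail_dir"] * tail_len),
                 stroke=geo["tail_stroke"], stroke_width="1",
                 opacity=_fmt(geo["opacity"]))
        _sub(g, "circle", cx=_fmt(head["cx"]), cy=_fmt(head["cy"]), r=_fmt(r),
             fill=geo["head_fill"], opacity=_fmt(geo["opacity"]))


def _draw_helix(parent, geo: dict) -> None:
    gid = f"helix_D{geo['domain_index']}_S{geo['helix_index']}"
    g = _sub(parent, "g", id=gid)
    x, w = geo["x"], geo["width"]
    top, bottom = geo["top"], geo["bottom"]
    fill, stroke = geo["fill"], geo["stroke"]
    if geo["draw_type"] == "box":
        _sub(g, "rect", x=_fmt(x), y=_fmt(top), width=_fmt(w),
             height=_fmt(bottom - top), fill=fill, stroke=stroke)
    elif geo["draw_type"] == "cylinder":
        ry = w / 3.0
        _sub(g, "rect", x=_fmt(x), y=_fmt(top), width=_fmt(w),
             height=_fmt(bottom - top), fill=fill, stroke="none")
        _sub(g, "ellipse", cx=_fmt(x + w / 2), cy=_fmt(bottom), rx=_fmt(w / 2),
             ry=_fmt(ry), fill=fill, stroke=stroke)
        _sub(g, "line", x1=_fmt(x), y1=_fmt(top), x2=_fmt(x), y2=_fmt(bottom),
             stroke=stroke, stroke_width="1")
        _sub(g, "line", x1=_fmt(x + w), y1=_fmt(top), x2=_fmt(x + w),
             y2=_fmt(bottom), stroke=stroke, stroke_width="1")
        _sub(g, "ellipse", cx=_fmt(x + w / 2), cy=_fmt(top), rx=_fmt(w / 2),
             ry=_fmt(ry), fill=fill, stroke=stroke)
    else:  # cartoon: rounded ribbon
        _sub(g, "rect", x=_fmt(x), y=_fmt(top - w / 4), width=_fmt(w),
             height=_fmt(bottom - top + w / 2), rx=_fmt(w / 2), fill=fill,
             stroke=stroke)


def render_svg(
    layout_result: LayoutResult,
    topology: TopologyModel,
    style: StyleConfig,
    fills: dict[int, str] | None = None,
    edges: list | None = None,
    texts: list[dict] | None = None,
) -> SvgDocument:
    """Render the full diagram; all inputs must be bound to one topology."""
    fills = fills or {}
    edges = edges or []
    texts = texts or []

    canvas = style["canvas"]
    root = etree.Element(
        f"{{{SVG_NS}}}svg", nsmap={None: SVG_NS},
        width=_fmt(canvas["width"]), height=_fmt(canvas["height"]),
    )
    root.set("viewBox", f"0 0 {_fmt(canvas['width'])} {_fmt(canvas['height'])}")

    _draw_membrane(root, layout_result.membrane_geometry)
    for geo in layout_result.helix_geometries:
        _draw_helix(root, geo)

    for idx, e in enumerate(topology.elements):
        if e.kind == "helix":
            continue
        pl = layout_result.loop_polylines[idx]
        cls = {"short_loop": "short", "pore_loop": "pore", "long_loop": "long",
               "n_term": "terminal", "c_term": "terminal"}[e.kind]
        loop_style = style["loops"][cls]
        g = _sub(root, "g", id=element_id(e))
        _sub(g, "path", d=_path_d(pl.points), fill="none",
             stroke=loop_style["stroke"],
             stroke_width=_fmt(loop_style["stroke_width"]),
             stroke_linecap="round")

    for i, edge in enumerate(edges):
        g = _sub(root, "g", id=f"edge_{i}")
        p0, ctrl, p1 = edge.path
        d = (f"M {_fmt(p0.x)} {_fmt(p0.y)} "
             f"Q {_fmt(ctrl.x)} {_fmt(ctrl.y)} {_fmt(p1.x)} {_fmt(p1.y)}")
        _sub(g, "path", d=d, fill="none", stroke=edge.color,
             stroke_width=_fmt(edge.width),
             opacity=_fmt(style.get("edges.opacity")), stroke_linecap="round")

    if fills:
        _draw_residue_fills(root, layout_result, topology, style, fills)

    for i, t in enumerate(texts):
        g = _sub(root, "g", id=f"text_{i}")
        el = _sub(g, "text", x=_fmt(t["x"]), y=_fmt(t["y"]), fill=t["color"],
                  font_size=_fmt(t["font_size"]))
        el.set("font-family", t["font_family"])
        el.text = t["text"]

    return SvgDocument(root)


def _draw_residue_fills(root, layout_result, topology, style, fills) -> None:
    """Colored chain segments (default) or circles at residue coordinates."""
    markers = style["residue_markers"]
    g = _sub(root, "g", id="residue_fills")
    coords = layout_result.residue_coordinates
    if markers["mode"] == "circle":
        for r in sorted(fills):
            p = coords[r]
            _sub(g, "circle", id=f"residue_{r}", cx=_fmt(p.x), cy=_fmt(p.y),
                 r=_fmt(markers["radius"]), fill=fills[r])
        return
    # stroke mode: a short segment per residue between the midpoints toward
    # its neighbours within the same topology element
    for e in topology.elements:
        for r in range(e.range.start, e.range.end + 1):
            if r not in fills:
                continue
            p = coords[r]
            prev_p = coords[r - 1] if r - 1 >= e.range.start else p
            next_p = coords[r + 1] if r + 1 <= e.range.end else p
            a = Point((prev_p.x + p.x) / 2, (prev_p.y + p.y) / 2)
            b = Point((next_p.x + p.x) / 2, (next_p.y + p.y) / 2)
            if a == b:  # isolated residue: fall back to a dot
                _sub(g, "circle", id=f"residue_{r}", cx=_fmt(p.x), cy=_fmt(p.y),
                     r=_fmt(markers["radius"]), fill=fills[r])
                continue
            _sub(g, "path", id=f"residue_{r}",
                 d=f"M {_fmt(a.x)} {_fmt(a.y)} L {_fmt(p.x)} {_fmt(p.y)} "
                   f"L {_fmt(b.x)} {_fmt(b.y)}",
                 fill="none", stroke=fills[r],
                 stroke_width=_fmt(markers["radius"] * 2), stroke_linecap="round")


def render_png(svg: SvgDocument, dpi: float = 96.0) -> bytes:
    """Rasterize the SVG to PNG at the given dpi (96 = 1 px per canvas unit).

    Requires an SVG rasterizer (cairosvg); raises :class:`CapabilityError`
    when none is importable — the SVG path always works.
    """
    if not isinstance(svg, SvgDocument) or "<svg" not in svg.xml:
        raise RenderError("not a valid SVG document")
    try:
        import cairosvg  # type: ignore
    except ImportError as exc:
        raise CapabilityError(
            "PNG export needs the 'cairosvg' package; install it or export SVG"
        ) from exc
    return cairosvg.svg2png(bytestring=svg.xml.encode("utf-8"), dpi=dpi,
                            scale=dpi / 96.0)
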