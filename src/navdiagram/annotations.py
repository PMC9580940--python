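"""Residue properties, relationships, color rules, edges and text annotations.

Property tables map residue indices to named numeric values (CSV with a
``Resid`` header column, or a residue-keyed JSON object).  Relationship
tables connect residues or topology elements (``source, target, raw_weight,
type``) and are drawn as weight-scaled edges.  Color rules are one-line
strings — ``"ALL, by:Conservation,#ADD8E6;#0000FF, min;max"`` paints every
residue along a light-blue-to-blue gradient of its Conservation value —
applied in order, later rules overriding earlier ones.
"""

from __future__ import annotations

import io
import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.colors import CSS4_COLORS

from .curves import Point
from .topology import TopologyElement, TopologyModel

__all__ = [
    "AnnotationError",
    "PropertyTable",
    "Relationship",
    "ElementAddress",
    "ColorRule",
    "TextAnnotation",
    "EdgeGeometry",
    "load_properties",
    "load_relationships",
    "resolve_address",
    "parse_color_rule",
    "interpolate_color",
    "build_fill_map",
    "edge_geometry",
    "place_text",
]


class AnnotationError(ValueError):
    """Malformed table, address, rule or annotation."""


# --------------------------------------------------------------------------
# Colors

_HEX = re.compile(r"^#[0-9a-fA-F]{6}$")


def normalize_color(spec: str) -> str:
    """Resolve an SVG/CSS keyword or #RRGGBB string to lowercase #rrggbb."""
    spec = spec.strip()
    if _HEX.match(spec):
        return spec.lower()
    key = spec.lower()
    if key in CSS4_COLORS:
        return CSS4_COLORS[key].lower()
    raise AnnotationError(f"unknown color {spec!r}")


def interpolate_color(c0: str, c1: str, t: float) -> str:
    """Per-channel linear interpolation in 8-bit sRGB, half away from zero."""
    if not (0.0 <= t <= 1.0):
        warnings.warn(f"gradient position {t} clamped to [0, 1]", stacklevel=2)
        t = min(1.0, max(0.0, t))
    c0, c1 = normalize_color(c0), normalize_color(c1)
    if t == 0.0:
        return c0
    if t == 1.0:
        return c1
    out = []
    for i in (1, 3, 5):
        v0 = int(c0[i:i + 2], 16)
        v1 = int(c1[i:i + 2], 16)
        v = v0 + (v1 - v0) * t
        out.append(int(v + 0.5) if v >= 0 else -int(-v + 0.5))
    return "#" + "".join(f"{v:02x}" for v in out)


# --------------------------------------------------------------------------
# Property tables (CSV per the Resid schema, or residue-keyed JSON)

@dataclass
class PropertyTable:
    values: dict[int, dict[str, float]]
    names: list[str]

    def column(self, name: str) -> dict[int, float]:
        if name not in self.names:
            raise AnnotationError(f"unknown property {name!r}")
        return {r: v[name] for r, v in self.values.items() if name in v}


def load_properties(doc: str) -> PropertyTable:
    """Load a property table from CSV (``Resid`` header) or JSON text.

    Both dialects with equivalent content produce identical tables.
    """
    text = doc.strip()
    if text.startswith("{"):
        try:
            obj = json.loads(text)
        except json.JSONDecodeError as exc:
            raise AnnotationError(f"malformed property JSON: {exc.msg}") from exc
        values: dict[int, dict[str, float]] = {}
        names: list[str] = []
        for key, props in obj.items():
            try:
                resid = int(key)
            except ValueError as exc:
                raise AnnotationError(f"non-integer residue key {key!r}") from exc
            if not isinstance(props, dict):
                raise AnnotationError(f"residue {key}: expected a name→value map")
            row = {}
            for name, v in props.items():
                if not isinstance(v, (int, float)) or isinstance(v, bool):
                    raise AnnotationError(
                        f"residue {key}, property {name!r}: non-numeric value {v!r}"
                    )
                row[name] = float(v)
                if name not in names:
                    names.append(name)
            values[resid] = row
        return PropertyTable(values=dict(sorted(values.items())), names=names)

    try:
        frame = pd.read_csv(io.StringIO(text), dtype=str, skipinitialspace=True)
    except Exception as exc:
        raise AnnotationError(f"malformed property CSV: {exc}") from exc
    if frame.empty and frame.columns.empty:
        raise AnnotationError("empty property table")
    if frame.columns[0].strip() != "Resid":
        raise AnnotationError(
            f"first property column must be 'Resid', got {frame.columns[0]!r}"
        )
    names = [c.strip() for c in frame.columns[1:]]
    values = {}
    for i, row in frame.iterrows():
        try:
            resid = int(str(row.iloc[0]).replace(",", ""))
        except ValueError as exc:
            raise AnnotationError(f"row {i + 2}: non-integer Resid {row.iloc[0]!r}") from exc
        entry = {}
        for name, cell in zip(names, row.iloc[1:]):
            if pd.isna(cell) or str(cell).strip() == "":
                continue
            try:
                entry[name] = float(cell)
            except ValueError as exc:
                raise AnnotationError(
                    f"row {i + 2}, column {name!r}: non-numeric value {cell!r}"
                ) from exc
        values[resid] = entry
    return PropertyTable(values=dict(sorted(values.items())), names=names)


# --------------------------------------------------------------------------
# Element addresses

_ROMAN = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100, "D": 500, "M": 1000}


def _roman_to_int(s: str) -> int:
    total, prev = 0, 0
    for ch in reversed(s.upper()):
        if ch not in _ROMAN:
            raise AnnotationError(f"invalid roman numeral {s!r}")
        v = _ROMAN[ch]
        total = total - v if v < prev else total + v
        prev = max(prev, v)
    if total <= 0:
        raise AnnotationError(f"invalid roman numeral {s!r}")
    return total


_ADDR_DOMAIN = re.compile(r"^Domain([IVXLCDM]+)\s*;\s*Helix(\d+)$", re.IGNORECASE)
_ADDR_INTERDOM = re.compile(r"^InterDomain(\d+)\s*;\s*Loop$", re.IGNORECASE)


@dataclass(frozen=True)
class ElementAddress:
    """Parsed address: a residue index, a (domain, helix), an interdomain
    loop index, or a terminus."""

    raw: str
    kind: str  # residue|helix|interdomain|n_term|c_term
    residue: int | None = None
    domain: int | None = None
    helix: int | None = None
    interdomain: int | None = None

    @classmethod
    def parse(cls, raw: object) -> "ElementAddress":
        text = str(raw).strip().replace(",", "")
        if re.fullmatch(r"\d+", text):
            return cls(raw=str(raw), kind="residue", residue=int(text))
        m = _ADDR_DOMAIN.match(text)
        if m:
            return cls(raw=str(raw), kind="helix",
                       domain=_roman_to_int(m.group(1)), helix=int(m.group(2)))
        m = _ADDR_INTERDOM.match(text)
        if m:
            return cls(raw=str(raw), kind="interdomain", interdomain=int(m.group(1)))
        if text.lower() == "nterm":
            return cls(raw=str(raw), kind="n_term")
        if text.lower() == "cterm":
            return cls(raw=str(raw), kind="c_term")
        raise AnnotationError(f"unparseable element address {raw!r}")


@dataclass(frozen=True)
class Relationship:
    source: ElementAddress
    target: ElementAddress
    raw_weight: float
    type: str


def load_relationships(doc: str) -> list[Relationship]:
    """Load relationships from CSV (source,target,raw_weight,type) or a JSON list."""
    text = doc.strip()
    if text.startswith("["):
        try:
            items = json.loads(text)
        except json.JSONDecodeError as exc:
            raise AnnotationError(f"malformed relationship JSON: {exc.msg}") from exc
        rows = []
        for i, item in enumerate(items):
            missing = {"source", "target", "raw_weight", "type"} - set(item)
            if missing:
                raise AnnotationError(f"item {i}: missing keys {sorted(missing)}")
            rows.append((item["source"], item["target"], item["raw_weight"], item["type"]))
    else:
        frame = pd.read_csv(io.StringIO(text), dtype=str, skipinitialspace=True)
        cols = {c.strip().lower(): c for c in frame.columns}
        required = ["source", "target", "raw_weight", "type"]
        missing = [c for c in required if c not in cols]
        if missing:
            raise AnnotationError(f"relationship table missing columns {missing}")
        rows = [
            (row[cols["source"]], row[cols["target"]],
             row[cols["raw_weight"]], row[cols["type"]])
            for _, row in frame.iterrows()
        ]

    out = []
    for i, (src, tgt, w, typ) in enumerate(rows):
        try:
            weight = float(str(w).replace(",", ""))
        except (TypeError, ValueError) as exc:
            raise AnnotationError(f"row {i + 1}: non-numeric raw_weight {w!r}") from exc
        out.append(Relationship(
            source=ElementAddress.parse(src),
            target=ElementAddress.parse(tgt),
            raw_weight=weight,
            type=str(typ).strip(),
        ))
    return out


def resolve_address(
    address: ElementAddress | str, topology: TopologyModel
) -> tuple[set[int], TopologyElement | None]:
    """Resolve an address to its residue set and the element it names.

    For a bare residue the element is None; the caller anchors at the residue
    coordinate.  Helix addresses anchor at the helix centre, interdomain-loop
    and terminus addresses at their polyline midpoint.
    """
    if isinstance(address, str):
        address = ElementAddress.parse(address)
    if address.kind == "residue":
        if not (1 <= address.residue <= topology.length):
            raise AnnotationError(
                f"residue {address.residue} outside chain of length {topology.length}"
            )
        return {address.residue}, None
    if address.kind == "helix":
        try:
            e = topology.helix(address.domain, address.helix)
        except KeyError:
            raise AnnotationError(f"cannot resolve address {address.raw!r}") from None
        return set(range(e.range.start, e.range.end + 1)), e
    if address.kind == "interdomain":
        loops = topology.of_kind("long_loop")
        match = [e for e in loops if e.interdomain_index == address.interdomain]
        if not match:
            raise AnnotationError(
                f"cannot resolve address {address.raw!r}: model has "
                f"{len(loops)} interdomain loops"
            )
        e = match[0]
        return set(range(e.range.start, e.range.end + 1)), e
    kind = address.kind  # n_term / c_term
    match = topology.of_kind(kind)
    if not match:
        raise AnnotationError(f"model has no {kind} element")
    e = match[0]
    return set(range(e.range.start, e.range.end + 1)), e


# --------------------------------------------------------------------------
# Color rules

_RANGE_ITEM = re.compile(r"^(\d+)(?:-(\d+))?$")


@dataclass(frozen=True)
class ColorRule:
    selector: str  # "ALL", an element address, or a residue list
    mode: str  # flat|gradient
    colors: tuple[str, ...]
    property: str | None = None
    range: tuple[float, float] | str = "min;max"


def parse_color_rule(rule: str) -> ColorRule:
    """Parse a one-line color rule.

    ``selector, color`` paints a flat color; ``selector, by:NAME, c0;c1,
    range`` paints a property gradient, where range is ``min;max`` (observed
    extremes) or two explicit numbers.
    """
    if not rule or not rule.strip():
        raise AnnotationError("empty color rule")
    fields = [f.strip() for f in rule.split(",")]
    if len(fields) < 2:
        raise AnnotationError(f"color rule needs at least selector and color: {rule!r}")
    selector = fields[0]
    if fields[1].lower().startswith("by:"):
        prop = fields[1][3:].strip()
        if not prop:
            raise AnnotationError(f"gradient rule without property name: {rule!r}")
        if len(fields) < 3:
            raise AnnotationError(f"gradient rule needs two colors: {rule!r}")
        colors = tuple(normalize_color(c) for c in fields[2].split(";"))
        if len(colors) != 2:
            raise AnnotationError(
                f"gradient rule needs exactly two ';'-separated colors: {rule!r}"
            )
        rng: tuple[float, float] | str = "min;max"
        if len(fields) >= 4 and fields[3]:
            if fields[3].replace(" ", "").lower() == "min;max":
                rng = "min;max"
            else:
                parts = fields[3].split(";")
                if len(parts) != 2:
                    raise AnnotationError(f"bad gradient range {fields[3]!r}")
                try:
                    rng = (float(parts[0]), float(parts[1]))
                except ValueError as exc:
                    raise AnnotationError(f"bad gradient range {fields[3]!r}") from exc
        return ColorRule(selector=selector, mode="gradient", colors=colors,
                         property=prop, range=rng)
    return ColorRule(selector=selector, mode="flat",
                     colors=(normalize_color(fields[1]),))


def _selector_residues(selector: str, topology: TopologyModel) -> set[int]:
    if selector.upper() == "ALL":
        return set(range(1, topology.length + 1))
    # residue list extension: ";"-separated integers and a-b ranges
    items = [s.strip() for s in selector.split(";") if s.strip()]
    if items and all(_RANGE_ITEM.match(s) for s in items):
        out: set[int] = set()
        for s in items:
            m = _RANGE_ITEM.match(s)
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            out.update(range(lo, hi + 1))
        return out
    residues, _ = resolve_address(selector, topology)
    return residues


def build_fill_map(
    rules: list[ColorRule],
    props: PropertyTable | None,
    topology: TopologyModel,
) -> dict[int, str]:
    """Apply color rules in order; later rules override on overlapping residues."""
    fills: dict[int, str] = {}
    for rule in rules:
        selected = _selector_residues(rule.selector, topology)
        if rule.mode == "flat":
            for r in selected:
                fills[r] = rule.colors[0]
            continue
        if props is None or rule.property not in props.names:
            raise AnnotationError(f"gradient rule needs property {rule.property!r}")
        column = props.column(rule.property)
        values = {r: column[r] for r in selected if r in column}
        if not values:
            continue
        if rule.range == "min;max":
            lo, hi = min(values.values()), max(values.values())
        else:
            lo, hi = rule.range
        if hi == lo:
            warnings.warn(
                f"gradient range degenerate (all values {lo}); using first color",
                stacklevel=2,
            )
            for r in values:
                fills[r] = rule.colors[0]
            continue
        for r, v in values.items():
            t = min(1.0, max(0.0, (v - lo) / (hi - lo)))
            fills[r] = interpolate_color(rule.colors[0], rule.colors[1], t)
    return fills


# --------------------------------------------------------------------------
# Edges

@dataclass(frozen=True)
class EdgeGeometry:
    path: tuple[Point, ...]  # control points of a single-bend curve
    width: float
    color: str
    type: str


def element_anchor(
    e: TopologyElement, topology: TopologyModel, layout_result
) -> Point:
    """Canvas anchor of an element: helix centre, or loop polyline midpoint."""
    if e.kind == "helix":
        for g in layout_result.helix_geometries:
            if (g["domain_index"], g["helix_index"]) == (e.domain_index, e.helix_index):
                return Point(g["x"] + g["width"] / 2.0, (g["top"] + g["bottom"]) / 2.0)
        raise AnnotationError(f"helix D{e.domain_index} S{e.helix_index} not placed")
    idx = topology.elements.index(e)
    pl = layout_result.loop_polylines[idx]
    arr = pl.as_array()
    seg = np.linalg.norm(np.diff(arr, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    half = cum[-1] / 2.0
    x = float(np.interp(half, cum, arr[:, 0]))
    y = float(np.interp(half, cum, arr[:, 1]))
    return Point(x, y)


def _endpoint(
    address: ElementAddress, topology: TopologyModel, layout_result
) -> Point:
    residues, element = resolve_address(address, topology)
    if element is None:
        (r,) = residues
        return layout_result.residue_coordinates[r]
    return element_anchor(element, topology, layout_result)


def edge_geometry(
    rel: Relationship,
    topology: TopologyModel,
    layout_result,
    style,
    weight_stats: tuple[float, float],
) -> EdgeGeometry:
    """Single-bend curve between two endpoints, width affine in the weight.

    The midpoint stroke width maps the weight linearly onto the style's
    [min_width, max_width]; a degenerate weight range yields the midrange.
    """
    p0 = _endpoint(rel.source, topology, layout_result)
    p1 = _endpoint(rel.target, topology, layout_result)
    edges = style["edges"]
    w_min, w_max = edges["min_width"], edges["max_width"]
    lo, hi = weight_stats
    if hi == lo:
        width = (w_min + w_max) / 2.0
    else:
        t = (rel.raw_weight - lo) / (hi - lo)
        width = w_min + (w_max - w_min) * min(1.0, max(0.0, t))
    mid = Point((p0.x + p1.x) / 2.0, (p0.y + p1.y) / 2.0)
    dx, dy = p1.x - p0.x, p1.y - p0.y
    norm = (dx * dx + dy * dy) ** 0.5 or 1.0
    sag = edges["sag"]
    ctrl = Point(mid.x - dy / norm * sag, mid.y + dx / norm * sag)
    color = edges["type_colors"].get(rel.type, edges["color"])
    return EdgeGeometry(path=(p0, ctrl, p1), width=width,
                        color=normalize_color(color), type=rel.type)


# --------------------------------------------------------------------------
# Text annotations

@dataclass(frozen=True)
class TextAnnotation:
    text: str
    mode: str = "absolute"  # absolute|relative
    x: float | None = None
    y: float | None = None
    target: str | None = None
    dx: float = 0.0
    dy: float = 0.0
    font_size: float | None = None
    font_family: str | None = None
    color: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("absolute", "relative"):
            raise AnnotationError(f"text mode must be absolute|relative, got {self.mode!r}")
        if self.mode == "absolute" and (self.x is None or self.y is None):
            raise AnnotationError("absolute text annotation needs x and y")
        if self.mode == "relative" and not self.target:
            raise AnnotationError("relative text annotation needs a target address")


def place_text(
    annotation: TextAnnotation,
    topology: TopologyModel,
    layout_result,
    style,
) -> dict:
    """Resolve an annotation to a positioned text record for the renderer."""
    if annotation.mode == "absolute":
        pos = Point(annotation.x + annotation.dx, annotation.y + annotation.dy)
    else:
        anchor = _endpoint(
            ElementAddress.parse(annotation.target), topology, layout_result
        )
        pos = Point(anchor.x + annotation.dx, anchor.y + annotation.dy)
    text_style = style["text"]
    return {
        "text": annotation.text,
        "x": pos.x,
        "y": pos.y,
        "font_size": annotation.font_size or text_style["font_size"],
        "font_family": annotation.font_family or text_style["font_family"],
        "color": normalize_color(annotation.color or text_style["color"]),
    }
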