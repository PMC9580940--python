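"""The style configuration: defaults, validation, deep merge, JSON round trip.

A :class:`StyleConfig` is a validated nested document controlling every
drawing aspect — canvas size, membrane depiction, helix draw type and gaps,
per-loop-class curve families and scaling, edge widths and colors, text
defaults.  A partial JSON document can be merged over the defaults; unknown
keys and type violations are rejected with the offending dotted path.
"""

from __future__ import annotations

import copy
import json
from typing import Any

from .curves import CurveParams, LoopScaleSpec

__all__ = ["StyleConfig", "StyleError", "default_style", "merge", "load_style", "save_style"]


class StyleError(ValueError):
    """Invalid style document (unknown key, bad type, out-of-range value)."""


# --- schema -----------------------------------------------------------------
# Leaves: (type(s), validator) — validator may be None, an allowed-value
# tuple, or a callable.  "map" nodes accept arbitrary string keys.

def _frac(v: float) -> bool:
    return 0.0 <= v <= 1.0


def _pos(v: float) -> bool:
    return v > 0


def _nonneg(v: float) -> bool:
    return v >= 0


_NUM = (int, float)

_CURVE_PARAM_SCHEMA = {
    "delta_y": (_NUM, _pos),
    "p_y": (_NUM, lambda v: 0 < v <= 1),
    "delta_x": (_NUM, _nonneg),
    "delta_cx": (_NUM, _nonneg),
    "p_y2": (_NUM, lambda v: 0 < v < 1),
}

_SCALE_SCHEMA = {
    "mode": (str, ("fixed", "scaled", "reslen", "custom")),
    "fixed_height": (_NUM, _pos),
    "scale_law": (str, ("linear", "power", "log")),
    "power_exponent": (_NUM, _pos),
    "max_height": (_NUM, _pos),
    "px_per_residue": (_NUM, _pos),
    "custom_heights": "map",
}


def _loop_class_schema(curves: tuple[str, ...]) -> dict:
    return {
        "curve": (str, curves),
        "params": dict(_CURVE_PARAM_SCHEMA),
        "scale": dict(_SCALE_SCHEMA),
        "stroke": (str, None),
        "stroke_width": (_NUM, _pos),
    }


_PAIR_CURVES = ("simple", "bulb", "swirl", "mushroom")

SCHEMA: dict[str, Any] = {
    "canvas": {
        "width": (_NUM, _pos),
        "height": (_NUM, _pos),
        "border": (_NUM, _nonneg),
    },
    "membrane": {
        "draw_type": (str, ("box", "bilayer")),
        "fill": (str, None),
        "opacity": (_NUM, _frac),
        "band_fraction": (_NUM, lambda v: 0 < v < 1),
        "thickness": (_NUM, _pos),
        "head_radius": (_NUM, _pos),
        "head_fill": (str, None),
        "tail_stroke": (str, None),
    },
    "helices": {
        "draw_type": (str, ("box", "cylinder", "cartoon")),
        "width": (_NUM, _pos),
        "fill": (str, None),
        "stroke": (str, None),
        "intra_gap": (_NUM, _pos),
        "inter_gap": (_NUM, _pos),
        "overrides": "list",  # [{domain_index?, helix_index?, fill}]
    },
    "loops": {
        "short": _loop_class_schema(("simple", "swirl", "bulb", "mushroom")),
        "pore": {
            "depth_fraction": (_NUM, lambda v: 0 < v <= 1),
            "arch_fraction": (_NUM, _frac),
            "scale": dict(_SCALE_SCHEMA),
            "stroke": (str, None),
            "stroke_width": (_NUM, _pos),
        },
        "long": _loop_class_schema(_PAIR_CURVES),
        "terminal": {
            "params": dict(_CURVE_PARAM_SCHEMA),
            "scale": dict(_SCALE_SCHEMA),
            "stroke": (str, None),
            "stroke_width": (_NUM, _pos),
        },
    },
    "edges": {
        "min_width": (_NUM, _pos),
        "max_width": (_NUM, _pos),
        "color": (str, None),
        "type_colors": "map",
        "sag": (_NUM, _nonneg),
        "opacity": (_NUM, _frac),
    },
    "text": {
        "font_family": (str, None),
        "font_size": (_NUM, _pos),
        "color": (str, None),
    },
    "residue_markers": {
        "mode": (str, ("stroke", "circle")),
        "radius": (_NUM, _pos),
    },
}

_DEFAULTS: dict[str, Any] = {
    "canvas": {"width": 1400, "height": 760, "border": 40},
    "membrane": {
        "draw_type": "bilayer",
        "fill": "#d9d9d9",
        "opacity": 0.6,
        "band_fraction": 0.5,
        "thickness": 90,
        "head_radius": 6,
        "head_fill": "#c8b89a",
        "tail_stroke": "#b0a080",
    },
    "helices": {
        "draw_type": "cylinder",
        "width": 26,
        "fill": "#c0392b",
        "stroke": "#2c2c2c",
        "intra_gap": 12,
        "inter_gap": 30,  # 2.5x the intra-domain gap
        "overrides": [{"helix_index": 4, "fill": "#2e6fbd"}],
    },
    "loops": {
        "short": {
            "curve": "simple",
            "params": {"delta_y": 40, "p_y": 0.5, "delta_x": 10, "delta_cx": 0.5, "p_y2": 0.25},
            "scale": {
                "mode": "scaled", "fixed_height": 40, "scale_law": "linear",
                "power_exponent": 0.5, "max_height": 70, "px_per_residue": 2.0,
                "custom_heights": {},
            },
            "stroke": "#2c2c2c",
            "stroke_width": 2.5,
        },
        "pore": {
            "depth_fraction": 0.6,
            "arch_fraction": 0.2,
            "scale": {
                "mode": "fixed", "fixed_height": 54, "scale_law": "linear",
                "power_exponent": 0.5, "max_height": 80, "px_per_residue": 2.0,
                "custom_heights": {},
            },
            "stroke": "#2c2c2c",
            "stroke_width": 2.5,
        },
        "long": {
            "curve": "bulb",
            "params": {"delta_y": 130, "p_y": 0.6, "delta_x": 14, "delta_cx": 0.5, "p_y2": 0.25},
            "scale": {
                "mode": "scaled", "fixed_height": 120, "scale_law": "log",
                "power_exponent": 0.5, "max_height": 190, "px_per_residue": 2.0,
                "custom_heights": {},
            },
            "stroke": "#2c2c2c",
            "stroke_width": 2.5,
        },
        "terminal": {
            "params": {"delta_y": 110, "p_y": 0.5, "delta_x": 70, "delta_cx": 0.5, "p_y2": 0.25},
            "scale": {
                "mode": "fixed", "fixed_height": 110, "scale_law": "linear",
                "power_exponent": 0.5, "max_height": 160, "px_per_residue": 2.0,
                "custom_heights": {},
            },
            "stroke": "#2c2c2c",
            "stroke_width": 2.5,
        },
    },
    "edges": {
        "min_width": 1.0,
        "max_width": 9.0,
        "color": "#800080",
        "type_colors": {},
        "sag": 40,
        "opacity": 0.8,
    },
    "text": {"font_family": "Helvetica, Arial, sans-serif", "font_size": 16, "color": "#1a1a1a"},
    "residue_markers": {"mode": "stroke", "radius": 2.5},
}


def _validate(doc: Any, schema: Any, path: str) -> None:
    if schema == "map":
        if not isinstance(doc, dict):
            raise StyleError(f"{path}: expected a mapping, got {type(doc).__name__}")
        return
    if schema == "list":
        if not isinstance(doc, list):
            raise StyleError(f"{path}: expected a list, got {type(doc).__name__}")
        return
    if isinstance(schema, dict):
        if not isinstance(doc, dict):
            raise StyleError(f"{path}: expected a mapping, got {type(doc).__name__}")
        for key, value in doc.items():
            if key not in schema:
                raise StyleError(f"unknown style key: {path}.{key}" if path else
                                 f"unknown style key: {key}")
            _validate(value, schema[key], f"{path}.{key}" if path else key)
        return
    types, check = schema
    if isinstance(doc, bool) or not isinstance(doc, types):
        want = types[0].__name__ if isinstance(types, tuple) else types.__name__
        raise StyleError(f"{path}: expected {want}, got {type(doc).__name__} ({doc!r})")
    if check is not None:
        if isinstance(check, tuple):
            if doc not in check:
                raise StyleError(f"{path}: {doc!r} not one of {check}")
        elif not check(doc):
            raise StyleError(f"{path}: value {doc!r} out of range")


def _deep_merge(base: dict, patch: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in patch.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


class StyleConfig:
    """Validated drawing configuration.  Access sections with ``style['canvas']``
    or dotted paths with ``style.get('helices.width')``."""

    def __init__(self, document: dict):
        _validate(document, SCHEMA, "")
        if document["edges"]["max_width"] < document["edges"]["min_width"]:
            raise StyleError("edges.max_width must be >= edges.min_width")
        self._doc = copy.deepcopy(document)

    def __getitem__(self, key: str) -> Any:
        return copy.deepcopy(self._doc[key])

    def get(self, dotted: str) -> Any:
        node: Any = self._doc
        for part in dotted.split("."):
            node = node[part]
        return copy.deepcopy(node)

    def to_dict(self) -> dict:
        return copy.deepcopy(self._doc)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, StyleConfig) and self._doc == other._doc

    # -- typed views consumed by the geometry engines ----------------------
    def curve_params(self, loop_class: str) -> CurveParams:
        node = self._doc["loops"][loop_class]
        p = node.get("params", {})
        curve = node.get("curve", "n_curve" if loop_class == "terminal" else "simple")
        return CurveParams(
            curve_type=curve,
            delta_y=float(p.get("delta_y", 60.0)),
            p_y=float(p.get("p_y", 0.5)),
            delta_x=float(p.get("delta_x", 12.0)),
            delta_cx=float(p.get("delta_cx", 0.5)),
            p_y2=float(p.get("p_y2", 0.25)),
        )

    def scale_spec(self, loop_class: str) -> LoopScaleSpec:
        s = self._doc["loops"][loop_class]["scale"]
        return LoopScaleSpec(
            mode=s["mode"],
            fixed_height=float(s["fixed_height"]),
            scale_law=s["scale_law"],
            power_exponent=float(s["power_exponent"]),
            max_height=float(s["max_height"]),
            px_per_residue=float(s["px_per_residue"]),
            custom_heights=dict(s["custom_heights"]),
        )

    def helix_fill(self, domain_index: int, helix_index: int) -> str:
        fill = self._doc["helices"]["fill"]
        for ov in self._doc["helices"]["overrides"]:
            if "helix_index" in ov and ov["helix_index"] != helix_index:
                continue
            if "domain_index" in ov and ov["domain_index"] != domain_index:
                continue
            if "fill" in ov:
                fill = ov["fill"]
        return fill


def default_style() -> StyleConfig:
    """A complete configuration able to render any valid topology model."""
    return StyleConfig(copy.deepcopy(_DEFAULTS))


def merge(base: StyleConfig, patch: dict) -> StyleConfig:
    """Deep-merge a partial style document over ``base``; the result validates."""
    _validate(patch, SCHEMA, "")
    return StyleConfig(_deep_merge(base.to_dict(), patch))


def load_style(text: str) -> StyleConfig:
    """Parse a (possibly partial) JSON style document; omitted keys default."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise StyleError(f"malformed style JSON at line {exc.lineno} col {exc.colno}: "
                         f"{exc.msg}") from exc
    if not isinstance(doc, dict):
        raise StyleError("style document must be a JSON object")
    return merge(default_style(), doc)


def save_style(style: StyleConfig) -> str:
    """Serialize to JSON; ``load_style(save_style(s)) == s``."""
    return json.dumps(style.to_dict(), indent=2, sort_keys=True)
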