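"""Property/relationship tables, addresses, color rules, edges and text."""

import json

import pytest

from navdiagram import (
    TextAnnotation,
    build_fill_map,
    default_style,
    edge_geometry,
    interpolate_color,
    load_properties,
    load_relationships,
    parse_color_rule,
    place_text,
    resolve_address,
)
from navdiagram.annotations import AnnotationError, ElementAddress

TABLE1_CSV = """Resid,Property
1,0.2871809547
2,0.9835970474
3,0.3891381106
4,0.2391246386
"""


class TestPropertyTable:
    def test_csv_values_parsed_as_floats(self):
        table = load_properties(TABLE1_CSV)
        assert table.names == ["Property"]
        assert table.values[1]["Property"] == pytest.approx(0.2871809547)
        assert table.values[2]["Property"] == pytest.approx(0.9835970474)

    def test_csv_json_dialect_equivalence(self):
        csv_doc = "Resid,Conservation\n1,0.1\n2,0.3\n3,0.5\n"
        json_doc = json.dumps(
            {"1": {"Conservation": 0.1}, "2": {"Conservation": 0.3}, "3": {"Conservation": 0.5}}
        )
        assert load_properties(csv_doc) == load_properties(json_doc)

    def test_wrong_header_rejected(self):
        with pytest.raises(AnnotationError, match="Resid"):
            load_properties("Residue,Property\n1,0.5\n")

    def test_non_numeric_cell_located(self):
        with pytest.raises(AnnotationError, match="row 3.*Property"):
            load_properties("Resid,Property\n1,0.5\n2,high\n")


TABLE2_ROWS = """source,target,raw_weight,type
776,660,0.6944505517,Resids
DomainII; Helix4,DomainIV; Helix4,0.9300459795,Elements
InterDomain1; Loop,305,0.1476849439,Elements
"""


class TestRelationships:
    def test_csv_rows(self):
        rels = load_relationships(TABLE2_ROWS)
        assert len(rels) == 3
        assert rels[0].source.kind == "residue" and rels[0].source.residue == 776
        assert rels[0].raw_weight == pytest.approx(0.6944505517)
        assert rels[1].source.kind == "helix"
        assert (rels[1].source.domain, rels[1].source.helix) == (2, 4)
        assert rels[2].source.kind == "interdomain"

    def test_json_list_dialect_equivalent(self):
        doc = json.dumps([
            {"source": "776", "target": "660", "raw_weight": 0.6944505517, "type": "Resids"},
            {"source": "DomainII; Helix4", "target": "DomainIV; Helix4",
             "raw_weight": 0.9300459795, "type": "Elements"},
            {"source": "InterDomain1; Loop", "target": "305",
             "raw_weight": 0.1476849439, "type": "Elements"},
        ])
        assert load_relationships(doc) == load_relationships(TABLE2_ROWS)

    def test_missing_column_and_bad_weight(self):
        with pytest.raises(AnnotationError, match="missing columns"):
            load_relationships("source,target,type\n1,2,Resids\n")
        with pytest.raises(AnnotationError, match="raw_weight"):
            load_relationships("source,target,raw_weight,type\n1,2,high,Resids\n")

    def test_thousands_separator_in_residue(self):
        rels = load_relationships('source,target,raw_weight,type\n"1,308",318,0.49,Resids\n')
        assert rels[0].source.residue == 1308


class TestAddresses:
    def test_domain_helix_resolution(self, canonical_topology):
        residues, element = resolve_address("DomainI;Helix6", canonical_topology)
        assert element.kind == "helix"
        assert (element.domain_index, element.helix_index) == (1, 6)
        assert residues == set(range(element.range.start, element.range.end + 1))

    def test_interdomain_with_whitespace(self, canonical_topology):
        _, element = resolve_address("InterDomain1; Loop", canonical_topology)
        assert element.kind == "long_loop" and element.interdomain_index == 1

    def test_termini(self, canonical_topology):
        assert resolve_address("NTerm", canonical_topology)[1].kind == "n_term"
        assert resolve_address("CTerm", canonical_topology)[1].kind == "c_term"

    def test_roman_numerals(self):
        assert ElementAddress.parse("DomainIV;Helix2").domain == 4
        assert ElementAddress.parse("DomainIX;Helix1").domain == 9

    @pytest.mark.parametrize("addr", ["DomainV;Helix1", "InterDomain5; Loop"])
    def test_out_of_range_named_in_error(self, canonical_topology, addr):
        with pytest.raises(AnnotationError, match="resolve"):
            resolve_address(addr, canonical_topology)

    def test_malformed_grammar(self):
        with pytest.raises(AnnotationError, match="unparseable"):
            ElementAddress.parse("Helix4;DomainI")


class TestColorRules:
    def test_gradient_rule_from_figure(self):
        rule = parse_color_rule("ALL, by:Conservation,#ADD8E6;#0000FF, min;max")
        assert rule.selector == "ALL"
        assert rule.mode == "gradient"
        assert rule.property == "Conservation"
        assert rule.colors == ("#add8e6", "#0000ff")
        assert rule.range == "min;max"

    def test_flat_named_color_on_element(self):
        rule = parse_color_rule("DomainI;Helix4, blue")
        assert rule.mode == "flat"
        assert rule.colors == ("#0000ff",)

    def test_gradient_with_one_color_rejected(self):
        with pytest.raises(AnnotationError, match="two"):
            parse_color_rule("ALL, by:Conservation,#ADD8E6, min;max")

    def test_bad_hex_rejected(self):
        with pytest.raises(AnnotationError, match="color"):
            parse_color_rule("ALL, #GGHHII")

    def test_explicit_numeric_range(self):
        rule = parse_color_rule("ALL, by:Score,#000000;#ffffff, 0;10")
        assert rule.range == (0.0, 10.0)


class TestInterpolateColor:
    def test_endpoints_byte_exact(self):
        assert interpolate_color("#ADD8E6", "#0000FF", 0.0) == "#add8e6"
        assert interpolate_color("#ADD8E6", "#0000FF", 1.0) == "#0000ff"

    def test_midpoint_rounds_half_away_from_zero(self):
        # channels: (173+0)/2=86.5 -> 87, (216+0)/2=108, (230+255)/2=242.5 -> 243
        assert interpolate_color("#ADD8E6", "#0000FF", 0.5) == "#576cf3"

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert interpolate_color("#000000", "#ffffff", 1.5) == "#ffffff"


class TestFillMap:
    def test_gradient_endpoints_on_data_extremes(self, canonical_topology):
        props = load_properties("Resid,Conservation\n1,0\n2,1\n")
        rules = [parse_color_rule("ALL, by:Conservation,#ADD8E6;#0000FF, min;max")]
        fills = build_fill_map(rules, props, canonical_topology)
        assert fills[1] == "#add8e6"
        assert fills[2] == "#0000ff"
        assert 3 not in fills  # residues without a value keep no fill

    def test_later_rule_overrides(self, canonical_topology):
        props = load_properties("Resid,Conservation\n1,0\n2,1\n")
        rules = [
            parse_color_rule("ALL, by:Conservation,#ADD8E6;#0000FF, min;max"),
            parse_color_rule("1, red"),
        ]
        fills = build_fill_map(rules, props, canonical_topology)
        assert fills[1] == "#ff0000"
        assert fills[2] == "#0000ff"

    def test_degenerate_range_warns_and_uses_first_color(self, canonical_topology):
        props = load_properties("Resid,Conservation\n1,0.5\n2,0.5\n")
        rules = [parse_color_rule("ALL, by:Conservation,#ADD8E6;#0000FF, min;max")]
        with pytest.warns(UserWarning, match="degenerate"):
            fills = build_fill_map(rules, props, canonical_topology)
        assert set(fills.values()) == {"#add8e6"}

    def test_residue_list_selector(self, canonical_topology):
        fills = build_fill_map([parse_color_rule("1;3-5, green")], None, canonical_topology)
        assert set(fills) == {1, 3, 4, 5}

    def test_unknown_property_named(self, canonical_topology):
        props = load_properties("Resid,Conservation\n1,0.5\n")
        with pytest.raises(AnnotationError, match="Phospho"):
            build_fill_map([parse_color_rule("ALL, by:Phospho,#000000;#ffffff")],
                           props, canonical_topology)


class TestEdges:
    def test_width_affine_in_weight(self, canonical_topology, canonical_layout):
        rels = load_relationships(
            "source,target,raw_weight,type\n10,20,0.2,Resids\n30,40,0.6,Resids\n50,60,1.0,Resids\n"
        )
        sty = default_style()  # min 1, max 9
        stats = (0.2, 1.0)
        widths = [edge_geometry(r, canonical_topology, canonical_layout, sty, stats).width
                  for r in rels]
        assert widths == pytest.approx([1.0, 5.0, 9.0])

    def test_single_edge_gets_midrange(self, canonical_topology, canonical_layout):
        rel = load_relationships("source,target,raw_weight,type\n10,20,0.7,Resids\n")[0]
        e = edge_geometry(rel, canonical_topology, canonical_layout, default_style(), (0.7, 0.7))
        assert e.width == pytest.approx(5.0)

    def test_per_type_color(self, canonical_topology, canonical_layout):
        from navdiagram import merge
        sty = merge(default_style(), {"edges": {"type_colors": {"Elements": "purple"}}})
        rel = load_relationships(
            "source,target,raw_weight,type\nDomainI; Helix4,DomainII; Helix4,0.5,Elements\n"
        )[0]
        e = edge_geometry(rel, canonical_topology, canonical_layout, sty, (0.0, 1.0))
        assert e.color == "#800080"

    def test_endpoints_at_resolved_coordinates(self, canonical_topology, canonical_layout):
        rel = load_relationships("source,target,raw_weight,type\n10,20,0.5,Resids\n")[0]
        e = edge_geometry(rel, canonical_topology, canonical_layout, default_style(), (0, 1))
        assert e.path[0] == canonical_layout.residue_coordinates[10]
        assert e.path[-1] == canonical_layout.residue_coordinates[20]


class TestText:
    def test_absolute_with_offsets(self, canonical_topology, canonical_layout):
        t = TextAnnotation(text="D-I", mode="absolute", x=100, y=50, dx=5, dy=-5)
        rec = place_text(t, canonical_topology, canonical_layout, default_style())
        assert (rec["x"], rec["y"]) == (105, 45)

    def test_relative_to_helix_anchor(self, canonical_topology, canonical_layout):
        t = TextAnnotation(text="S4", mode="relative", target="DomainI;Helix4", dy=-20)
        rec = place_text(t, canonical_topology, canonical_layout, default_style())
        for g in canonical_layout.helix_geometries:
            if (g["domain_index"], g["helix_index"]) == (1, 4):
                assert rec["x"] == pytest.approx(g["x"] + g["width"] / 2)
                assert rec["y"] == pytest.approx((g["top"] + g["bottom"]) / 2 - 20)

    def test_relative_to_interdomain_loop_midpoint(self, canonical_topology, canonical_layout):
        t = TextAnnotation(text="ID-LOOP", mode="relative", target="InterDomain1; Loop", dy=30)
        rec = place_text(t, canonical_topology, canonical_layout, default_style())
        idx = next(i for i, e in enumerate(canonical_topology.elements)
                   if e.kind == "long_loop" and e.interdomain_index == 1)
        pl = canonical_layout.loop_polylines[idx]
        xs = [p.x for p in pl.points]
        assert min(xs) <= rec["x"] <= max(xs)
        assert rec["y"] > canonical_layout.regions.membrane_bottom  # intracellular

    def test_validation(self):
        with pytest.raises(AnnotationError, match="x and y"):
            TextAnnotation(text="x", mode="absolute")
        with pytest.raises(AnnotationError, match="target"):
            TextAnnotation(text="x", mode="relative")
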