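# navdiagram

Annotated 2D membrane-topology diagrams of voltage-gated sodium channel
(Nav) alpha subunits, rendered as SVG from UniProt-format flat text.

Nav alpha subunits are single chains of ~1,500–2,000 residues with a
distinctive architecture: four homologous domains (D1–D4), each built from
six transmembrane helices (S1–S6), with a reentrant pore loop between S5 and
S6 that dips into the membrane without crossing it, short loops between the
other helices, long intracellular loops between domains, and free N/C
termini.  Diagrams of this architecture are a fixture of the ion-channel
literature — they are how the field communicates voltage-sensor positions,
selectivity-filter residues, glycosylation and phosphorylation sites, toxin
binding sites and disease mutations.  `navdiagram` generates them
programmatically, so experimental data can be mapped straight onto the
figure: per-residue color gradients, weight-scaled edges between residues or
elements, and positioned text.

## How it works

1. **Parse & classify** — the UniProt feature table (`FT TRANSMEM`,
   `TOPO_DOM`, `INTRAMEM` lines) is parsed and classified into an ordered
   element model that tiles the chain: helices verbatim from TRANSMEM,
   every inter-helix gap a loop, with loop classes (short / pore / long /
   terminal) assigned from domain structure and membrane sidedness from
   TOPO_DOM annotations or canonical alternation.
2. **Lay out** — the canvas is partitioned into a membrane band and helix
   slots; helices are placed with anchor points on both band faces; each
   loop is drawn as a natural cubic spline (zero second derivative at the
   ends, uniform parameterization) through a family-specific control-point
   set — *simple*, *bulb*, *swirl* and *mushroom* shapes governed by the
   parameters Δy, p_Y, Δx, Δcx, p_Y2; pore loops as a reentrant hairpin;
   termini as open S-tails.  Loop heights come from one of four scaling
   modes: fixed, scaled by residue count (linear/power/log), residue-length
   (arc length = px·residues, solved by bisection), or custom per loop.
3. **Annotate & render** — every residue gets one canvas coordinate, so
   property tables (CSV/JSON), relationship tables, one-line color rules
   such as `"ALL, by:Conservation,#ADD8E6;#0000FF, min;max"` and text
   annotations resolve to concrete geometry; the result is deterministic
   SVG with one stable-id fragment per element (`helix_D1_S4`, `ploop_D2`,
   `idloop_1`, ...).

## Worked example

```python
from navdiagram import (FixtureSpec, make_record, parse_flat_text, classify,
                        default_style, layout, arc_length, render_svg)

text, _ = make_record(FixtureSpec(seed=42))   # synthetic canonical record
topo = classify(parse_flat_text(text))
print(f"chain length : {topo.length} residues")
print(f"domains      : {topo.n_domains}")
print(f"helices      : {len(topo.helices())}")
print(f"pore loops   : {len(topo.of_kind('pore_loop'))}")
print(f"long loops   : {len(topo.of_kind('long_loop'))}")

style = default_style()
result = layout(topo, style)
idx = next(i for i, e in enumerate(topo.elements)
           if e.kind == "long_loop" and e.interdomain_index == 1)
loop = topo.elements[idx]
print(f"ID-loop 1    : {loop.n_residues} residues, "
      f"curve length {arc_length(result.loop_polylines[idx]):.1f} px")

doc = render_svg(result, topo, style)
open("nav.svg", "w").write(doc.xml)
print(f"svg fragments: {len(doc.index)} (helix_D1_S4 in doc: {'helix_D1_S4' in doc})")
```

prints

```
chain length : 1806 residues
domains      : 4
helices      : 24
pore loops   : 4
long loops   : 3
ID-loop 1    : 242 residues, curve length 407.9 px
svg fragments: 50 (helix_D1_S4 in doc: True)
```

The classifier recovered the canonical 4×6 architecture from the flat text
alone; the first inter-domain loop (242 residues, the largest intracellular
loop) was drawn as a bulb curve whose height the log scaling law set from
its residue count; the SVG contains one addressable fragment per topology
element plus membrane and annotation groups.

The same pipeline is available from a shell:

```sh
navdiagram fixture --seed 42 --out-prefix toy
navdiagram render --record toy.txt --properties toy_props.csv \
    --relationships toy_rels.csv \
    --color-rule "ALL, by:Conservation,#ADD8E6;#0000FF, min;max" \
    --out nav.svg
```

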