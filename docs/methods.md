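# Methods

## The element model

A record is reduced to an ordered list of elements that tile the chain
`[1, L]` with no gaps or overlaps: helices (taken verbatim from TRANSMEM
features) alternating with loops.  Loop classes are assigned structurally:

- the region before the first helix is the **N-terminal loop**, after the
  last the **C-terminal loop**;
- inside a domain, the gap between helices 5 and 6 is the **pore loop**
  (an overlapping INTRAMEM feature, or any feature note mentioning the
  pore, takes precedence over position — real records vary in annotation
  richness);
- other intra-domain gaps are **short loops**; gaps between domains are
  **long loops**, numbered in sequence order.

Domain grouping: when the helix count is a multiple of six, domains are
consecutive runs of six (the canonical Nav reading).  Otherwise the chain is
split at every inter-helix loop longer than a configurable threshold
(default 50 residues); the threshold exists because no rule for
non-canonical helix counts is standard, and 50 residues separates typical
short/pore loops (≤ 45) from inter-domain linkers (≥ 80) by a comfortable
margin.

Membrane sidedness comes from TOPO_DOM features when present (the note's
"Cytoplasmic"/"Extracellular" keyword); otherwise sides alternate along the
chain starting from an intracellular N-terminus, which is the canonical Nav
topology and our convention for unannotated records.  Annotating the same
loop on both faces is a fatal inconsistency.

## Curves

Every loop is a natural cubic spline — zero second derivative at both ends —
through a small control set, interpolated with uniform (index)
parameterization.  Uniform rather than chord-length parameterization was a
deliberate choice: it reproduces the behaviour of the common web
interpolators these diagrams are drawn with, and makes control-point
geometry the single source of curve shape.  Sample density is
`max(64, 8·n_controls)` points per loop.

Control-point families, with anchors `a1`, `a2` on one membrane face,
`cx` their midpoint, and `direction` ±1 away from the membrane:

- **simple**: `[a1, (cx, a1.y + dir·Δy), a2]`.
- **bulb**: adds two flank points at height `p_Y·Δy` pushed *outward* by Δx
  (away from their closest anchor), giving the loop a belly.
- **swirl**: the bulb's flanks placed instead *toward the centroid*:
  `x = a.x + Δcx·(cx − a.x)`.  At Δcx = 1 both flanks sit under the apex;
  beyond Δcx = 2 each flank passes the far anchor and the flanks cross,
  producing the swirl.  The symmetric toward-centroid rule is our
  resolution of an ambiguous construction; it is recorded here as an
  interpretation.
- **mushroom**: the bulb plus two lower points at height `p_Y2·Δy`
  (`p_Y2 < p_Y` enforced) placed toward the centroid by Δcx, pinching the
  stalk under the cap.
- **pore**: a mirror-symmetric reentrant hairpin for the P-loop: descend
  from `a1` into the membrane band to `depth_fraction` of its thickness
  (default 0.6), turn, ascend to a small extracellular arch over the anchor
  midpoint (arch height 0.2 of the band by default), dip again, rejoin
  `a2`.  The shape is our construction; the mirror symmetry follows from
  the symmetric-anchor requirement.
- **n_curve** (termini): an open S-tail from a single anchor; the free
  terminus ends exactly Δy from the membrane face and Δx toward the chosen
  side, with an intermediate counter-bend giving the S.

Degenerate parameters are normalized: a bulb with Δx = 0 and p_Y = 1, or a
swirl with Δcx = 0 and p_Y = 1, carries no information in its flank points
and collapses to the simple three-point set, so those families reduce to
the simple curve exactly rather than to a corner-inflected variant.

## Loop scaling

Four modes set a loop's vertical extent Δy:

- **fixed** — one height per loop class (px).
- **scaled** — `Δy = max_height · f(n)/f(n_max)` with `f` linear, power
  (default exponent 0.5) or `log(n+1)`, normalized *per loop class*
  (short/long/pore separately): a 250-residue inter-domain loop should not
  flatten every short loop to invisibility.
- **reslen** — the drawn curve's total arc length equals
  `px_per_residue · n` (default 2 px/residue).  Solved by bisection on Δy
  over `[0, 20·target]`, tolerance `max(0.5 px, 1e-3·target)`, ≤ 200
  iterations; arc length is monotone in Δy for every family with the other
  parameters fixed, which the test suite asserts by property.  Only Δy is
  solved; horizontal parameters stay fixed, keeping the search
  one-dimensional and provably monotone.  A target below the family's
  flattest achievable curve (short loops of a few residues between
  well-separated helices) is unreachable; the curve engine reports it as an
  error, and the layout degrades that loop to the flattest curve with a
  warning so a whole-figure residue-length render never dies on one short
  loop.
- **custom** — explicit per-loop heights keyed by loop identifier; a
  missing key is an error, not a silent default.

## Layout

Canvas partitioning is pure arithmetic from the style: helix slots of fixed
width separated by an intra-domain gap g and a larger inter-domain gap G
(default 30 px = 2.5·g), left-aligned at the border; the membrane band is
centred at a height fraction (default 0.5) with fixed thickness.  A canvas
too narrow for the slots raises an error naming the minimum width.  The
extracellular face is at the top — SVG's y grows downward, so intracellular
loops have direction +1.

Helix crossing direction alternates along the chain from the N-terminal
face (intracellular N-terminus ⇒ S1 crosses bottom→top).  Helix residues
are evenly spaced along the helix axis *in crossing order* — residue
coordinates follow the chain, not a fixed top-down rule.  Loop residues are
evenly spaced by arc length at fractions `i/(n+1)`, so a 1-residue loop
sits at the curve's arc midpoint and residues never collide with the
flanking helix ends.  The N-terminal polyline is stored free-end-first so
all polylines run in chain order.  The layout contains no randomness:
identical inputs give bit-identical geometry and byte-identical SVG.

## Annotations

Property tables (CSV with a `Resid` first column, or residue-keyed JSON)
and relationship tables (`source,target,raw_weight,type` CSV or a JSON
list) are parsed into identical in-memory objects regardless of dialect.
Element addresses accept Roman-numeral domains (`DomainIV;Helix2`,
extensible beyond IV), `InterDomainK;Loop`, `NTerm`/`CTerm` and bare
residue numbers, with whitespace tolerated around `;` (real tables mix
both spacings).  As an extension, a color-rule selector may also be a
`;`-separated residue list with `a-b` ranges.

Color rules apply in list order, later rules overriding earlier on
overlapping residues.  Gradients interpolate per channel in 8-bit sRGB
(not linearized — the naive reading that reproduces the stated endpoint
colors exactly), rounding half away from zero; `min;max` ranges are
computed over the rule's *selected* residues only.  A degenerate range
(all values equal) paints the first color and warns.  Named colors resolve
through the CSS/SVG keyword table before hex normalization.

Edges are single-bend quadratic curves between resolved endpoints (helix
centre, loop arc-midpoint, or residue coordinate), bent perpendicular to
the chord by a style-set sag; the stroke width maps the weight affinely
onto `[min_width, max_width]` over the loaded set's weight range, midrange
when all weights are equal.  Text is positioned absolutely (`x`, `y`) or
relative to an element anchor, plus `dx`/`dy` offsets in both modes.

## Synthetic records

The fixture generator emits the study architecture: 4 domains × 6 helices
(20–26 residues each), short loops of 5–15 residues, pore loops of 25–45,
inter-domain loops of 80–300, termini of 60–150 — ranges chosen to bracket
human Nav isoforms, whose chains come out at ~1,500–2,000 residues.  It
writes a parseable flat-text record (ID/AC/SQ plus modern `start..end` FT
lines with `/note=` continuations; a flag switches to the legacy columnar
dialect) and returns the ground-truth model built directly from the
generation plan, so parser+classifier round trips are checked against an
independent construction.  The emitted records are also readable by
Biopython's SwissProt parser, which the tests use as a second, independent
parser on the TRANSMEM set.

What the generator does not emulate: non-helical TRANSMEM annotations,
missing or partial feature tables (beyond the TOPO_DOM on/off flag),
evidence tags, isoform blocks and sequence conflicts.  Passing round-trip
tests therefore demonstrate correct handling of well-formed records of
canonical and near-canonical architecture, not robustness to the full
variety of hand-curated database entries.

## Numerical and rendering choices

Coordinates are serialized at 3 decimal places with fixed attribute order,
making re-renders byte-identical.  Spline interpolation is exact at control
points to 1e-9 px.  Residue fills default to short colored chain segments
along the backbone (between midpoints toward each neighbour within the
element) with a circle fallback for isolated residues; a style switch
selects circles everywhere.  PNG export delegates to a rasterizer when one
is importable and otherwise raises an explicit capability error; SVG export
has no optional dependencies.

## Known limitations

- No collision avoidance: long-loop curves, edges and text can overlap.
- Scaled-mode normalization is per loop class; a global normalization is
  not offered.
- The reslen mode guarantees arc length, not visual height; very long
  loops between close anchors become tall and thin.
- Beta subunits and non-Nav membrane proteins are out of scope, though the
  classifier degrades gracefully to any helix count via the threshold rule.
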