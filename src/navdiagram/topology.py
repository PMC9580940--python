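"""Parse UniProt-format flat text and classify features into the Nav element model.

Voltage-gated sodium channel (Nav) alpha subunits are single chains of four
homologous domains (D1-D4), each built from six transmembrane helices (S1-S6)
with a reentrant pore loop between S5 and S6.  This module turns the UniProt
feature table of such a record (TRANSMEM / TOPO_DOM / INTRAMEM lines) into an
ordered, classified element model that tiles the whole sequence: helices,
short intra-domain loops, pore loops, long inter-domain loops and the two
termini.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ParseError",
    "ClassifyError",
    "ResidueRange",
    "Feature",
    "FeatureSet",
    "TopologyElement",
    "TopologyModel",
    "parse_flat_text",
    "classify",
]

#: FT feature kinds the classifier understands; anything else is counted and skipped.
RECOGNIZED_KINDS = ("TRANSMEM", "TOPO_DOM", "INTRAMEM", "MOD_RES", "CARBOHYD")


class ParseError(ValueError):
    """Fatal problem in the flat-text record (missing sequence, bad range...)."""


class ClassifyError(ValueError):
    """Feature set cannot be classified into a topology model."""


@dataclass(frozen=True, order=True)
class ResidueRange:
    """1-based inclusive residue interval, UniProt convention."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid residue range {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "ResidueRange") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass(frozen=True)
class Feature:
    kind: str
    range: ResidueRange
    note: str = ""


@dataclass
class FeatureSet:
    """Sequence plus the recognized features of one record, sorted by start."""

    sequence: str
    features: list[Feature]
    report: dict = field(default_factory=dict)

    def of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]


@dataclass
class TopologyElement:
    """One tile of the chain: a helix or one of the five loop classes.

    ``side`` is the membrane face the element sits on (``membrane`` for
    helices, which span the band).  Pore loops sit on the extracellular face
    and dip into the membrane without crossing it.
    """

    kind: str  # helix|short_loop|pore_loop|long_loop|n_term|c_term
    range: ResidueRange
    side: str  # extracellular|intracellular|membrane
    domain_index: int | None = None
    helix_index: int | None = None
    interdomain_index: int | None = None

    @property
    def n_residues(self) -> int:
        return len(self.range)


@dataclass
class TopologyModel:
    sequence: str
    elements: list[TopologyElement]
    n_domains: int

    @property
    def length(self) -> int:
        return len(self.sequence)

    def helices(self) -> list[TopologyElement]:
        return [e for e in self.elements if e.kind == "helix"]

    def loops(self) -> list[TopologyElement]:
        return [e for e in self.elements if e.kind != "helix"]

    def of_kind(self, kind: str) -> list[TopologyElement]:
        return [e for e in self.elements if e.kind == kind]

    def helix(self, domain_index: int, helix_index: int) -> TopologyElement:
        for e in self.elements:
            if (
                e.kind == "helix"
                and e.domain_index == domain_index
                and e.helix_index == helix_index
            ):
                return e
        raise KeyError(f"no helix S{helix_index} in domain {domain_index}")


# --------------------------------------------------------------------------
# Flat-text parsing

_FT_MODERN = re.compile(
    r"^FT\s{3}(?P<kind>[A-Z_]+)\s+(?P<start>[<?]?\d+)\.\.(?P<end>[>?]?\d+)\s*$"
)
# legacy columnar dialect: FT   TRANSMEM    127    152       Helical.
_FT_LEGACY = re.compile(
    r"^FT\s{3}(?P<kind>[A-Z_]+)\s+(?P<start>[<?]?\d+)\s+(?P<end>[>?]?\d+)(?:\s+(?P<desc>.*))?$"
)
_FT_CONT = re.compile(r"^FT\s{10,}(?P<text>\S.*)$")
_NOTE = re.compile(r'/note="?([^"]*)"?')


def _parse_pos(token: str, lineno: int, line: str) -> int:
    token = token.lstrip("<>")
    if not token.isdigit():
        raise ParseError(f"line {lineno}: malformed range token in: {line.rstrip()}")
    return int(token)


def parse_flat_text(raw: str) -> FeatureSet:
    """Parse a UniProt flat-text record into a :class:`FeatureSet`.

    Accepts the modern FT dialect (``FT   TRANSMEM        127..152`` with
    ``/note=`` continuation lines), the legacy columnar dialect, and either a
    full SQ block or bare sequence lines.  Ranges are 1-based inclusive.
    Unrecognized FT kinds are skipped silently but counted in ``report``.

    Raises :class:`ParseError` when the sequence is missing, a range token is
    malformed, or a feature falls outside the sequence.
    """
    seq_parts: list[str] = []
    in_sq = False
    pending: list[dict] = []  # raw features, notes attached to the last one
    skipped: dict[str, int] = {}

    for lineno, line in enumerate(raw.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("SQ"):
            in_sq = True
            continue
        if line.startswith("//"):
            in_sq = False
            continue
        if in_sq:
            seq_parts.append(re.sub(r"[\s\d]", "", line))
            continue
        if line.startswith("FT"):
            m = _FT_MODERN.match(line) or _FT_LEGACY.match(line)
            if m:
                kind = m.group("kind")
                if kind not in RECOGNIZED_KINDS:
                    skipped[kind] = skipped.get(kind, 0) + 1
                    pending.append({"kind": None})
                    continue
                start = _parse_pos(m.group("start"), lineno, line)
                end = _parse_pos(m.group("end"), lineno, line)
                if start > end:
                    raise ParseError(
                        f"line {lineno}: start > end in: {line.rstrip()}"
                    )
                note = ""
                if m.groupdict().get("desc"):
                    note = m.group("desc").strip().rstrip(".")
                pending.append(
                    {"kind": kind, "start": start, "end": end, "note": note,
                     "line": line.rstrip(), "lineno": lineno}
                )
                continue
            mc = _FT_CONT.match(line)
            if mc and pending:
                if pending[-1]["kind"] is not None:
                    nm = _NOTE.search(mc.group("text"))
                    extra = nm.group(1) if nm else mc.group("text").strip()
                    prev = pending[-1]["note"]
                    pending[-1]["note"] = f"{prev} {extra}".strip()
                continue
            # an FT line that matches no dialect and is not a continuation
            if re.match(r"^FT\s{3}\S", line):
                raise ParseError(f"line {lineno}: unparseable FT line: {line.rstrip()}")
            continue
        # bare sequence line (no recognized line code, all letters)
        if re.fullmatch(r"[A-Za-z\s\d]+", line) and not re.match(
            r"^(ID|AC|DE|GN|OS|OC|OX|DT|PE|KW|DR|CC|RN|RP|RC|RX|RA|RT|RL|RG|OH)\s", line
        ):
            seq_parts.append(re.sub(r"[\s\d]", "", line))

    sequence = "".join(seq_parts).upper()
    if not sequence:
        raise ParseError("record contains no sequence (no SQ block or sequence lines)")

    features: list[Feature] = []
    for p in pending:
        if p["kind"] is None:
            continue
        if p["end"] > len(sequence):
            raise ParseError(
                f"line {p['lineno']}: feature range {p['start']}..{p['end']} outside "
                f"sequence of length {len(sequence)}: {p['line']}"
            )
        features.append(Feature(p["kind"], ResidueRange(p["start"], p["end"]), p["note"]))
    features.sort(key=lambda f: (f.range.start, f.range.end))

    report = {
        "sequence_length": len(sequence),
        "n_features": len(features),
        "skipped_kinds": skipped,
    }
    return FeatureSet(sequence=sequence, features=features, report=report)


# --------------------------------------------------------------------------
# Classification

_SIDE_WORDS = {
    "cytoplasmic": "intracellular",
    "intracellular": "intracellular",
    "extracellular": "extracellular",
    "lumenal": "extracellular",
}


def _topo_dom_side(note: str) -> str | None:
    low = note.lower()
    for word, side in _SIDE_WORDS.items():
        if word in low:
            return side
    return None


def _group_domains(
    helices: list[Feature], gaps: list[ResidueRange | None], threshold: int
) -> list[list[int]]:
    """Partition helix indices into domains.

    When the helix count is a multiple of six, domains are consecutive runs of
    six.  Otherwise the chain is split at every inter-helix loop longer than
    ``threshold`` residues.
    """
    n = len(helices)
    if n % 6 == 0:
        return [list(range(i, i + 6)) for i in range(0, n, 6)]
    domains: list[list[int]] = [[0]]
    for i in range(1, n):
        gap = gaps[i - 1]
        if gap is not None and len(gap) > threshold:
            domains.append([i])
        else:
            domains[-1].append(i)
    return domains


def classify(
    fset: FeatureSet, *, domain_split_threshold: int = 50
) -> TopologyModel:
    """Classify a feature set into an ordered :class:`TopologyModel`.

    Helices are the TRANSMEM features verbatim; every gap between consecutive
    helices becomes a loop.  The region before the first helix is the
    N-terminal loop, the region after the last is the C-terminal loop.  Inside
    a domain the gap between helices 5 and 6 is the pore loop (an INTRAMEM
    feature or a note containing "Pore" overriding position when present);
    other intra-domain gaps are short loops and gaps between domains are long
    loops.  Sides come from TOPO_DOM features when present, otherwise from
    alternation starting at an intracellular N-terminus — the canonical Nav
    topology.
    """
    helices = fset.of_kind("TRANSMEM")
    if not helices:
        raise ClassifyError("record has no TRANSMEM features")
    L = len(fset.sequence)

    for a, b in zip(helices, helices[1:]):
        if a.range.end >= b.range.start:
            raise ClassifyError(
                f"overlapping TRANSMEM features {a.range.start}..{a.range.end} and "
                f"{b.range.start}..{b.range.end}"
            )

    # inter-helix gaps; None when helices are adjacent (no loop residues)
    gaps: list[ResidueRange | None] = []
    for a, b in zip(helices, helices[1:]):
        if b.range.start - a.range.end > 1:
            gaps.append(ResidueRange(a.range.end + 1, b.range.start - 1))
        else:
            gaps.append(None)

    domains = _group_domains(helices, gaps, domain_split_threshold)
    n_domains = len(domains)

    # helix -> (domain_index, helix_index), both 1-based
    helix_pos: dict[int, tuple[int, int]] = {}
    for d, members in enumerate(domains, start=1):
        for h, idx in enumerate(members, start=1):
            helix_pos[idx] = (d, h)

    intramem = fset.of_kind("INTRAMEM")

    def is_pore_gap(gap_i: int) -> bool:
        """Gap between helix gap_i and gap_i+1 (0-based helices)."""
        d1, h1 = helix_pos[gap_i]
        d2, h2 = helix_pos[gap_i + 1]
        if d1 != d2:
            return False
        gap = gaps[gap_i]
        if gap is not None:
            # annotation-rich records: an INTRAMEM feature, or any feature
            # whose note mentions the pore, overlapping the gap
            for f in intramem:
                if f.range.overlaps(gap):
                    return True
            for f in fset.features:
                if "pore" in f.note.lower() and f.range.overlaps(gap):
                    return True
        return h1 == 5 and h2 == 6

    # build ordered elements
    elements: list[TopologyElement] = []
    if helices[0].range.start > 1:
        elements.append(
            TopologyElement("n_term", ResidueRange(1, helices[0].range.start - 1), "")
        )
    interdomain = 0
    for i, h in enumerate(helices):
        d, hi = helix_pos[i]
        elements.append(TopologyElement("helix", h.range, "membrane", d, hi))
        if i < len(helices) - 1:
            gap = gaps[i]
            if gap is None:
                continue
            d2, _ = helix_pos[i + 1]
            if d2 != d:
                interdomain += 1
                elements.append(
                    TopologyElement(
                        "long_loop", gap, "", interdomain_index=interdomain
                    )
                )
            elif is_pore_gap(i):
                elements.append(TopologyElement("pore_loop", gap, "", domain_index=d))
            else:
                elements.append(TopologyElement("short_loop", gap, "", domain_index=d))
    if helices[-1].range.end < L:
        elements.append(
            TopologyElement("c_term", ResidueRange(helices[-1].range.end + 1, L), "")
        )

    _assign_sides(elements, fset)
    return TopologyModel(sequence=fset.sequence, elements=elements, n_domains=n_domains)


def _assign_sides(elements: list[TopologyElement], fset: FeatureSet) -> None:
    topo_doms = fset.of_kind("TOPO_DOM")

    def annotated_side(rng: ResidueRange) -> str | None:
        found: set[str] = set()
        for f in topo_doms:
            if f.range.overlaps(rng):
                side = _topo_dom_side(f.note)
                if side:
                    found.add(side)
        if len(found) > 1:
            raise ClassifyError(
                f"contradictory TOPO_DOM sides for loop {rng.start}..{rng.end}"
            )
        return found.pop() if found else None

    # starting face: annotated N-terminal side, else intracellular (canonical Nav)
    loops = [e for e in elements if e.kind != "helix"]
    start_side = None
    if loops and loops[0].kind == "n_term":
        start_side = annotated_side(loops[0].range)
    if start_side is None:
        start_side = "intracellular"

    side = start_side
    first = True
    for e in elements:
        if e.kind == "helix":
            side = "extracellular" if side == "intracellular" else "intracellular"
            continue
        expected = side
        annotated = annotated_side(e.range)
        e.side = annotated if annotated is not None else expected
        if first and e.kind == "n_term":
            first = False
        # alternation tracks the face after each full crossing; pore loops sit
        # between two band-spanning helices in the drawing, so no special case
        side = e.side
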