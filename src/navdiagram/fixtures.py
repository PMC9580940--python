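"""Synthetic UniProt-format Nav records and matching annotation tables.

The generator emits flat-text records realizing the canonical Nav alpha
subunit architecture — four domains of six transmembrane helices, a reentrant
pore loop between S5 and S6 of each domain, short intra-domain loops, long
intracellular inter-domain loops and free N/C termini — together with the
ground-truth topology model, so that parser and classifier can be tested by
round trip without any network access.  Matching property and relationship
tables in the CSV schemas are generated the same way.  Everything is
deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topology import Feature, ResidueRange, TopologyElement, TopologyModel

__all__ = ["FixtureSpec", "make_record", "make_properties", "make_relationships"]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_ROMANS = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]


@dataclass(frozen=True)
class FixtureSpec:
    """Architecture and annotation parameters of one synthetic record.

    Defaults produce a canonical Nav alpha subunit.  Residue-count ranges are
    inclusive (low, high) bounds drawn uniformly per element.
    """

    seed: int = 0
    n_domains: int = 4
    helices_per_domain: int = 6
    helix_len: tuple[int, int] = (20, 26)
    short_loop: tuple[int, int] = (5, 15)
    pore_loop: tuple[int, int] = (25, 45)
    long_loop: tuple[int, int] = (80, 300)
    terminal: tuple[int, int] = (60, 150)
    include_topo_dom: bool = True
    include_intramem: bool = True
    legacy_ft: bool = False
    property_names: tuple[str, ...] = ("Conservation",)
    n_relationships: int = 8

    def __post_init__(self) -> None:
        for name in ("helix_len", "short_loop", "pore_loop", "long_loop", "terminal"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} range must be positive and ordered")
        if self.n_domains < 1 or self.helices_per_domain < 2:
            raise ValueError("need at least one domain of two helices")


def _wrap_sequence(seq: str) -> list[str]:
    """SQ block body: 60 residues per line in 10-residue chunks, indented."""
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i:i + 60]
        grouped = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append("     " + grouped)
    return lines


def make_record(spec: FixtureSpec) -> tuple[str, TopologyModel]:
    """Emit a flat-text record and its ground-truth topology model."""
    rng = np.random.default_rng(spec.seed)

    def draw(bounds: tuple[int, int]) -> int:
        return int(rng.integers(bounds[0], bounds[1] + 1))

    # --- architecture: ordered (kind, length) plan ------------------------
    plan: list[tuple[str, int, dict]] = []
    plan.append(("n_term", draw(spec.terminal), {}))
    hp = spec.helices_per_domain
    for d in range(1, spec.n_domains + 1):
        for h in range(1, hp + 1):
            plan.append(("helix", draw(spec.helix_len), {"domain": d, "helix": h}))
            if h < hp:
                if h == hp - 1:  # S5 -> S6 gap: the reentrant pore loop
                    plan.append(("pore_loop", draw(spec.pore_loop), {"domain": d}))
                else:
                    plan.append(("short_loop", draw(spec.short_loop), {"domain": d}))
        if d < spec.n_domains:
            plan.append(("long_loop", draw(spec.long_loop), {"interdomain": d}))
    plan.append(("c_term", draw(spec.terminal), {}))

    total = sum(n for _, n, _ in plan)
    sequence = "".join(rng.choice(list(_AA), size=total))

    # --- features + ground-truth elements ---------------------------------
    features: list[Feature] = []
    elements: list[TopologyElement] = []
    pos = 1
    side = "intracellular"  # canonical Nav: N-terminus inside
    sides: list[tuple[int, int, str]] = []
    for kind, n, meta in plan:
        start, end = pos, pos + n - 1
        rng_ = ResidueRange(start, end)
        pos = end + 1
        if kind == "helix":
            roman = _ROMANS[meta["domain"] - 1]
            features.append(Feature(
                "TRANSMEM", rng_,
                f"Helical; Name=S{meta['helix']} of repeat {roman}",
            ))
            elements.append(TopologyElement(
                "helix", rng_, "membrane", meta["domain"], meta["helix"]
            ))
            side = "extracellular" if side == "intracellular" else "intracellular"
        else:
            sides.append((start, end, side))
            elements.append(TopologyElement(
                kind, rng_, side,
                domain_index=meta.get("domain"),
                interdomain_index=meta.get("interdomain"),
            ))
            if kind == "pore_loop" and spec.include_intramem:
                # the reentrant segment occupies the middle of the loop
                third = max(1, n // 3)
                features.append(Feature(
                    "INTRAMEM", ResidueRange(start + third - 1, end - third + 1),
                    "Pore-forming",
                ))

    if spec.include_topo_dom:
        for start, end, face in sides:
            note = "Cytoplasmic" if face == "intracellular" else "Extracellular"
            features.append(Feature("TOPO_DOM", ResidueRange(start, end), note))

    features.sort(key=lambda f: (f.range.start, f.range.end))

    # --- flat text ---------------------------------------------------------
    lines = [
        f"ID   NAVX{spec.seed}_SYN            Reviewed;        {total} AA.",
        f"AC   P{spec.seed % 100000:05d};",
        "DE   RecName: Full=Sodium channel protein alpha subunit (synthetic);",
    ]
    for f in features:
        if spec.legacy_ft:
            lines.append(f"FT   {f.kind:<12}{f.range.start:>7}{f.range.end:>7}       {f.note}.")
        else:
            lines.append(f"FT   {f.kind:<16}{f.range.start}..{f.range.end}")
            if f.note:
                lines.append(f'FT                   /note="{f.note}"')
    lines.append(f"SQ   SEQUENCE   {total} AA;  0 MW;  0000000000000000 CRC64;")
    lines.extend(_wrap_sequence(sequence))
    lines.append("//")
    text = "\n".join(lines) + "\n"

    model = TopologyModel(
        sequence=sequence, elements=elements, n_domains=spec.n_domains
    )
    return text, model


def make_properties(
    seed: int, n_residues: int, names: tuple[str, ...] = ("Conservation",)
) -> str:
    """Property CSV: uniform [0, 1] values per residue per name, 10 decimals."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    header = "Resid," + ",".join(names)
    rows = [header]
    values = rng.uniform(0.0, 1.0, size=(n_residues, len(names)))
    for i in range(n_residues):
        cells = ",".join(f"{v:.10f}" for v in values[i])
        rows.append(f"{i + 1},{cells}")
    return "\n".join(rows) + "\n"


def make_relationships(seed: int, topology: TopologyModel, n: int = 8) -> str:
    """Relationship CSV mixing residue-residue and element-element rows.

    All emitted addresses resolve against the given topology.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    helices = topology.helices()
    long_loops = topology.of_kind("long_loop")
    rows = ["source,target,raw_weight,type"]
    for _ in range(n):
        weight = rng.uniform(0.0, 1.0)
        if rng.random() < 0.5 or not helices:
            a = int(rng.integers(1, topology.length + 1))
            b = int(rng.integers(1, topology.length + 1))
            rows.append(f"{a},{b},{weight:.10f},Resids")
        else:
            def element_address() -> str:
                if long_loops and rng.random() < 0.3:
                    e = long_loops[int(rng.integers(len(long_loops)))]
                    return f"InterDomain{e.interdomain_index}; Loop"
                e = helices[int(rng.integers(len(helices)))]
                return f"Domain{_ROMANS[e.domain_index - 1]}; Helix{e.helix_index}"

            rows.append(f"{element_address()},{element_address()},{weight:.10f},Elements")
    return "\n".join(rows) + "\n"
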