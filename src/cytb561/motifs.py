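"""Region-constrained motif scanning and the ferric-reductase residue checklist.

The family's diagnostic patterns are short position-constrained motifs, each
tied to a topological region:

* ``KXXXXKXH`` — the non-cytoplasmic loop between H2 and H3 of TScytb-like
  proteins, its histidine canonically at H3−5 (so the two lysines sit at
  H3−12 and H3−7);
* C-terminal dileucine sorting signals ``EDXXLL`` ⊃ ``(D/E)XXXL(L/I)`` and
  ``DXXLL``, scanned only downstream of the last transmembrane segment;
* ``SXDXXMGXD`` — the DOMON-domain aspartate pocket whose methionine is a
  putative heme ligand.

The checklist collects the substrate- and heme-binding residues of the
reference ferric reductase Dcytb, each expressed in anchor-relative
coordinates with the substitution set actually observed across the family;
the four activity-critical items (H2+22 His, H2+21 Asn/Ser, H3−3 Tyr,
H4+25 aromatic) gate the ``core4_pass`` verdict.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .anchors import AnchorMap, RelPos, TMTopology, resolve
from .identity import Span
from .seqio import AMINO_ACIDS, AlignmentBlock, ProteinRecord

__all__ = [
    "MotifSpec",
    "MotifHit",
    "ChecklistItem",
    "ChecklistReport",
    "scan_motif",
    "dileucine_signals",
    "kxh_site",
    "domon_heme_ligands",
    "cysteine_loop_profile",
    "ferric_reductase_checklist",
    "KXH_MOTIF",
    "EDXXLL",
    "DILEUCINE_GENERAL",
    "DXXLL",
    "DOMON_POCKET",
    "CHECKLIST_CATALOG",
]


@dataclass(frozen=True)
class MotifSpec:
    """A named pattern of position constraints.

    Each position is either a frozenset of allowed residues or None for a
    wildcard. Pattern strings use X for wildcards and (A/B) for classes,
    e.g. ``(D/E)XXXL(L/I)``.
    """

    name: str
    positions: tuple[frozenset[str] | None, ...]
    region_constraint: str | None = None

    def __post_init__(self) -> None:
        if len(self.positions) < 3:
            raise ValueError(f"motif {self.name!r}: pattern length must be >= 3")
        for p in self.positions:
            if p is not None and not p:
                raise ValueError(f"motif {self.name!r}: empty residue class")

    def __len__(self) -> int:
        return len(self.positions)

    @classmethod
    def parse(
        cls, name: str, pattern: str, region_constraint: str | None = None
    ) -> "MotifSpec":
        positions: list[frozenset[str] | None] = []
        for token in re.findall(r"\(([A-Z/]+)\)|([A-Z])", pattern):
            cls_text, single = token
            if cls_text:
                positions.append(frozenset(cls_text.split("/")))
            elif single == "X":
                positions.append(None)
            else:
                positions.append(frozenset(single))
        return cls(name=name, positions=tuple(positions), region_constraint=region_constraint)

    def matches(self, fragment: str) -> bool:
        if len(fragment) != len(self.positions):
            return False
        for ch, constraint in zip(fragment, self.positions):
            if constraint is None:
                continue  # wildcard: any residue, including ambiguity codes
            if ch not in AMINO_ACIDS or ch not in constraint:
                return False  # ambiguity codes only match wildcards
        return True


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence: 1-based inclusive coordinates on the sequence."""

    motif: str
    seq_id: str
    start: int
    end: int
    matched: str
    region: str = ""
    canonical_register: bool | None = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.matched):
            raise ValueError("hit span inconsistent with matched substring")


KXH_MOTIF = MotifSpec.parse("KXXXXKXH", "KXXXXKXH", "non-cytoplasmic loop H2-H3")
EDXXLL = MotifSpec.parse("EDXXLL", "EDXXLL", "C-terminal tail")
DILEUCINE_GENERAL = MotifSpec.parse(
    "(D/E)XXXL(L/I)", "(D/E)XXXL(L/I)", "C-terminal tail"
)
DXXLL = MotifSpec.parse("DXXLL", "DXXLL", "C-terminal tail")
DOMON_POCKET = MotifSpec.parse("SXDXXMGXD", "SXDXXMGXD", None)


def scan_motif(
    seq: ProteinRecord,
    spec: MotifSpec,
    region: Span | None = None,
    region_label: str = "",
) -> list[MotifHit]:
    """All (possibly overlapping) matches of a motif within a region.

    Left-to-right; a hit must lie entirely inside the region. Returns an
    empty list when nothing matches.
    """
    s = seq.sequence
    lo = region.start if region else 1
    hi = region.end if region else len(s)
    hi = min(hi, len(s))
    hits = []
    for start in range(lo, hi - len(spec) + 2):
        fragment = s[start - 1 : start - 1 + len(spec)]
        if spec.matches(fragment):
            hits.append(
                MotifHit(
                    motif=spec.name,
                    seq_id=seq.id,
                    start=start,
                    end=start + len(spec) - 1,
                    matched=fragment,
                    region=region_label or (spec.region_constraint or ""),
                )
            )
    return hits


def dileucine_signals(seq: ProteinRecord, topology: TMTopology) -> list[MotifHit]:
    """Dileucine-type sorting signals in the tail downstream of the last
    transmembrane segment.

    Each 6-residue hit is labeled with the most specific spec it satisfies
    (EDXXLL before the general (D/E)XXXL(L/I)); DXXLL hits are reported as
    their own 5-residue spans. No tail means no hits.
    """
    if not topology.segments:
        raise ValueError("topology has no transmembrane segments")
    tail_start = topology.segments[-1][1] + 1
    if tail_start > len(seq.sequence):
        return []
    tail = Span(tail_start, len(seq.sequence))
    hits: list[MotifHit] = []
    general = scan_motif(seq, DILEUCINE_GENERAL, tail)
    exact_starts = {h.start for h in scan_motif(seq, EDXXLL, tail)}
    for h in general:
        if h.start in exact_starts:
            hits.append(
                MotifHit(
                    motif="EDXXLL",
                    seq_id=h.seq_id,
                    start=h.start,
                    end=h.end,
                    matched=h.matched,
                    region="C-terminal tail",
                )
            )
        else:
            hits.append(h)
    hits.extend(scan_motif(seq, DXXLL, tail))
    return sorted(hits, key=lambda h: (h.start, -len(h.matched)))


def kxh_site(seq: ProteinRecord, amap: AnchorMap) -> list[MotifHit]:
    """KXXXXKXH occurrences in the inter-anchor window H2+1 .. H3−1.

    Each hit records whether its histidine sits exactly at H3−5, the
    canonical register of TScytb-like proteins (implying lysines at H3−12
    and H3−7).
    """
    idxs = amap.anchor_indices(seq.id)
    h2, h3 = idxs[1], idxs[2]
    if h2 is None or h3 is None:
        raise ValueError(f"{seq.id}: H2/H3 anchors unmapped")
    if h3 - h2 - 1 < len(KXH_MOTIF):
        return []
    window = Span(h2 + 1, h3 - 1)
    hits = scan_motif(seq, KXH_MOTIF, window, region_label="non-cytoplasmic loop H2-H3")
    return [
        MotifHit(
            motif=h.motif,
            seq_id=h.seq_id,
            start=h.start,
            end=h.end,
            matched=h.matched,
            region=h.region,
            canonical_register=(h.end == h3 - 5),
        )
        for h in hits
    ]


def domon_heme_ligands(
    seq: ProteinRecord,
    domon_span: Span,
    aln: AlignmentBlock | None = None,
    his_fraction_min: float = 0.90,
) -> tuple[int | None, int | None]:
    """Putative DOMON heme ligands: the SXDXXMGXD methionine and, given an
    alignment of DOMON domains, the conserved downstream histidine.

    Met is the M of the unique pocket match within the span (None for zero
    or multiple matches). His requires an alignment: the residue of this
    sequence at the best column downstream of the Met column carrying His in
    at least ``his_fraction_min`` of rows (ties break leftward). In
    single-sequence mode His is None.
    """
    if domon_span.end > len(seq.sequence):
        raise ValueError(
            f"DOMON span ({domon_span.start}, {domon_span.end}) outside "
            f"sequence {seq.id!r}"
        )
    hits = scan_motif(seq, DOMON_POCKET, domon_span)
    if len(hits) != 1:
        return (None, None)
    met_index = hits[0].start + 5  # S x D x x M g x d

    if aln is None:
        return (met_index, None)
    row = aln.row(seq.id)
    # locate the alignment column of met_index
    met_col = None
    count = 0
    for col, ch in enumerate(row, start=1):
        if ch != "-":
            count += 1
            if count == met_index:
                met_col = col
                break
    if met_col is None:
        return (met_index, None)
    best_col, best_frac = None, 0.0
    for col in range(met_col + 1, aln.n_columns + 1):
        frac = aln.column(col).count("H") / aln.n_rows
        if frac >= his_fraction_min and frac > best_frac:
            best_col, best_frac = col, frac
    if best_col is None:
        return (met_index, None)
    his_index = aln.residue_index(seq.id, best_col)
    return (met_index, his_index)


def cysteine_loop_profile(
    seq: ProteinRecord,
    amap: AnchorMap,
    topology: TMTopology,
) -> dict:
    """Cysteine census of the three core-domain loops.

    The loops run cytoplasmic, non-cytoplasmic, cytoplasmic between the four
    anchor-bearing segments. A sequence is "Nemy-like cysteine-rich" when
    both cytoplasmic loops carry at least two cysteines.
    """
    if topology.core_register == "undetermined" or not topology.region_sides:
        raise ValueError(f"{seq.id}: core register/sidedness undetermined")
    idxs = amap.anchor_indices(seq.id)
    if any(i is None for i in idxs):
        raise ValueError(f"{seq.id}: anchors unmapped")
    first = topology.segment_of(idxs[0])
    loops = []
    for k in range(3):
        span = topology.loop_span(first + k)
        if span is None:
            loops.append("")
        else:
            loops.append(seq.sequence[span[0] - 1 : span[1]])
    counts = tuple(loop.count("C") for loop in loops)
    double = tuple("CC" in loop for loop in loops)
    return {
        "loops": tuple(loops),
        "sides": ("cytoplasmic", "non-cytoplasmic", "cytoplasmic"),
        "cys_counts": counts,
        "double_cys": double,
        "nemy_like": counts[0] >= 2 and counts[2] >= 2,
    }


#: The Dcytb-derived residue catalog: anchor-relative position -> allowed
#: residues. The four activity-critical items come first.
CHECKLIST_CORE4: tuple[tuple[str, frozenset[str]], ...] = (
    ("H2+22", frozenset("H")),
    ("H2+21", frozenset("NS")),
    ("H3-3", frozenset("Y")),
    ("H4+25", frozenset("FYW")),
)
CHECKLIST_SUPPORTING: tuple[tuple[str, frozenset[str]], ...] = (
    ("H1-3", frozenset("F")),
    ("H2-7", frozenset("KR")),
    ("H2-3", frozenset("KR")),
    ("H4-7", frozenset("KR")),
    ("H1+20", frozenset("RK")),
    ("H3+14", frozenset("QST")),
    ("H3-2", frozenset("STN")),
    ("H3-5", frozenset("NH")),
    ("H3+2", frozenset("W")),
    ("H3+4", frozenset("GAS")),
    ("H3+18", frozenset("GAS")),
    ("H4+4", frozenset("GAS")),
    ("H4+18", frozenset("GAS")),
)
CHECKLIST_CATALOG = CHECKLIST_CORE4 + CHECKLIST_SUPPORTING


@dataclass(frozen=True)
class ChecklistItem:
    position: str
    expected: frozenset[str]
    observed: str | None  # None when the offset leaves the sequence
    residue_index: int | None

    @property
    def resolvable(self) -> bool:
        return self.observed is not None

    @property
    def passed(self) -> bool:
        return self.observed is not None and self.observed in self.expected


@dataclass(frozen=True)
class ChecklistReport:
    seq_id: str
    items: tuple[ChecklistItem, ...]

    @property
    def core4(self) -> tuple[ChecklistItem, ...]:
        names = {pos for pos, _ in CHECKLIST_CORE4}
        return tuple(i for i in self.items if i.position in names)

    @property
    def core4_pass(self) -> bool:
        return all(i.passed for i in self.core4)

    @property
    def score(self) -> int:
        """Number of catalog items passed."""
        return sum(1 for i in self.items if i.passed)

    def item(self, position: str) -> ChecklistItem:
        for i in self.items:
            if i.position == position:
                return i
        raise KeyError(position)


def ferric_reductase_checklist(
    seq: ProteinRecord,
    amap: AnchorMap,
    catalog: tuple[tuple[str, frozenset[str]], ...] = CHECKLIST_CATALOG,
) -> ChecklistReport:
    """Evaluate the Dcytb-derived residue catalog on one sequence.

    Offsets that leave the sequence are unresolvable, not failures, but an
    unresolvable activity-critical item still blocks ``core4_pass``.
    """
    items = []
    for pos_text, expected in catalog:
        pos = RelPos.parse(pos_text)
        try:
            ridx, aa = resolve(amap, seq.id, pos)
        except IndexError:
            items.append(
                ChecklistItem(
                    position=pos_text, expected=expected, observed=None,
                    residue_index=None,
                )
            )
            continue
        items.append(
            ChecklistItem(
                position=pos_text, expected=expected, observed=aa, residue_index=ridx
            )
        )
    return ChecklistReport(seq_id=seq.id, items=tuple(items))
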