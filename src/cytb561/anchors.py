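"""Histidine anchors, the H1±n residue coordinate system, and membrane topology.

Every cytochrome b561 domain carries four universally conserved histidines
(H1–H4) that coordinate the two b-type hemes; H1/H3 ligate the
non-cytoplasmic heme and H2/H4 the cytoplasmic one. Because loop lengths
drift freely across the family, absolute residue numbers are not comparable
between sequences — positions are therefore expressed as signed offsets from
the nearest anchor (H1+20, H3-5, ...), which is the coordinate system the
rest of the package speaks.

Transmembrane segments are assigned from Kyte–Doolittle hydropathy, a
sequence-only surrogate for reading helices off a structure; its window,
threshold and minimum length are exposed.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass, field

from .seqio import AlignmentBlock, ProteinRecord

__all__ = [
    "AnchorError",
    "AnchorMap",
    "RelPos",
    "TMTopology",
    "find_histidine_anchors",
    "to_relative",
    "resolve",
    "core_region",
    "predict_tm_segments",
    "assign_sidedness",
    "KYTE_DOOLITTLE",
]

ANCHOR_NAMES = ("H1", "H2", "H3", "H4")

#: Kyte & Doolittle (1982) hydropathy index.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
    # ambiguity codes: neutral
    "X": 0.0, "B": -3.5, "Z": -3.5, "U": 2.5,
}


class AnchorError(ValueError):
    """Raised when the four heme histidines cannot be located or resolved."""


@dataclass(frozen=True)
class RelPos:
    """A residue position relative to one of the four anchor histidines."""

    anchor: str  # H1..H4
    offset: int  # signed; 0 means the anchor itself

    _PATTERN = re.compile(r"^(H[1-4])(?:([+-])(\d+))?$")

    def __post_init__(self) -> None:
        if self.anchor not in ANCHOR_NAMES:
            raise ValueError(f"anchor must be one of {ANCHOR_NAMES}, got {self.anchor!r}")

    def __str__(self) -> str:
        if self.offset == 0:
            return self.anchor
        sign = "+" if self.offset > 0 else "-"
        return f"{self.anchor}{sign}{abs(self.offset)}"

    @classmethod
    def parse(cls, text: str) -> "RelPos":
        m = cls._PATTERN.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse relative position {text!r}")
        anchor, sign, digits = m.groups()
        offset = 0 if digits is None else int(digits) * (1 if sign == "+" else -1)
        return cls(anchor=anchor, offset=offset)


@dataclass(frozen=True)
class AnchorMap:
    """Alignment columns and per-sequence residue indices of H1–H4."""

    anchor_columns: tuple[int, int, int, int]  # 1-based, strictly increasing
    per_sequence: dict[str, tuple[int | None, int | None, int | None, int | None]]
    his_fraction: tuple[float, float, float, float]
    sequences: dict[str, str] = field(default_factory=dict)  # id -> ungapped seq

    def __post_init__(self) -> None:
        c = self.anchor_columns
        if not (c[0] < c[1] < c[2] < c[3]):
            raise AnchorError(f"anchor columns not strictly increasing: {c}")
        for sid, idxs in self.per_sequence.items():
            seq = self.sequences.get(sid)
            if seq is None:
                continue
            for k, idx in enumerate(idxs):
                if idx is not None and seq[idx - 1] != "H":
                    raise AnchorError(
                        f"{sid}: residue at anchor H{k + 1} index {idx} is "
                        f"{seq[idx - 1]!r}, not His"
                    )

    def anchor_indices(self, seq_id: str) -> tuple[int | None, ...]:
        try:
            return self.per_sequence[seq_id]
        except KeyError:
            raise AnchorError(f"sequence {seq_id!r} not in anchor map") from None

    def is_fully_mapped(self, seq_id: str) -> bool:
        return all(i is not None for i in self.anchor_indices(seq_id))


def find_histidine_anchors(
    aln: AlignmentBlock,
    h_min: float = 0.95,
    min_gap: int = 15,
    max_gap: int = 90,
) -> AnchorMap:
    """Locate the four heme-coordinating histidine columns of an alignment.

    Candidate columns are those where the His fraction (over all rows,
    gaps counting against) is at least ``h_min``. Among quadruples of
    candidates whose consecutive column spacings all fall in
    [``min_gap``, ``max_gap``], the one maximising the summed His fraction
    wins; ties break toward the leftmost column tuple.
    """
    if aln.n_rows < 2:
        raise AnchorError("anchor detection needs at least 2 sequences")
    n = aln.n_rows
    fractions = {}
    for col in range(1, aln.n_columns + 1):
        frac = aln.column(col).count("H") / n
        if frac >= h_min:
            fractions[col] = frac
    candidates = sorted(fractions)
    if len(candidates) < 4:
        raise AnchorError(
            f"anchors not found: only {len(candidates)} candidate columns with "
            f"His fraction >= {h_min} (need 4); candidates: {candidates}"
        )

    best: tuple[int, ...] | None = None
    best_score = float("-inf")
    for quad in itertools.combinations(candidates, 4):
        if not all(min_gap <= b - a <= max_gap for a, b in zip(quad, quad[1:])):
            continue
        score = sum(fractions[c] for c in quad)
        if score > best_score or (score == best_score and (best is None or quad < best)):
            best, best_score = quad, score
    if best is None:
        raise AnchorError(
            "anchors not found: no quadruple of candidate columns satisfies "
            f"spacing in [{min_gap}, {max_gap}]; candidates: {candidates}"
        )

    per_sequence = {}
    sequences = {}
    for sid in aln.ids:
        idxs = []
        seq = aln.row(sid).replace("-", "")
        for col in best:
            ridx = aln.residue_index(sid, col)
            if ridx is not None and seq[ridx - 1] != "H":
                ridx = None  # substituted at the anchor column: treat as absent
            idxs.append(ridx)
        per_sequence[sid] = tuple(idxs)
        sequences[sid] = seq
    return AnchorMap(
        anchor_columns=tuple(best),
        per_sequence=per_sequence,
        his_fraction=tuple(fractions[c] for c in best),
        sequences=sequences,
    )


def to_relative(amap: AnchorMap, seq_id: str, residue_index: int) -> RelPos:
    """Express a residue index as an offset from the nearest anchor.

    Ties between two equidistant anchors resolve to the downstream-of-anchor
    (positive-offset) form.
    """
    idxs = amap.anchor_indices(seq_id)
    if all(i is None for i in idxs):
        raise AnchorError(f"sequence {seq_id!r} has no mapped anchors")
    seq = amap.sequences.get(seq_id)
    if seq is not None and not 1 <= residue_index <= len(seq):
        raise IndexError(f"residue index {residue_index} outside sequence {seq_id!r}")
    best: RelPos | None = None
    for name, aidx in zip(ANCHOR_NAMES, idxs):
        if aidx is None:
            continue
        off = residue_index - aidx
        if best is None or abs(off) < abs(best.offset) or (
            abs(off) == abs(best.offset) and off > best.offset
        ):
            best = RelPos(anchor=name, offset=off)
    assert best is not None
    return best


def resolve(amap: AnchorMap, seq_id: str, pos: RelPos | str) -> tuple[int, str]:
    """Map an anchor-relative position to (1-based residue index, amino acid)."""
    if isinstance(pos, str):
        pos = RelPos.parse(pos)
    idxs = amap.anchor_indices(seq_id)
    aidx = idxs[ANCHOR_NAMES.index(pos.anchor)]
    if aidx is None:
        raise AnchorError(f"anchor {pos.anchor} is unmapped in sequence {seq_id!r}")
    seq = amap.sequences.get(seq_id)
    if seq is None:
        raise AnchorError(f"no sequence stored for {seq_id!r}")
    ridx = aidx + pos.offset
    if not 1 <= ridx <= len(seq):
        raise IndexError(
            f"offset leaves sequence: {pos} of {seq_id!r} maps to {ridx} "
            f"(sequence length {len(seq)})"
        )
    return ridx, seq[ridx - 1]


def core_region(
    amap: AnchorMap,
    aln: AlignmentBlock,
    upstream_flank: int = 10,
    downstream_flank: int = 10,
) -> dict[str, tuple[int, int]]:
    """Per-sequence residue spans of the ~130-residue heme-carrying core.

    The core is the alignment window [H1 column − upstream_flank,
    H4 column + downstream_flank], clipped to the alignment; each sequence's
    span is the ungapped projection of that window.
    """
    start_col = max(1, amap.anchor_columns[0] - upstream_flank)
    end_col = min(aln.n_columns, amap.anchor_columns[3] + downstream_flank)
    spans = {}
    for sid in aln.ids:
        row = aln.row(sid)
        first = last = None
        for col in range(start_col, end_col + 1):
            if row[col - 1] != "-":
                ridx = aln.residue_index(sid, col)
                if first is None:
                    first = ridx
                last = ridx
        if first is None:
            continue  # fully gapped in the window
        spans[sid] = (first, last)
    return spans


@dataclass(frozen=True)
class TMTopology:
    """Predicted transmembrane segments with sidedness annotation.

    ``region_sides`` covers the n_segments+1 soluble regions (N-terminal
    region, the inter-segment loops, C-terminal region); ``loop_sides`` is
    the inter-segment subset. Sides strictly alternate across each segment.
    """

    segments: tuple[tuple[int, int], ...]  # 1-based inclusive spans
    n_terminus_side: str | None = None  # cytoplasmic | non-cytoplasmic
    region_sides: tuple[str, ...] = ()
    core_register: str = "undetermined"  # TM2-TM5 | TM1-TM4 | undetermined

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.segments, self.segments[1:]):
            if not (s1 <= e1 < s2 <= e2):
                raise ValueError(f"segments overlap or are unordered: {self.segments}")
        if self.region_sides:
            for a, b in zip(self.region_sides, self.region_sides[1:]):
                if a == b:
                    raise ValueError("sides must alternate across each segment")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def loop_sides(self) -> tuple[str, ...]:
        """Sides of the inter-segment loops only."""
        return self.region_sides[1:-1] if self.region_sides else ()

    def segment_of(self, residue_index: int) -> int | None:
        """1-based segment number containing a residue, or None if in a loop."""
        for k, (s, e) in enumerate(self.segments, start=1):
            if s <= residue_index <= e:
                return k
        return None

    def loop_span(self, after_segment: int) -> tuple[int, int] | None:
        """Residue span of the loop following segment ``after_segment``."""
        if not 1 <= after_segment < self.n_segments:
            raise IndexError(f"no loop after segment {after_segment}")
        s = self.segments[after_segment - 1][1] + 1
        e = self.segments[after_segment][0] - 1
        return (s, e) if s <= e else None


def predict_tm_segments(
    seq: ProteinRecord,
    window: int = 19,
    threshold: float = 1.6,
    min_len: int = 15,
) -> TMTopology:
    """Predict transmembrane helices from windowed Kyte–Doolittle hydropathy.

    The hydropathy profile is averaged over a centred ``window`` (computed
    only where the full window fits); maximal runs of centres at or above
    ``threshold`` become segments, runs separated by fewer than 3 residues
    are merged, and segments shorter than ``min_len`` are dropped.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    s = seq.sequence
    if len(s) < window:
        raise ValueError(
            f"sequence {seq.id!r} shorter ({len(s)}) than window ({window})"
        )
    half = window // 2
    values = [KYTE_DOOLITTLE[c] for c in s]
    # centres in 1-based coordinates half+1 .. len-half
    total = sum(values[:window])
    averages: dict[int, float] = {half + 1: total / window}
    for centre in range(half + 2, len(s) - half + 1):
        total += values[centre + half - 1] - values[centre - half - 2]
        averages[centre] = total / window

    runs: list[list[int]] = []
    for centre in sorted(averages):
        if averages[centre] >= threshold:
            if runs and centre == runs[-1][1] + 1:
                runs[-1][1] = centre
            else:
                runs.append([centre, centre])
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 < 3:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    segments = tuple(
        (a, b) for a, b in merged if b - a + 1 >= min_len
    )
    return TMTopology(segments=segments)


def assign_sidedness(
    topology: TMTopology,
    amap: AnchorMap,
    seq_id: str,
    architecture: str = "single-domain",
) -> TMTopology:
    """Complete a topology with membrane sidedness and the core register.

    Single-domain cytochromes b561 start cytoplasmic (N-in); CYBDOMs start
    non-cytoplasmic (their DOMON/reeler domains are extracellular). Sides
    alternate at every membrane crossing. The register is TM2–TM5 when H1
    falls in segment 2 and TM1–TM4 when it falls in segment 1; any anchor
    landing outside a segment, or anchors not occupying four consecutive
    segments, leaves the register undetermined with a warning.
    """
    if architecture not in ("single-domain", "cybdom"):
        raise ValueError(f"unknown architecture {architecture!r}")
    n_side = "cytoplasmic" if architecture == "single-domain" else "non-cytoplasmic"
    sides = [n_side]
    for _ in topology.segments:
        sides.append(
            "non-cytoplasmic" if sides[-1] == "cytoplasmic" else "cytoplasmic"
        )

    idxs = amap.anchor_indices(seq_id)
    register = "undetermined"
    if all(i is not None for i in idxs):
        segs = [topology.segment_of(i) for i in idxs]
        if None not in segs and tuple(segs) == tuple(
            range(segs[0], segs[0] + 4)  # type: ignore[arg-type]
        ):
            if segs[0] == 2:
                register = "TM2-TM5"
            elif segs[0] == 1:
                register = "TM1-TM4"
    if register == "undetermined":
        warnings.warn(
            f"{seq_id}: anchors do not occupy four consecutive transmembrane "
            "segments; core register undetermined",
            stacklevel=2,
        )
    else:
        # The three core loops must run cytoplasmic, non-cytoplasmic,
        # cytoplasmic (H1/H3 sit by the non-cytoplasmic heme, H2/H4 by the
        # cytoplasmic one). The loop after segment k has side sides[k].
        first = topology.segment_of(idxs[0])
        core_loops = sides[first : first + 3]
        if core_loops != ["cytoplasmic", "non-cytoplasmic", "cytoplasmic"]:
            warnings.warn(
                f"{seq_id}: core loop sidedness {core_loops} inconsistent with "
                "heme geometry; check architecture",
                stacklevel=2,
            )
    return TMTopology(
        segments=topology.segments,
        n_terminus_side=n_side,
        region_sides=tuple(sides),
        core_register=register,
    )
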