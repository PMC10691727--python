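"""Alignment-column conservation: consensus symbols, a physicochemical
property score, and standardized entropy scores.

Three views of the same alignment, matching how the family is usually
inspected. The consensus row is the modal residue with '+' marking frequency
ties and '-' marking gap-dominated columns. The 0–11 property score counts
the physicochemical properties (hydrophobic, polar, small, tiny, aliphatic,
aromatic, charged, positive, negative, proline) on which every residue in a
column agrees, with 11 reserved for gap-free single-residue columns — the
convention under which "a score of 8 or 9" reads as high conservation. The
z-score view standardizes per-column Shannon entropy so that positive means
more conserved than the alignment average; display clamps to ±1.5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .seqio import AMINO_ACIDS, AlignmentBlock

__all__ = [
    "PROPERTY_TABLE",
    "ConservationProfile",
    "consensus_logo",
    "amas_conservation",
    "al2co_standardized",
    "group_consensus",
    "profile",
]

#: Physicochemical property sets (Taylor-style, as used by alignment viewers).
PROPERTY_TABLE: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("ILVCAGMFYWHKT"),
    "polar": frozenset("YWHKREQDNSTC"),
    "small": frozenset("VCAGDNSTP"),
    "tiny": frozenset("AGS"),
    "aliphatic": frozenset("ILV"),
    "aromatic": frozenset("FYWH"),
    "charged": frozenset("HKRED"),
    "positive": frozenset("HKR"),
    "negative": frozenset("ED"),
    "proline": frozenset("P"),
}


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation of one alignment (or row subset)."""

    frequencies: tuple[dict[str, float], ...]  # residue/gap -> fraction of rows
    consensus: str  # one symbol per column: residue, '+', or '-'
    amas_scores: tuple[int, ...]
    z_scores: tuple[float, ...]

    @property
    def n_columns(self) -> int:
        return len(self.consensus)

    def clamped_z(self, bound: float = 1.5) -> tuple[float, ...]:
        """Display-clamped z-scores (the raw values stay in ``z_scores``)."""
        return tuple(max(-bound, min(bound, z)) for z in self.z_scores)


def _column_counts(aln: AlignmentBlock) -> list[dict[str, int]]:
    counts = []
    for col in range(1, aln.n_columns + 1):
        c: dict[str, int] = {}
        for ch in aln.column(col):
            c[ch] = c.get(ch, 0) + 1
        counts.append(c)
    return counts


def consensus_logo(aln: AlignmentBlock) -> tuple[tuple[dict[str, float], ...], str]:
    """Per-column residue/gap frequencies and the consensus string.

    The consensus symbol is the modal residue; '+' when two or more residues
    tie for the maximum; '-' when the gap frequency strictly exceeds every
    residue's frequency.
    """
    n = aln.n_rows
    freqs = []
    symbols = []
    for counts in _column_counts(aln):
        freq = {ch: cnt / n for ch, cnt in counts.items()}
        freqs.append(freq)
        residue_counts = {ch: c for ch, c in counts.items() if ch != "-"}
        gap_count = counts.get("-", 0)
        if not residue_counts:
            symbols.append("-")
            continue
        top = max(residue_counts.values())
        if gap_count > top:
            symbols.append("-")
        elif sum(1 for c in residue_counts.values() if c == top) >= 2:
            symbols.append("+")
        else:
            symbols.append(max(residue_counts, key=residue_counts.get))
    return tuple(freqs), "".join(symbols)


def amas_score_column(residues: set[str], has_gap: bool) -> int:
    """Property-agreement score of one column given its distinct residues."""
    if not residues:
        return 0
    if len(residues) == 1 and not has_gap:
        return 11
    score = 0
    for members in PROPERTY_TABLE.values():
        inside = residues & members
        if not inside or inside == residues:
            score += 1
    if has_gap:
        score = max(0, score - 1)
    return score


def amas_conservation(aln: AlignmentBlock) -> tuple[int, ...]:
    """0–11 property-agreement score per column.

    11 only for gap-free single-residue columns; a gap in the column costs
    one point (floor 0); all-gap columns score 0. Ambiguity codes (X/B/Z/U)
    carry no properties, so any of them breaks every property agreement.
    """
    scores = []
    for counts in _column_counts(aln):
        residues = {ch for ch in counts if ch != "-"}
        has_gap = "-" in counts
        if residues - AMINO_ACIDS:
            # ambiguity codes carry no properties: nothing can agree
            scores.append(0)
            continue
        scores.append(amas_score_column(residues, has_gap))
    return tuple(scores)


def al2co_standardized(aln: AlignmentBlock) -> tuple[float, ...]:
    """Standardized entropy conservation per column (higher = more conserved).

    Column entropy S = −Σ f ln f over non-gap frequencies (renormalized over
    residues present); z = (mean(S) − S) / sd(S). If all columns share one
    entropy the z-scores are undefined and reported as 0 with a warning.
    """
    entropies = []
    for counts in _column_counts(aln):
        residue_counts = {ch: c for ch, c in counts.items() if ch != "-"}
        total = sum(residue_counts.values())
        if total == 0:
            entropies.append(0.0)
            continue
        s = -sum(
            (c / total) * math.log(c / total) for c in residue_counts.values()
        )
        entropies.append(s)
    arr = np.asarray(entropies)
    sd = float(arr.std())
    if sd == 0.0:
        warnings.warn(
            "all columns have identical entropy; conservation z-scores undefined, "
            "reporting 0",
            stacklevel=2,
        )
        return tuple(0.0 for _ in entropies)
    mean = float(arr.mean())
    return tuple(float((mean - s) / sd) for s in arr)


def profile(aln: AlignmentBlock) -> ConservationProfile:
    """Full conservation profile of an alignment."""
    freqs, consensus = consensus_logo(aln)
    return ConservationProfile(
        frequencies=freqs,
        consensus=consensus,
        amas_scores=amas_conservation(aln),
        z_scores=al2co_standardized(aln),
    )


def group_consensus(
    aln: AlignmentBlock, group_labels: dict[str, str]
) -> dict[str, ConservationProfile]:
    """Per-group conservation profiles (row subsets, all columns retained)."""
    missing = [i for i in aln.ids if i not in group_labels]
    if missing:
        raise KeyError(f"alignment rows without a group label: {missing}")
    groups: dict[str, list[str]] = {}
    for sid in aln.ids:
        groups.setdefault(group_labels[sid], []).append(sid)
    return {g: profile(aln.subset(ids)) for g, ids in groups.items()}
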