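"""Percent-identity computation, best-human-match classification, and a
neighbor-joining utility.

Identity between two family members is computed over their homologous
regions: sequences are (optionally) restricted to per-sequence spans, pairs
are globally aligned under BLOSUM62 with affine gaps, and identity is the
fraction of identical residues among columns where both rows carry a
residue. The denominator choice makes identity symmetric and stable under
span restriction; because the original viewer's convention is undocumented,
recomputed values should be read with a ±2-point tolerance.

The tree builder is plain neighbor joining — a deliberately documented
surrogate for likelihood phylogenetics, exact only on additive distance
matrices. Output metadata labels it "NJ" to prevent silent misuse.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .seqio import HUMAN_COLUMNS, AlignmentBlock, ProteinRecord

__all__ = [
    "Span",
    "IdentityMatrix",
    "GroupSummary",
    "align_pair",
    "percent_identity",
    "common_region",
    "identity_matrix",
    "identity_matrix_from_alignment",
    "best_match",
    "flag_group4a",
    "summarize_groups",
    "nj_tree",
]


@dataclass(frozen=True)
class Span:
    """1-based inclusive residue span on a named sequence."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid span ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def slice(self, sequence: str) -> str:
        if self.end > len(sequence):
            raise ValueError(
                f"span ({self.start}, {self.end}) exceeds sequence length "
                f"{len(sequence)}"
            )
        return sequence[self.start - 1 : self.end]


def _aligner(substitution_table: str, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(substitution_table)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair(
    a: ProteinRecord,
    b: ProteinRecord,
    substitution_table: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> tuple[str, str]:
    """Globally align two sequences; returns the two gapped rows.

    End-to-end alignment maximising the affine-gap score (a gap of length k
    costs gap_open + (k-1)*gap_extend). The first alignment of the
    deterministic optimal-alignment enumeration is returned.
    """
    aligner = _aligner(substitution_table, gap_open, gap_extend)
    aln = aligner.align(a.sequence, b.sequence)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    return row_a, row_b


def alignment_score(
    a: ProteinRecord,
    b: ProteinRecord,
    substitution_table: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> float:
    """Optimal global affine-gap alignment score for a pair."""
    aligner = _aligner(substitution_table, gap_open, gap_extend)
    return float(aligner.score(a.sequence, b.sequence))


def percent_identity(row_a: str, row_b: str) -> float:
    """Percent identical residues over columns where both rows are non-gap.

    Returns NaN when no column has residues in both rows (undefined).
    """
    if len(row_a) != len(row_b):
        raise ValueError(
            f"gapped rows differ in length ({len(row_a)} vs {len(row_b)})"
        )
    shared = ident = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            shared += 1
            if ca == cb:
                ident += 1
    if shared == 0:
        return math.nan
    return 100.0 * ident / shared


def common_region(spans: list[Span] | dict[str, Span]) -> Span:
    """Intersection of homologous-region spans on a shared reference frame.

    The common region runs from the maximum start to the minimum end; an
    empty intersection is an error.
    """
    items = list(spans.values()) if isinstance(spans, dict) else list(spans)
    if not items:
        raise ValueError("no spans given")
    start = max(s.start for s in items)
    end = min(s.end for s in items)
    if start > end:
        raise ValueError(f"no common region: intersection ({start}, {end}) is empty")
    return Span(start, end)


@dataclass(frozen=True)
class IdentityMatrix:
    """Percent identities of row sequences against column sequences."""

    values: pd.DataFrame  # index: row accessions, columns: reference accessions

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and ((finite < 0) | (finite > 100)).any():
            raise ValueError("identities must lie in [0, 100]")

    @property
    def row_ids(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def col_ids(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def cell(self, row_id: str, col_id: str) -> float:
        return float(self.values.at[row_id, col_id])

    def to_tsv(self, path) -> None:
        self.values.round(1).to_csv(path, sep="\t", float_format="%.1f")


def identity_matrix(
    records: list[ProteinRecord],
    refs: list[ProteinRecord],
    spans: dict[str, Span] | None = None,
    substitution_table: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 1.0,
) -> IdentityMatrix:
    """Pairwise-alignment identity matrix over (span-restricted) sequences.

    Cells whose alignment or identity is undefined are NaN (flagged missing),
    never an exception for the whole matrix.
    """
    def restricted(rec: ProteinRecord) -> ProteinRecord:
        if spans and rec.id in spans:
            return ProteinRecord(rec.id, spans[rec.id].slice(rec.sequence))
        return rec

    rows = {}
    for rec in records:
        r = restricted(rec)
        row = {}
        for ref in refs:
            try:
                ra, rb = align_pair(
                    r, restricted(ref), substitution_table, gap_open, gap_extend
                )
                row[ref.id] = percent_identity(ra, rb)
            except (ValueError, IndexError):
                row[ref.id] = math.nan
        rows[rec.id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.reindex(index=[r.id for r in records], columns=[r.id for r in refs])
    return IdentityMatrix(values=df)


def identity_matrix_from_alignment(
    aln: AlignmentBlock, row_ids: list[str], col_ids: list[str]
) -> IdentityMatrix:
    """Identity matrix by extracting row pairs from a joint multiple alignment
    (the protocol that pairs every family member within one MSA)."""
    data = {
        rid: {cid: percent_identity(aln.row(rid), aln.row(cid)) for cid in col_ids}
        for rid in row_ids
    }
    df = pd.DataFrame.from_dict(data, orient="index").reindex(
        index=row_ids, columns=col_ids
    )
    return IdentityMatrix(values=df)


def best_match(matrix: IdentityMatrix, row_id: str) -> tuple[str, float]:
    """The column with the highest identity for one row.

    Ties break by the fixed human column order (Dcytb, Lcytb, CGcytb,
    TScytb, CYB561D1, SDR2) when the columns are the human references, else
    by the matrix's own column order.
    """
    if row_id not in matrix.values.index:
        raise KeyError(f"row {row_id!r} not in matrix")
    row = matrix.values.loc[row_id]
    order = [c for c in HUMAN_COLUMNS if c in row.index] or list(row.index)
    best_col, best_val = None, -math.inf
    for col in order:
        val = row[col]
        if not math.isnan(val) and val > best_val:
            best_col, best_val = col, float(val)
    if best_col is None:
        raise ValueError(f"row {row_id!r} has no non-missing cells")
    return best_col, best_val


def flag_group4a(
    human_matrix: IdentityMatrix,
    dm_matrix: IdentityMatrix,
    exclude_self: bool = True,
) -> dict[str, bool]:
    """Flag rows closer to a human reference than to any D. melanogaster
    paralog (strict inequality of row maxima). Self-comparisons in the
    D. melanogaster matrix are excluded."""
    flags = {}
    for rid in human_matrix.row_ids:
        if rid not in dm_matrix.values.index:
            raise KeyError(f"row {rid!r} missing from the D. melanogaster matrix")
        h = human_matrix.values.loc[rid]
        d = dm_matrix.values.loc[rid]
        if exclude_self:
            d = d.drop(index=rid, errors="ignore")
        h_best = np.nanmax(h.to_numpy(dtype=float))
        d_best = np.nanmax(d.to_numpy(dtype=float))
        flags[rid] = bool(h_best > d_best)
    return flags


@dataclass(frozen=True)
class GroupSummary:
    """Per-row best matches rolled up per group."""

    best: dict[str, tuple[str, float]]  # row -> (col, value)
    counts: dict[str, dict[str, int]]  # group -> best-match column -> count
    ranges: dict[str, tuple[float, float]]  # group -> (min, max) of best values
    group4a: dict[str, bool] = field(default_factory=dict)


def summarize_groups(
    matrix: IdentityMatrix,
    group_labels: dict[str, str],
    group4a: dict[str, bool] | None = None,
) -> GroupSummary:
    """Best-match counts and best-value ranges per group label."""
    missing = [r for r in matrix.row_ids if r not in group_labels]
    if missing:
        raise KeyError(f"rows without a group label: {missing}")
    best = {rid: best_match(matrix, rid) for rid in matrix.row_ids}
    counts: dict[str, dict[str, int]] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for rid, (col, val) in best.items():
        g = group_labels[rid]
        counts.setdefault(g, {}).setdefault(col, 0)
        counts[g][col] += 1
        lo, hi = ranges.get(g, (math.inf, -math.inf))
        ranges[g] = (min(lo, val), max(hi, val))
    return GroupSummary(best=best, counts=counts, ranges=ranges, group4a=group4a or {})


def nj_tree(distances: pd.DataFrame | np.ndarray, labels: list[str] | None = None) -> str:
    """Neighbor-joining tree from a square symmetric distance matrix, as Newick.

    Deterministic: joins the pair minimising the Q-criterion, ties broken by
    the sorted label pair. Negative branch lengths are clamped to zero with a
    warning. Exact on additive matrices.
    """
    if isinstance(distances, pd.DataFrame):
        labels = list(distances.index)
        d = distances.to_numpy(dtype=float)
    else:
        d = np.asarray(distances, dtype=float)
        if labels is None:
            labels = [f"t{i}" for i in range(d.shape[0])]
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise ValueError("distance matrix diagonal must be zero")

    def fmt(length: float) -> float:
        if length < 0:
            if length < -1e-9:
                warnings.warn(
                    f"negative NJ branch length {length:.4g} clamped to 0",
                    stacklevel=3,
                )
            return 0.0
        return length

    d = d.copy()
    nodes = [f"{lab}" for lab in labels]  # newick fragment per active node
    names = list(labels)  # tie-break keys

    while len(nodes) > 3:
        m = d.shape[0]
        totals = d.sum(axis=1)
        best_pair, best_q, best_key = None, math.inf, None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - totals[i] - totals[j]
                key = tuple(sorted((names[i], names[j])))
                if q < best_q - 1e-12 or (
                    abs(q - best_q) <= 1e-12 and (best_key is None or key < best_key)
                ):
                    best_pair, best_q, best_key = (i, j), q, key
        i, j = best_pair
        li = 0.5 * d[i, j] + (totals[i] - totals[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = fmt(li), fmt(lj)
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        new_name = min(names[i], names[j])
        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d_new = np.zeros((len(keep) + 1, len(keep) + 1))
        d_new[:-1, :-1] = d[np.ix_(keep, keep)]
        d_new[-1, :-1] = d_new[:-1, -1] = du[keep]
        d = d_new
        nodes = [nodes[k] for k in keep] + [new]
        names = [names[k] for k in keep] + [new_name]

    # final 3-node star: closed-form branch lengths
    (a, b, c) = (0, 1, 2)
    la = fmt(0.5 * (d[a, b] + d[a, c] - d[b, c]))
    lb = fmt(0.5 * (d[a, b] + d[b, c] - d[a, c]))
    lc = fmt(0.5 * (d[a, c] + d[b, c] - d[a, b]))
    return (
        f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},{nodes[c]}:{lc:.10g});"
    )
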