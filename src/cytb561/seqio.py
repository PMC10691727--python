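"""Readers and writers for the formats the annotation pipeline touches.

FASTA and alignment parsing go through Biopython; PDB parsing goes through
gemmi. The module's own job is validation (sequence alphabet, unique ids,
rectangular alignments) and the lightweight containers the rest of the
package operates on, plus the parser for the bundled human-vs-insect
percent-identity fixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import AlignIO, SeqIO

__all__ = [
    "AMINO_ACIDS",
    "ParseError",
    "ProteinRecord",
    "AlignmentBlock",
    "SimilarityFixture",
    "Atom",
    "StructureModel",
    "read_sequences",
    "write_sequences",
    "read_alignment",
    "write_alignment",
    "read_similarity_fixture",
    "load_table1_fixture",
    "read_structure",
    "HUMAN_COLUMNS",
]

#: 20 standard residues plus the ambiguity/rare codes accepted on input.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
EXTENDED_CODES = AMINO_ACIDS | frozenset("XBZU")

#: Fixed human reference column order (also the best-match tie-break order).
HUMAN_COLUMNS = ("Dcytb", "Lcytb", "CGcytb", "TScytb", "CYB561D1", "SDR2")

#: Printed per-group row counts of the bundled fixture (Group 4 = 4A + 4B).
FIXTURE_GROUP_SIZES = {"CG1275": 11, "Nemy": 8, "CG8399": 10, "Group 4": 25}


class ParseError(ValueError):
    """Raised when an input file violates a format or content contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """One identified protein sequence.

    ``sequence`` is an upper-case amino-acid string; gap characters and
    whitespace are a hard error here, not silently removed — a gapped
    "sequence" is an alignment row and belongs in :class:`AlignmentBlock`.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("record has an empty id")
        if not self.sequence:
            raise ParseError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - EXTENDED_CODES
        if bad:
            raise ParseError(
                f"record {self.id!r} contains illegal characters: "
                + ", ".join(sorted(map(repr, bad)))
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, index: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= index <= len(self.sequence):
            raise IndexError(f"position {index} outside 1..{len(self.sequence)}")
        return self.sequence[index - 1]


@dataclass(frozen=True)
class AlignmentBlock:
    """A rectangular multiple alignment with '-' gaps.

    '.' gaps from mixed dialects are normalised to '-' on construction.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ParseError("alignment has no rows")
        if len(self.ids) != len(self.rows):
            raise ParseError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if list(self.ids).count(i) > 1})
            raise ParseError(f"duplicate alignment ids: {', '.join(dupes)}")
        object.__setattr__(
            self, "rows", tuple(r.upper().replace(".", "-") for r in self.rows)
        )
        widths = {len(r) for r in self.rows}
        if len(widths) != 1:
            raise ParseError(f"ragged alignment rows (widths {sorted(widths)})")
        for rid, row in zip(self.ids, self.rows):
            bad = set(row) - EXTENDED_CODES - {"-"}
            if bad:
                raise ParseError(
                    f"alignment row {rid!r} contains illegal characters: "
                    + ", ".join(sorted(map(repr, bad)))
                )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"no alignment row with id {seq_id!r}") from None

    def ungapped(self, seq_id: str) -> ProteinRecord:
        """The source sequence of one row, gaps removed."""
        return ProteinRecord(id=seq_id, sequence=self.row(seq_id).replace("-", ""))

    def column(self, index: int) -> str:
        """Alignment column at a 1-based index, one character per row."""
        if not 1 <= index <= self.n_columns:
            raise IndexError(f"column {index} outside 1..{self.n_columns}")
        return "".join(r[index - 1] for r in self.rows)

    def subset(self, ids: Sequence[str]) -> "AlignmentBlock":
        """Row subset in the given order; all columns retained."""
        return AlignmentBlock(tuple(ids), tuple(self.row(i) for i in ids))

    def residue_index(self, seq_id: str, column: int) -> int | None:
        """1-based ungapped residue index at a column, or None if gapped."""
        row = self.row(seq_id)
        if not 1 <= column <= self.n_columns:
            raise IndexError(f"column {column} outside 1..{self.n_columns}")
        if row[column - 1] == "-":
            return None
        return column - row[:column].count("-")


def read_sequences(path: str | Path, format: str = "fasta") -> list[ProteinRecord]:
    """Read protein sequences from FASTA, enforcing unique ids and a clean
    alphabet. Gap characters in the input are an error."""
    if format != "fasta":
        raise ParseError(f"unsupported sequence format {format!r}")
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if any(g in seq for g in "-. \t"):
            raise ParseError(f"record {rec.id!r} contains gap or whitespace characters")
        if rec.id in seen:
            raise ParseError(f"duplicate sequence id {rec.id!r} in {path.name}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return records


def write_sequences(records: Iterable[ProteinRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


_DIALECTS = {"aligned-fasta": "fasta", "clustal": "clustal"}


def read_alignment(path: str | Path, dialect: str = "aligned-fasta") -> AlignmentBlock:
    """Read a multiple alignment in aligned-FASTA or Clustal dialect."""
    if dialect not in _DIALECTS:
        raise ParseError(
            f"unknown alignment dialect {dialect!r}; expected one of {sorted(_DIALECTS)}"
        )
    try:
        aln = AlignIO.read(str(path), _DIALECTS[dialect])
    except ValueError as exc:
        raise ParseError(f"cannot parse {path} as {dialect}: {exc}") from exc
    return AlignmentBlock(
        ids=tuple(rec.id for rec in aln),
        rows=tuple(str(rec.seq).upper() for rec in aln),
    )


def write_alignment(
    aln: AlignmentBlock, path: str | Path, dialect: str = "aligned-fasta"
) -> None:
    if dialect not in _DIALECTS:
        raise ParseError(f"unknown alignment dialect {dialect!r}")
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=rid, description="") for rid, row in zip(aln.ids, aln.rows)]
    )
    AlignIO.write(msa, str(path), _DIALECTS[dialect])


@dataclass(frozen=True)
class SimilarityFixture:
    """The bundled insect-vs-human percent-identity table.

    54 insect rows by 6 human reference columns in fixed order, with a group
    label and species code per row. Best-match cells are not stored; they are
    recomputed by the classifier.
    """

    matrix: pd.DataFrame  # index: accession, columns: HUMAN_COLUMNS
    groups: dict[str, str] = field(default_factory=dict)  # accession -> group
    species: dict[str, str] = field(default_factory=dict)  # accession -> code

    def __post_init__(self) -> None:
        if tuple(self.matrix.columns) != HUMAN_COLUMNS:
            raise ParseError(
                f"fixture columns must be {HUMAN_COLUMNS}, got {tuple(self.matrix.columns)}"
            )
        if len(self.matrix) != 54:
            raise ParseError(f"fixture must have 54 rows, got {len(self.matrix)}")
        vals = self.matrix.to_numpy()
        if not ((vals >= 0) & (vals <= 100)).all():
            raise ParseError("fixture values must lie in [0, 100]")

    def lookup(self, accession: str, human: str) -> float:
        """Percent identity for one (insect accession, human column) cell."""
        return float(self.matrix.at[accession, human])

    def group_of(self, accession: str) -> str:
        return self.groups[accession]

    @property
    def accessions(self) -> tuple[str, ...]:
        return tuple(self.matrix.index)


def read_similarity_fixture(path: str | Path) -> SimilarityFixture:
    """Parse a fixture TSV: accession, species, group, then the 6 human columns."""
    df = pd.read_csv(path, sep="\t", dtype={"accession": str})
    expected = ["accession", "species", "group", *HUMAN_COLUMNS]
    if list(df.columns) != expected:
        raise ParseError(
            f"fixture header must be {expected}, got {list(df.columns)}"
        )
    if df["accession"].duplicated().any():
        raise ParseError("fixture contains duplicate accessions")
    matrix = df.set_index("accession")[list(HUMAN_COLUMNS)].astype(float)
    if matrix.isna().any().any():
        raise ParseError("fixture contains non-numeric identity cells")
    return SimilarityFixture(
        matrix=matrix,
        groups=dict(zip(df["accession"], df["group"])),
        species=dict(zip(df["accession"], df["species"])),
    )


def load_table1_fixture() -> SimilarityFixture:
    """The packaged 54-sequence insect-vs-human identity table."""
    with resources.as_file(
        resources.files("cytb561.data") / "table1_identity.tsv"
    ) as p:
        return read_similarity_fixture(p)


@dataclass(frozen=True)
class Atom:
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    is_hetero: bool = False

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.residue_name)


@dataclass(frozen=True)
class StructureModel:
    """Flat atom list from a PDB file, residue numbering preserved."""

    atoms: tuple[Atom, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ParseError("structure contains no atoms")
        for a in self.atoms:
            if not all(math.isfinite(v) for v in a.xyz):
                raise ParseError(
                    f"non-finite coordinates for atom {a.atom_name} "
                    f"{a.residue_name}{a.residue_number}"
                )
            if not a.element:
                raise ParseError(
                    f"element not assignable for atom {a.atom_name} "
                    f"{a.residue_name}{a.residue_number}"
                )

    def ligand_atoms(self, names: Iterable[str] | None = None) -> tuple[Atom, ...]:
        """HETATM records, optionally restricted to given residue names."""
        wanted = {n.upper() for n in names} if names is not None else None
        return tuple(
            a
            for a in self.atoms
            if a.is_hetero and (wanted is None or a.residue_name in wanted)
        )

    def protein_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if not a.is_hetero)

    def select(self, **criteria) -> tuple[Atom, ...]:
        """Atoms matching simple equality criteria (chain=, residue_name=...)."""
        out = self.atoms
        for key, val in criteria.items():
            vals = {val} if isinstance(val, (str, int)) else set(val)
            out = tuple(a for a in out if getattr(a, key) in vals)
        return out


def read_structure(path: str | Path) -> StructureModel:
    """Read ATOM/HETATM records from a PDB file via gemmi."""
    import gemmi

    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse PDB file {path}: {exc}") from exc
    atoms: list[Atom] = []
    if len(st) == 0:
        raise ParseError(f"structure {path} has no models")
    model = st[0]
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for at in res:
                el = at.element.name.upper()
                atoms.append(
                    Atom(
                        chain=chain.name,
                        residue_number=res.seqid.num,
                        residue_name=res.name.strip().upper(),
                        atom_name=at.name,
                        element=el,
                        x=at.pos.x,
                        y=at.pos.y,
                        z=at.pos.z,
                        occupancy=at.occ,
                        is_hetero=het,
                    )
                )
    return StructureModel(atoms=tuple(atoms))
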