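"""Synthetic cytochrome-b561 families and toy structures with full ground truth.

The generator emulates the family structure the annotation pipeline is built
for: six-transmembrane-helix proteins whose four heme histidines sit at
fixed inter-anchor spacings (default 36/34/39, mirroring the reference
ferric reductase's His50/86/120/159), with group-specific conserved residues
at anchor-relative offsets, loop-confined indels, and optionally planted
motifs with per-sequence on/off ground truth. Because substitutions are
uniform over the 19 alternative residues and indels never touch segments or
anchors, expected identities and recovery rates stay closed-form and every
recorded feature is literally present in the emitted sequences.

Families are emitted together with their *true* multiple alignment (each
insertion is its own column), so anchor detection and conservation scoring
can be tested without running an external aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anchors import KYTE_DOOLITTLE, RelPos
from .motifs import MotifSpec
from .seqio import AlignmentBlock, ProteinRecord

__all__ = [
    "SpecError",
    "ConservedSite",
    "PlantedMotif",
    "FamilySpec",
    "GroundTruth",
    "SequenceTruth",
    "make_template",
    "evolve_family",
    "simulate_family",
    "make_helix_bundle",
    "write_toy_pdb",
    "default_insect_spec",
    "cg8399_like_spec",
    "cg1275_nemy_spec",
    "DCYTB_SITE_CATALOG",
]

_TM_POOL = ("I", "V")
_TM_WEIGHTS = (0.6, 0.4)
_LOOP_POOL = ("S", "T", "G", "N", "Q", "D", "E", "K", "R", "P")
_LOOP_WEIGHTS = (0.22, 0.22, 0.18, 0.08, 0.05, 0.07, 0.07, 0.06, 0.03, 0.02)
#: mildly polar helix-cap residues flanking each loop, so windowed
#: hydropathy resolves adjacent helices cleanly
_CAP_POOL = ("G", "S", "T")
_CAP_LEN = 5
_RESIDUES = tuple("ACDEFGHIKLMNPQRSTVWY")


class SpecError(ValueError):
    """Raised when a family specification is internally inconsistent."""


@dataclass(frozen=True)
class ConservedSite:
    """A group-specific conserved residue at an anchor-relative offset.

    Groups listed in ``on_groups`` carry ``residue`` at the site (protected
    from substitution); in all other groups the site is scrambled per
    sequence, so group consensus logos differ at it. ``on_groups`` of None
    means on in every group.
    """

    position: str  # RelPos text, e.g. "H1+20"
    residue: str
    on_groups: frozenset[str] | None = None

    def is_on(self, group: str) -> bool:
        return self.on_groups is None or group in self.on_groups


@dataclass(frozen=True)
class PlantedMotif:
    """A motif written into a named region with per-sequence probability."""

    spec: MotifSpec
    region: str  # H2-H3 loop | H1-H2 loop | C-terminal tail | N-terminal region
    probability: float
    groups: frozenset[str] | None = None  # None = all groups

    def applies(self, group: str) -> bool:
        return self.groups is None or group in self.groups


#: The reference ferric reductase's substrate/heme residue catalog, used as
#: the planted conservation pattern of Dcytb-like groups.
DCYTB_SITE_CATALOG: tuple[tuple[str, str], ...] = (
    ("H1-3", "F"), ("H1+20", "R"),
    ("H2-7", "K"), ("H2-3", "K"), ("H2+21", "N"), ("H2+22", "H"),
    ("H3-5", "N"), ("H3-4", "M"), ("H3-3", "Y"), ("H3-2", "S"),
    ("H3+2", "W"), ("H3+4", "G"), ("H3+14", "Q"), ("H3+18", "G"),
    ("H3+22", "F"),
    ("H4-7", "R"), ("H4-3", "M"), ("H4+4", "G"), ("H4+18", "G"),
    ("H4+21", "E"), ("H4+25", "F"),
)

#: Nemy's hallmark double cysteines in the two cytoplasmic core loops.
NEMY_CYS_SITES: tuple[tuple[str, str], ...] = (
    ("H2-11", "C"), ("H2-10", "C"), ("H4-11", "C"), ("H4-10", "C"),
)


@dataclass(frozen=True)
class FamilySpec:
    """Everything needed to generate one synthetic family deterministically."""

    groups: tuple[tuple[str, int], ...] = (
        ("CG1275", 11), ("Nemy", 8), ("Group 4A", 7), ("Group 4B", 18)
    )
    architecture: str = "single-domain"  # or "cybdom"
    anchor_offsets: tuple[int, int, int] = (36, 34, 39)
    conserved_sites: tuple[ConservedSite, ...] = ()
    planted_motifs: tuple[PlantedMotif, ...] = ()
    site_mutation_rate: float = 0.10
    loop_indel_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("single-domain", "cybdom"):
            raise SpecError(f"unknown architecture {self.architecture!r}")
        if any(s <= 0 for s in self.anchor_offsets):
            raise SpecError("anchor spacings must be positive")
        for rate in (self.site_mutation_rate, self.loop_indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise SpecError(f"rate {rate} outside [0, 1]")
        for pm in self.planted_motifs:
            if not 0.0 <= pm.probability <= 1.0:
                raise SpecError(f"motif probability {pm.probability} outside [0, 1]")

    @property
    def n_sequences(self) -> int:
        return sum(n for _, n in self.groups)


def default_insect_spec(seed: int = 0, **overrides) -> FamilySpec:
    """The default single-domain insect family: Dcytb-like conservation in
    CG1275/Nemy, cysteine doublets in Nemy, the KXXXXKXH loop motif in 6/7
    of Group 4A, and a C-terminal EDXXLL signal in CG1275."""
    dcytb_on = frozenset({"CG1275", "Nemy"})
    sites = tuple(
        ConservedSite(pos, res, dcytb_on) for pos, res in DCYTB_SITE_CATALOG
    ) + tuple(
        ConservedSite(pos, res, frozenset({"Nemy"})) for pos, res in NEMY_CYS_SITES
    )
    motifs = (
        PlantedMotif(
            MotifSpec.parse("KXXXXKXH", "KXXXXKXH"),
            "H2-H3 loop", 6 / 7, frozenset({"Group 4A"}),
        ),
        PlantedMotif(
            MotifSpec.parse("EDXXLL", "EDXXLL"),
            "C-terminal tail", 1.0, frozenset({"CG1275"}),
        ),
    )
    return FamilySpec(
        conserved_sites=sites, planted_motifs=motifs, seed=seed, **overrides
    )


def cg8399_like_spec(seed: int = 0, n_sequences: int = 10) -> FamilySpec:
    """A CYBDOM family: extracellular N-terminal region housing the DOMON
    aspartate pocket, core register TM1-TM4, nonpolar H2+22 and glutamate
    H2+21 (the residues that rule out a Dcytb-style non-cytoplasmic site).

    Only loop-resident or hydrophobic sites are planted so the helices stay
    recoverable by windowed hydropathy; the DOMON heme histidine, which in a
    full-length alignment would be a fifth perfectly conserved His column,
    is exercised via dedicated DOMON-domain alignments instead.
    """
    sites = (
        ConservedSite("H1+20", "R"),
        ConservedSite("H2+21", "E"),
        ConservedSite("H2+22", "L"),
        ConservedSite("H3+4", "G"),
        ConservedSite("H4-7", "R"),
        ConservedSite("H4+4", "G"),
    )
    motifs = (
        PlantedMotif(
            MotifSpec.parse("SXDXXMGXD", "SXDXXMGXD"),
            "N-terminal region", 1.0, None,
        ),
    )
    return FamilySpec(
        groups=(("CG8399", n_sequences),),
        architecture="cybdom",
        conserved_sites=sites,
        planted_motifs=motifs,
        seed=seed,
    )


def cg1275_nemy_spec(seed: int = 0, n_per_group: int = 6) -> FamilySpec:
    """A light two-group single-domain family for topology-dependent checks.

    All planted sites are loop-resident, so the six helices survive
    hydropathy prediction: CG1275 sequences carry the C-terminal EDXXLL
    sorting signal, Nemy sequences the double cysteines in both cytoplasmic
    core loops, and both share the cytoplasmic ascorbate-binding basics.
    """
    shared = frozenset({"CG1275", "Nemy"})
    sites = (
        ConservedSite("H1+20", "R", shared),
        ConservedSite("H2-7", "K", shared),
        ConservedSite("H2-3", "K", shared),
        ConservedSite("H4-7", "R", shared),
    ) + tuple(
        ConservedSite(pos, res, frozenset({"Nemy"})) for pos, res in NEMY_CYS_SITES
    )
    motifs = (
        PlantedMotif(
            MotifSpec.parse("EDXXLL", "EDXXLL"),
            "C-terminal tail", 1.0, frozenset({"CG1275"}),
        ),
    )
    return FamilySpec(
        groups=(("CG1275", n_per_group), ("Nemy", n_per_group)),
        conserved_sites=sites,
        planted_motifs=motifs,
        site_mutation_rate=0.04,
        loop_indel_rate=0.05,
        seed=seed,
    )


@dataclass
class SequenceTruth:
    """Ground truth for one emitted sequence (1-based, post-indel indices)."""

    seq_id: str
    group: str
    anchors: tuple[int, int, int, int]
    tm_segments: tuple[tuple[int, int], ...]
    motifs: tuple[tuple[str, int, int, str], ...]  # (name, start, end, region)
    mutated_positions: tuple[int, ...]


@dataclass
class GroundTruth:
    """Template layout plus per-sequence truth and the true alignment."""

    architecture: str
    template_anchors: tuple[int, int, int, int]
    template_segments: tuple[tuple[int, int], ...]
    template_length: int
    sequences: dict[str, SequenceTruth] = field(default_factory=dict)
    alignment: AlignmentBlock | None = None


def _rng(spec: FamilySpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, stream])


def _segment_mean_kd(seq: list[str], span: tuple[int, int]) -> float:
    vals = [KYTE_DOOLITTLE[c] for c in seq[span[0] - 1 : span[1]]]
    return sum(vals) / len(vals)


def make_template(spec: FamilySpec) -> tuple[ProteinRecord, GroundTruth]:
    """Deterministically build the family template.

    Six hydrophobic segments (length 21–22, windowed-hydropathy
    recoverable), hydrophilic loops of at least 10 residues, the four
    anchor histidines planted 5–7 residues into the architecture-appropriate
    segments at the spec's spacings, and every conserved site written at its
    resolved offset.
    """
    rng = _rng(spec, 0)
    core_first = 1 if spec.architecture == "cybdom" else 2

    # one anchor depth for all four histidines keeps the loop arithmetic
    # exact; the middle core segment length is pinned by the H2-H3 spacing
    h = int(rng.integers(5, 7))
    h_off = [h, h, h, h]
    t_len = [int(rng.integers(22, 24)) for _ in range(6)]
    min_loop = 12
    # inter-core loops are fixed by the anchor spacings
    core_loops = []
    for k, spacing in enumerate(spec.anchor_offsets):
        seg_idx = core_first - 1 + k
        max_seg = spacing - min_loop - h_off[k + 1] + h_off[k]
        if max_seg < 19:
            raise SpecError(
                f"anchor spacing {spacing} too tight for a >=19-residue "
                "segment with >=12-residue loops"
            )
        t_len[seg_idx] = min(t_len[seg_idx], max_seg)
        core_loops.append(spacing - t_len[seg_idx] - h_off[k + 1] + h_off[k])

    if spec.architecture == "cybdom":
        n_term = int(rng.integers(45, 61))
    else:
        n_term = int(rng.integers(12, 19))
    other_loops = [int(rng.integers(12, 19)) for _ in range(2)]  # non-core loops
    tail = int(rng.integers(18, 31))

    # assemble region list: (kind, length)
    regions: list[tuple[str, int]] = [("loop", n_term)]
    loop_iter = iter(other_loops)
    core_loop_iter = iter(core_loops)
    for seg in range(6):
        regions.append(("tm", t_len[seg]))
        if seg < 5:
            in_core = core_first - 1 <= seg < core_first + 2
            regions.append(("loop", next(core_loop_iter) if in_core else next(loop_iter)))
    regions.append(("loop", tail))

    def loop_residues(length: int) -> list[str]:
        cap = min(_CAP_LEN, length // 2)
        inner = length - 2 * cap
        return (
            list(rng.choice(_CAP_POOL, size=cap))
            + list(rng.choice(_LOOP_POOL, size=inner, p=_LOOP_WEIGHTS))
            + list(rng.choice(_CAP_POOL, size=cap))
        )

    seq: list[str] = []
    segments: list[tuple[int, int]] = []
    pos = 1
    for kind, length in regions:
        if kind == "tm":
            segments.append((pos, pos + length - 1))
            seq.extend(rng.choice(_TM_POOL, size=length, p=_TM_WEIGHTS))
        else:
            seq.extend(loop_residues(length))
        pos += length

    anchors = tuple(
        segments[core_first - 1 + k][0] + h_off[k] for k in range(4)
    )
    for a in anchors:
        seq[a - 1] = "H"

    # resolve conserved sites against the template anchors
    site_index: dict[int, ConservedSite] = {}
    collisions = []
    for site in spec.conserved_sites:
        rel = RelPos.parse(site.position)
        idx = anchors["H1 H2 H3 H4".split().index(rel.anchor)] + rel.offset
        if not 1 <= idx <= len(seq):
            raise SpecError(f"conserved site {site.position} leaves the template")
        if idx in set(anchors) or idx in site_index:
            collisions.append(site.position)
            continue
        site_index[idx] = site
        seq[idx - 1] = site.residue
    if collisions:
        raise SpecError(
            "conserved sites collide with anchors or each other: "
            + ", ".join(collisions)
        )

    # keep every segment comfortably hydrophobic despite planted polar sites
    for span in segments:
        guard = 0
        while _segment_mean_kd(seq, span) < 2.0 and guard < 50:
            free = [
                i for i in range(span[0], span[1] + 1)
                if i not in site_index and i not in anchors and seq[i - 1] not in ("I",)
            ]
            if not free:
                break
            seq[free[0] - 1] = "I"
            guard += 1

    template = ProteinRecord(id="template", sequence="".join(seq))
    truth = GroundTruth(
        architecture=spec.architecture,
        template_anchors=anchors,
        template_segments=tuple(segments),
        template_length=len(seq),
    )
    return template, truth


def _resolve_region(
    spec: FamilySpec,
    truth: GroundTruth,
    region: str,
    motif_len: int,
    rng: np.random.Generator,
) -> int:
    """Template start index for a planted motif in a named region."""
    anchors = truth.template_anchors
    segments = truth.template_segments
    core_first = 1 if truth.architecture == "cybdom" else 2
    if region == "H2-H3 loop":
        # canonical register: the motif's last residue lands at H3-5
        start = anchors[2] - 5 - motif_len + 1
        if start <= anchors[1]:
            raise SpecError(f"motif of length {motif_len} does not fit H2-H3 loop")
        return start
    if region == "H1-H2 loop":
        seg = segments[core_first - 1]
        return seg[1] + 2
    if region == "C-terminal tail":
        tail_start = segments[-1][1] + 1
        slack = truth.template_length - motif_len - tail_start - 1
        if slack < 0:
            raise SpecError("motif does not fit the C-terminal tail")
        return tail_start + 2 + int(rng.integers(0, max(1, slack - 2)))
    if region == "N-terminal region":
        limit = segments[0][0] - motif_len - 2
        if limit < 3:
            raise SpecError("motif does not fit the N-terminal region")
        return 3
    raise SpecError(f"unknown motif region {region!r}")


def _realize_motif(mspec: MotifSpec, rng: np.random.Generator) -> str:
    out = []
    for constraint in mspec.positions:
        if constraint is None:
            out.append(str(rng.choice(_RESIDUES)))
        else:
            out.append(str(rng.choice(sorted(constraint))))
    return "".join(out)


def evolve_family(
    template: ProteinRecord,
    truth: GroundTruth,
    spec: FamilySpec,
) -> tuple[list[ProteinRecord], GroundTruth]:
    """Evolve the template into the full family.

    Per sequence: conserved sites that are "off" for its group are scrambled,
    planted motifs are written per their probabilities, every unconstrained
    site is substituted with probability ``site_mutation_rate`` (uniform over
    the other 19 residues), and loop indels (length 1–5, never touching
    segments or anchors) are applied with ``loop_indel_rate`` per loop.
    Identical (spec, seed) inputs yield byte-identical output, including the
    true alignment stored on the returned ground truth.
    """
    rng = _rng(spec, 1)
    anchors = truth.template_anchors
    segments = truth.template_segments
    tmpl = template.sequence
    length = len(tmpl)

    site_at: dict[int, ConservedSite] = {}
    for site in spec.conserved_sites:
        rel = RelPos.parse(site.position)
        idx = anchors["H1 H2 H3 H4".split().index(rel.anchor)] + rel.offset
        site_at[idx] = site

    motif_starts = {
        pm: _resolve_region(spec, truth, pm.region, len(pm.spec), rng)
        for pm in spec.planted_motifs
    }

    # Indels are confined to loops outside the anchor/conserved-site span:
    # the inter-anchor core is length-conserved in this family (that is what
    # makes the anchor-relative coordinate system family-wide), so an indel
    # between an anchor and a planted site would silently shift the site's
    # offset. Terminal regions keep their length variability.
    fixed_positions = set(anchors) | set(site_at)
    for start in motif_starts.values():
        fixed_positions.add(start)
    lo_fixed, hi_fixed = min(fixed_positions), max(fixed_positions)
    loops = []
    candidates = [(1, segments[0][0] - 1)] if segments[0][0] > 1 else []
    for (s1, e1), (s2, e2) in zip(segments, segments[1:]):
        if s2 - e1 > 1:
            candidates.append((e1 + 1, s2 - 1))
    if segments[-1][1] < length:
        candidates.append((segments[-1][1] + 1, length))
    for lo, hi in candidates:
        if hi < lo_fixed or lo > hi_fixed:
            loops.append((lo, hi))

    records: list[ProteinRecord] = []
    new_truth = GroundTruth(
        architecture=truth.architecture,
        template_anchors=anchors,
        template_segments=segments,
        template_length=length,
    )
    rows: dict[str, list[tuple[tuple, str]]] = {}
    insert_uid = 0

    for group, n in spec.groups:
        for k in range(n):
            seq_id = f"{group.replace(' ', '')}_{k + 1:02d}"
            # (key, residue) pairs; template column c has key (c, 0)
            cells: list[tuple[tuple, str]] = [((c, 0), tmpl[c - 1]) for c in range(1, length + 1)]
            protected: set[int] = set(anchors)
            mutated_cols: list[int] = []
            planted: list[tuple[str, int, int, str]] = []  # template coords

            # group-specific conserved sites
            for idx, site in site_at.items():
                if site.is_on(group):
                    protected.add(idx)
                else:
                    current = cells[idx - 1][1]
                    choices = [r for r in _RESIDUES if r != current]
                    cells[idx - 1] = (cells[idx - 1][0], str(rng.choice(choices)))

            # planted motifs (overwrite; protected from substitution)
            for pm, start in motif_starts.items():
                if not pm.applies(group):
                    continue
                if rng.random() >= pm.probability:
                    continue
                realization = _realize_motif(pm.spec, rng)
                for j, res in enumerate(realization):
                    cells[start - 1 + j] = (cells[start - 1 + j][0], res)
                    protected.add(start + j)
                planted.append((pm.spec.name, start, start + len(realization) - 1, pm.region))

            # substitutions at unconstrained sites
            for c in range(1, length + 1):
                if c in protected:
                    continue
                if rng.random() < spec.site_mutation_rate:
                    current = cells[c - 1][1]
                    choices = [r for r in _RESIDUES if r != current]
                    cells[c - 1] = (cells[c - 1][0], str(rng.choice(choices)))
                    mutated_cols.append(c)

            # loop indels (template-coordinate bookkeeping via keys)
            drop_cols: set[int] = set()
            inserts: list[tuple[int, str]] = []  # (after template col, residues)
            for lo, hi in loops:
                if rng.random() >= spec.loop_indel_rate:
                    continue
                if rng.random() < 0.5:  # deletion
                    free = [c for c in range(lo, hi + 1) if c not in protected]
                    max_del = min(5, len(free) - 8)
                    if max_del < 1:
                        continue
                    k_del = int(rng.integers(1, max_del + 1))
                    start_at = int(rng.integers(0, len(free) - k_del + 1))
                    drop_cols.update(free[start_at : start_at + k_del])
                else:  # insertion
                    k_ins = int(rng.integers(1, 6))
                    at = int(rng.integers(lo, hi + 1))
                    residues = "".join(rng.choice(_LOOP_POOL, size=k_ins, p=_LOOP_WEIGHTS))
                    inserts.append((at, residues))

            final: list[tuple[tuple, str]] = []
            ins_by_col: dict[int, list[str]] = {}
            for at, residues in inserts:
                ins_by_col.setdefault(at, []).append(residues)
            for key, res in cells:
                col = key[0]
                if col in drop_cols:
                    continue
                final.append((key, res))
                for chunk in ins_by_col.get(col, ()):
                    for r in chunk:
                        insert_uid += 1
                        final.append(((col, insert_uid), r))

            seq_str = "".join(r for _, r in final)
            key_pos = {key: i + 1 for i, (key, _) in enumerate(final)}
            anchor_pos = tuple(key_pos[(a, 0)] for a in anchors)
            seg_pos = tuple(
                (key_pos[(s, 0)], key_pos[(e, 0)]) for s, e in segments
            )
            motif_pos = tuple(
                (name, key_pos[(s, 0)], key_pos[(e, 0)], region)
                for name, s, e, region in planted
            )
            mutated_pos = tuple(
                key_pos[(c, 0)] for c in mutated_cols if (c, 0) in key_pos
            )
            records.append(ProteinRecord(id=seq_id, sequence=seq_str))
            rows[seq_id] = final
            new_truth.sequences[seq_id] = SequenceTruth(
                seq_id=seq_id,
                group=group,
                anchors=anchor_pos,
                tm_segments=seg_pos,
                motifs=motif_pos,
                mutated_positions=mutated_pos,
            )

    # true alignment: union of cell keys over all sequences
    all_keys = sorted({key for cells in rows.values() for key, _ in cells})
    col_of = {key: i for i, key in enumerate(all_keys)}
    aln_rows = []
    for seq_id, cells in rows.items():
        row = ["-"] * len(all_keys)
        for key, res in cells:
            row[col_of[key]] = res
        aln_rows.append("".join(row))
    new_truth.alignment = AlignmentBlock(tuple(rows), tuple(aln_rows))
    return records, new_truth


def simulate_family(spec: FamilySpec) -> tuple[list[ProteinRecord], GroundTruth]:
    """Template + evolution in one call."""
    template, truth = make_template(spec)
    return evolve_family(template, truth, spec)


def make_helix_bundle(
    n_points: int,
    outliers: int = 0,
    displacement: float = 8.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """A Cα helix trace and a rigidly transformed copy with planted outliers.

    Returns (A, B, truth): B is R·A + t with ``outliers`` randomly chosen
    points additionally displaced by ``displacement`` Å; truth records the
    transform and the outlier indices.
    """
    if n_points < 3:
        raise ValueError("need at least 3 points")
    rng = np.random.default_rng(seed)
    # idealized alpha-helix CA trace: rise 1.5 Å, 100 deg per residue, r 2.3 Å
    idx = np.arange(n_points)
    theta = np.deg2rad(100.0) * idx
    a = np.column_stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * idx])

    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-20, 20, size=3)
    b = a @ rot.T + trans
    outlier_idx = tuple(
        int(i) for i in sorted(rng.choice(n_points, size=outliers, replace=False))
    )
    for i in outlier_idx:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        b[i] += displacement * direction
    truth = {"rotation": rot, "translation": trans, "outliers": outlier_idx}
    return a, b, truth


def write_toy_pdb(coords: np.ndarray, path, chain: str = "A") -> None:
    """Serialize a Cα trace as a minimal PDB file (one ALA CA per point)."""
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(np.asarray(coords, dtype=float), start=1):
            fh.write(
                f"ATOM  {i:5d}  CA  ALA {chain}{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
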