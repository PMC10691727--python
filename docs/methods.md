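# Methods

This note documents the models, conventions, and numerical choices behind
the package, and what its synthetic benchmarks do and do not demonstrate.

## The anchor coordinate system

All family-wide residue comparisons run through the four conserved
heme-coordinating histidines. `find_histidine_anchors` scores every
alignment column by its His fraction (gaps count against), keeps columns at
or above `h_min` (default 0.95 — strict conservation is the biological
expectation, but one truncated sequence in a real alignment should not
abort the run), and selects among spacing-feasible quadruples
(consecutive column gaps within [15, 90], bracketing the observed
inter-anchor spacings of 36/34/39 with generous room for loop indels) the
one maximizing summed His fraction, ties broken toward the leftmost
columns. A sequence substituted at an anchor column is mapped "absent" at
that anchor rather than silently mis-anchored.

`to_relative` labels a residue by the nearest anchor in sequence
coordinates, ties resolving to the downstream (positive-offset) form.
Published residue labels in this family are not always sequence-nearest —
they can follow helix membership, so a residue 20 past H1 may be called
H1+20 even when H2 is 16 away. This implementation keeps the simpler
sequence-nearest contract; everything that consumes specific catalog
positions uses `resolve` (anchor + explicit offset) and is unaffected by
the labeling convention.

The core domain is the alignment window [H1 − 10, H4 + 10] columns,
projected per sequence; with the default spacings this yields the
~130-residue four-helix span that carries both hemes.

## Topology surrogate

Helix assignment uses windowed Kyte–Doolittle hydropathy (window 19,
threshold 1.6, minimum run 15, runs separated by fewer than 3 residues
merged) rather than structure-derived helices: it is sequence-only and
download-free. The window average is computed only where the full window
fits. Sidedness is propagated from the N-terminus (cytoplasmic for
single-domain proteins, non-cytoplasmic for CYBDOMs), alternating at every
crossing; the core register (TM2–TM5 vs TM1–TM4) is read off the segment
containing H1 and is reported "undetermined", with a warning, whenever the
four anchors do not occupy four consecutive predicted segments. The three
core loops must then run cytoplasmic / non-cytoplasmic / cytoplasmic,
which is checked as a structural invariant.

## Percent identity and classification

Pairs are aligned globally under BLOSUM62 with affine gaps (open 10,
extend 1; a gap of length k costs 10 + (k−1)). The alignment engine is
Biopython's `PairwiseAligner`; its deterministic first optimal alignment is
used, which replaces the hand-specified traceback preference of an earlier
design with an equally deterministic one at the same optimal score.
Identity is 100 × (identical columns) / (columns where both rows hold a
residue). This denominator makes identity symmetric and stable under span
restriction, but the viewer used for the original table is undocumented on
this point, so recomputed table values should be read with a ±2-point
tolerance. A matrix can also be extracted from a joint multiple alignment
(`identity_matrix_from_alignment`) for users wanting the joint-MSA
protocol.

Best-match classification takes the row argmax with ties broken by the
fixed human column order (Dcytb, Lcytb, CGcytb, TScytb, CYB561D1, SDR2 —
the table's header order). The Group 4A rule flags a row whose maximum
against the human references strictly exceeds its maximum against the
*D. melanogaster* paralogs (self-comparisons excluded). The bundled
fixture stores no best-match markers; the classifier recomputes them.

The tree builder is canonical neighbor joining with deterministic
tie-breaking by sorted taxon label and negative branch lengths clamped to
zero with a warning. It is exact on additive matrices — the property the
tests verify — and is deliberately labelled NJ in output: it is a
clustering utility, not a reproduction of likelihood phylogenetics.

## Conservation scoring

Three per-column views:

- consensus: modal residue, '+' when two or more residues tie for the
  maximum, '−' when the gap count strictly exceeds every residue's count;
- property score: the number of ten physicochemical property sets
  (hydrophobic, polar, small, tiny, aliphatic, aromatic, charged,
  positive, negative, proline — Taylor-style sets, fixed in
  `conservation.PROPERTY_TABLE`) on which all residues of the column agree
  (all members, or none); gap-free single-residue columns score 11, a gap
  costs one point (floor 0), and ambiguity codes zero the column since
  they carry no properties. Equivalence with any particular viewer's
  arithmetic is not claimed — "8 or 9" thresholds are to be read against
  this scorer, whose table ships with the package;
- entropy z-scores: S = −Σ f ln f over non-gap frequencies (natural log,
  unweighted — no sequence weighting scheme is applied), standardized as
  z = (mean − S)/sd so higher means more conserved, clamped to ±1.5 for
  display only.

Group profiles are computed on row subsets with all columns retained, so
column indices remain comparable across groups.

## Motif scanning and the checklist

Motif patterns are position lists: fixed residue, residue class, or
wildcard. Pattern X means any of the 20 standard residues; ambiguity codes
in a *sequence* match only wildcard positions, preventing spurious hits
through unknowns. All overlapping matches are reported. Region constraints
are strict: `KXXXXKXH` is scanned only in the H2+1..H3−1 window (the
sequence-level stand-in for the non-cytoplasmic core loop; a hit whose His
falls exactly at H3−5 is flagged canonical), and the dileucine signals
only downstream of the last predicted transmembrane segment, each hit
labelled with the most specific spec it satisfies (EDXXLL before the
general (D/E)XXXL(L/I); DXXLL hits are separate 5-residue spans).

The DOMON heme ligands are the Met of the unique `SXDXXMGXD` match inside
the given domain span (ambiguous on zero or multiple matches) and, when a
DOMON-domain alignment is supplied, the residue at the best column
downstream of the Met carrying His in ≥ 90 % of rows.

The ferric-reductase checklist fixes 17 anchor-relative positions with the
substitution sets observed across the family; the four activity-critical
items (H2+22 ∈ {H}, H2+21 ∈ {N,S}, H3−3 ∈ {Y}, H4+25 ∈ {F,Y,W}) gate
`core4_pass`. Offsets that leave the sequence are reported unresolvable
rather than failed, but an unresolvable critical item still blocks the
core verdict. Users may pass a custom catalog.

## Structure geometry

Superposition is SVD-based Kabsch with the proper-rotation correction;
`prune_superpose` iterates fit → drop pairs deviating more than 2.0 Å →
refit until stable (never below 3 pairs), reporting the pruned-pair RMSD
alongside the all-pairs RMSD under the final transform, mirroring how
pruned/all pair counts are reported by structure viewers. The 2.0 Å
default is exposed; the exact pruning schedule of any particular viewer is
not published, so pair-count replication is approximate by construction.

Contacts use overlap = r_a + r_b − d ≥ cutoff (default −0.4 Å) on a fixed,
named van-der-Waals table (Bondi 1964 extended with common metals,
`geometry.VDW_RADII`), with an optional allowance subtracted for N/O–N/O
pairs; pairs within one residue are never reported. Hydrogen bonds are
heavy-atom geometric: donor–acceptor ≤ 3.5 Å and
antecedent–donor–acceptor ≥ 120° for at least one covalently bonded
antecedent (heavy atoms within 1.9 Å in the same residue). No hydrogens
are placed — predicted models and mid-resolution crystal structures carry
none — so donors without an antecedent pass the angle test vacuously.
Exact replication of any viewer's contact counts is declared approximate
(±2 residues) because radii tables and hydrogen inference differ.

## The synthetic-family generator

`simulate` builds templates with six hydrophobic segments (Ile/Val pools,
lengths 22–23 with the H2-segment length pinned by the 34-residue H2–H3
spacing), hydrophilic loops of at least 12 residues with mild polar
{G,S,T} caps at the helix junctions, and the four histidines planted 5–6
residues into the architecture-appropriate segments at spacings 36/34/39 —
the geometry is tuned so the package's own hydropathy predictor recovers
all six helices, making topology-dependent stages testable end to end.
Evolution applies uniform substitutions over the 19 alternatives at
unconstrained sites (so expected identity is 1 − m in closed form),
scrambles "off"-group conserved sites, writes planted motifs per their
probabilities, and applies loop indels of length 1–5. Indels are confined
to loops outside the anchor/conserved-site span: the inter-anchor core is
length-conserved in this family — that is precisely why anchor-relative
coordinates work — and an indel between an anchor and a planted site would
silently shift the site's offset. The generator emits the true multiple
alignment (every insertion its own column), so anchor detection and
conservation scoring are tested without an external aligner.

Preset study conditions: the default insect family carries the group
census 11 CG1275 / 8 Nemy / 7 Group 4A / 18 Group 4B, the full Dcytb
residue catalog in CG1275/Nemy, Nemy's cytoplasmic cysteine doublets, the
`KXXXXKXH` motif in Group 4A at probability 6/7, and a C-terminal EDXXLL
in CG1275; substitution and indel rates default to 0.10. The CYBDOM preset
(10 sequences) has the TM1–TM4 register, a nonpolar H2+22 and glutamate
H2+21, and the DOMON aspartate pocket in its ectodomain; its planted sites
are restricted to loop-resident or hydrophobic positions so helices remain
recoverable, and the DOMON heme histidine — which would be a fifth
perfectly conserved His column in a full-length alignment — is exercised
through dedicated DOMON-domain alignments instead. A light CG1275/Nemy
preset (rates 0.04/0.05, loop-resident sites only) backs the
topology-dependent checks, modelling close homologs.

What passing these benchmarks shows: the pipeline recovers exactly what
was planted, under uniform substitution, loop-confined indels, and a
hydropathy-friendly helix geometry. What it does not show: performance on
real families with matrix-structured substitution, core-loop length
variation, low-hydropathy helices, or alignment error from a real MSA
program — on real data the anchor finder's `h_min` and the spacing window
are the knobs to relax first.

## Determinism and sizes

All randomness flows through numpy Generators seeded from the family spec
or function arguments; identical (spec, seed) inputs yield byte-identical
sequences, truth, and alignments. The recovery suite uses 50 replicate
8-sequence families for anchor recovery, 12 replicate 44-sequence families
for motif recall, 20 single-sequence replicates for the identity-vs-rate
check, and a 60-point helix bundle with 5 planted 8 Å outliers for the
superposition check; these sizes put every recovery estimate's binomial
confidence interval well inside the asserted tolerances while keeping the
whole suite fast.
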