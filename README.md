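# cytb561 — annotation toolkit for the cytochrome b561 protein family

Cytochromes b561 are six-transmembrane-helix oxidoreductases that carry
single electrons across a membrane between two b-type hemes, reducing
non-cytoplasmic substrates such as Fe³⁺ or monodehydroascorbate. The family
is anchored by four universally conserved histidines (H1–H4): H1/H3 ligate
the non-cytoplasmic heme, H2/H4 the cytoplasmic one. Because loop lengths
drift freely between homologs, comparative work labels residues by their
signed offset from the nearest anchor — H1+20, H3−5 — rather than by
absolute position.

This package is for sequence analysts annotating cytb561 families (insect
candidates for ferric reductase activity in particular). It provides:

- **seqio** — FASTA/alignment/PDB readers and the bundled 54×6
  insect-vs-human percent-identity table (accessions, species, groups).
- **anchors** — detection of the four histidine anchor columns in a family
  alignment, the H±n coordinate system (`to_relative` / `resolve`), the
  ~130-residue core-domain span, Kyte–Doolittle transmembrane prediction,
  and membrane sidedness with the TM2–TM5 (single-domain) vs TM1–TM4
  (CYBDOM) core register.
- **identity** — global BLOSUM62 pairwise alignment, percent identity over
  both-non-gap columns, the common-homologous-region intersection rule,
  best-human-match classification with the "Group 4A" rule (closer to a
  human cytb561 than to any *D. melanogaster* paralog), and a
  neighbor-joining utility (labelled NJ; not a likelihood tree).
- **conservation** — consensus logos ('+' on frequency ties, '−' on
  gap-modal columns), a 0–11 physicochemical property-agreement score, and
  standardized entropy z-scores.
- **motifs** — region-constrained scanners for `KXXXXKXH` (non-cytoplasmic
  H2→H3 loop, His canonically at H3−5), the C-terminal dileucine sorting
  signals `EDXXLL` / `(D/E)XXXL(L/I)` / `DXXLL`, the DOMON-domain
  `SXDXXMGXD` aspartate pocket with its Met/His heme ligands, cysteine-loop
  profiling, and the Dcytb-derived ferric-reductase residue checklist
  (activity-critical core: H2+22 His, H2+21 Asn/Ser, H3−3 Tyr, H4+25
  aromatic).
- **geometry** — Kabsch superposition with iterative outlier pruning
  (pruned and all-pairs RMSDs), van-der-Waals-overlap contact detection
  (overlap = r_a + r_b − d against a −0.4 Å cutoff), heavy-atom hydrogen
  bonds, and per-residue ligand contact tables.
- **simulate** — synthetic cytb561-like families with full ground truth
  (planted anchors at spacings 36/34/39, group-specific conserved sites,
  loop indels, planted motifs) so every stage is testable without
  downloads.
- a `cytb561` command-line interface (`anchor`, `topology`, `identity`,
  `classify`, `tree`, `conserve`, `motifs`, `checklist`, `superpose`,
  `contacts`, `simulate`, `run`).

## Worked example

Classify the bundled insect-vs-human identity table and annotate a
synthetic family:

```python
from cytb561 import (load_table1_fixture, IdentityMatrix, best_match,
                     summarize_groups, find_histidine_anchors, resolve)
from cytb561.motifs import ferric_reductase_checklist
from cytb561.simulate import default_insect_spec, simulate_family

fx = load_table1_fixture()
m = IdentityMatrix(values=fx.matrix)
print(best_match(m, "NP_728727.1"))   # ('Dcytb', 45.7)
print(best_match(m, "NP_611079.2"))   # ('SDR2', 37.0)

merged = {a: ("Group 4" if g.startswith("Group 4") else g)
          for a, g in fx.groups.items()}
s = summarize_groups(m, merged)
print(s.counts["Group 4"])  # {'TScytb': 21, 'CGcytb': 1, 'CYB561D1': 2, 'Lcytb': 1}
print(s.ranges["CG8399"])   # (36.5, 43.4)

recs, truth = simulate_family(default_insect_spec(seed=1))
amap = find_histidine_anchors(truth.alignment)
print(amap.anchor_indices("CG1275_01"))      # (60, 96, 130, 169)
print(resolve(amap, "CG1275_01", "H3-3"))    # (127, 'Y')
rep = ferric_reductase_checklist(recs[0], amap)
print(rep.core4_pass, rep.score)             # True 17
```

The first block says the *D. melanogaster* CG1275 protein is most similar
to human Dcytb (45.7 % identity over the homologous region) while CG8399 is
most similar to SDR2 (37.0 %); 21 of the 25 fourth-group sequences match
TScytb best, and the ten CYBDOM-class CG8399 orthologs span 36.5–43.4 %
identity to SDR2. The second block detects the four heme histidines in a
simulated family, reads off the tyrosine at H3−3 (one of the residues
required for ferric reduction by Dcytb), and reports that the sequence
passes all four activity-critical checklist items (and all 17 catalog
items).

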