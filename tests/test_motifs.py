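"""Motif scanners, region constraints, and the residue checklist."""

import numpy as np
import pytest

from cytb561.anchors import AnchorMap, TMTopology, find_histidine_anchors
from cytb561.identity import Span
from cytb561.motifs import (
    CHECKLIST_CATALOG,
    DOMON_POCKET,
    KXH_MOTIF,
    MotifSpec,
    cysteine_loop_profile,
    dileucine_signals,
    domon_heme_ligands,
    ferric_reductase_checklist,
    kxh_site,
    scan_motif,
)
from cytb561.seqio import AlignmentBlock, ProteinRecord
from cytb561.simulate import default_insect_spec, simulate_family

RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _brute_force_scan(seq: str, spec: MotifSpec, lo: int, hi: int):
    hits = []
    for start in range(lo, hi - len(spec) + 2):
        frag = seq[start - 1 : start - 1 + len(spec)]
        ok = True
        for ch, constraint in zip(frag, spec.positions):
            if constraint is None:
                continue
            if ch not in constraint or ch not in "ACDEFGHIKLMNPQRSTVWY":
                ok = False
                break
        if ok:
            hits.append(start)
    return hits


class TestMotifSpec:
    def test_parse_classes_and_wildcards(self):
        spec = MotifSpec.parse("dileu", "(D/E)XXXL(L/I)")
        assert len(spec) == 6
        assert spec.positions[0] == frozenset("DE")
        assert spec.positions[1] is None
        assert spec.positions[5] == frozenset("LI")

    def test_short_pattern_rejected(self):
        with pytest.raises(ValueError, match="length"):
            MotifSpec.parse("xy", "KX")


class TestScanMotif:
    def test_domon_pocket_at_reported_position(self):
        # the aspartate-pocket pattern placed so its Met lands at 286
        rng = np.random.default_rng(0)
        background = "".join(
            rng.choice([r for r in RESIDUES if r not in "SDMG"], size=400)
        )
        seq_str = background[:280] + "SVDAAMGKD" + background[289:]
        rec = ProteinRecord(id="NP_toy", sequence=seq_str)
        hits = scan_motif(rec, DOMON_POCKET)
        assert [(h.start, h.end) for h in hits] == [(281, 289)]
        assert rec.residue(286) == "M"

    def test_kxh_literal(self):
        rec = ProteinRecord(id="x", sequence="KAAAAKAH")
        hits = scan_motif(rec, KXH_MOTIF)
        assert [(h.start, h.end) for h in hits] == [(1, 8)]
        assert hits[0].matched == "KAAAAKAH"

    @pytest.mark.parametrize(
        "pattern", ["KXXXXKXH", "EDXXLL", "(D/E)XXXL(L/I)", "DXXLL", "SXDXXMGXD"]
    )
    def test_random_sequences_match_exhaustive_oracle(self, pattern):
        spec = MotifSpec.parse(pattern, pattern)
        rng = np.random.default_rng(hash(pattern) & 0xFFFF)
        for _ in range(200):
            seq_str = "".join(rng.choice(RESIDUES, size=200))
            rec = ProteinRecord(id="r", sequence=seq_str)
            got = [h.start for h in scan_motif(rec, spec)]
            assert got == _brute_force_scan(seq_str, spec, 1, 200)

    def test_region_constraint_is_strict(self):
        rec = ProteinRecord(id="x", sequence="AAAKAAAAKAHAAA")
        inside = scan_motif(rec, KXH_MOTIF, Span(4, 11))
        outside = scan_motif(rec, KXH_MOTIF, Span(1, 10))
        assert len(inside) == 1 and len(outside) == 0

    def test_sequence_ambiguity_matches_only_wildcards(self):
        spec = MotifSpec.parse("m", "KXH")
        assert scan_motif(ProteinRecord(id="a", sequence="KXH"), spec)
        assert not scan_motif(ProteinRecord(id="b", sequence="XAH"), spec)
        assert not scan_motif(ProteinRecord(id="c", sequence="KAX"), spec)

    def test_overlapping_matches_all_reported(self):
        spec = MotifSpec.parse("m", "AXA")
        rec = ProteinRecord(id="x", sequence="AAAAA")
        assert [h.start for h in scan_motif(rec, spec)] == [1, 2, 3]


def _tail_topology(seq_len, tail_len):
    return TMTopology(segments=((1, seq_len - tail_len),))


class TestDileucine:
    def test_edxxll_labeled_most_specific(self):
        rec = ProteinRecord(id="x", sequence="M" * 30 + "AEDSALLA")
        topo = _tail_topology(len(rec), 8)
        hits = dileucine_signals(rec, topo)
        assert any(h.motif == "EDXXLL" for h in hits)
        assert not any(h.motif == "(D/E)XXXL(L/I)" for h in hits)

    def test_general_signal_without_ed_prefix(self):
        rec = ProteinRecord(id="x", sequence="M" * 30 + "ADAAALLA")
        hits = dileucine_signals(rec, _tail_topology(len(rec), 8))
        assert {h.motif for h in hits} == {"(D/E)XXXL(L/I)"}

    def test_dxxll_only(self):
        rec = ProteinRecord(id="x", sequence="M" * 30 + "DAALL")
        hits = dileucine_signals(rec, _tail_topology(len(rec), 5))
        assert [h.motif for h in hits] == ["DXXLL"]

    def test_signal_upstream_of_last_segment_ignored(self):
        rec = ProteinRecord(id="x", sequence="EDSALL" + "M" * 30 + "AAA")
        hits = dileucine_signals(rec, _tail_topology(len(rec), 3))
        assert hits == []

    def test_no_tail_returns_empty(self):
        rec = ProteinRecord(id="x", sequence="M" * 30)
        assert dileucine_signals(rec, _tail_topology(30, 0)) == []


class TestKxhSite:
    def test_canonical_register_in_group4a(self):
        records, truth = simulate_family(default_insect_spec(seed=19))
        amap = find_histidine_anchors(truth.alignment)
        planted = [
            r for r in records
            if any(m[0] == "KXXXXKXH" for m in truth.sequences[r.id].motifs)
        ]
        assert planted  # the preset plants it in most Group 4A sequences
        for rec in planted:
            hits = kxh_site(rec, amap)
            assert hits and hits[0].canonical_register

    def test_motif_in_wrong_loop_not_reported(self):
        seq = ["A"] * 200
        for i, a in enumerate((50, 86, 120, 159)):
            seq[a - 1] = "H"
        # plant in the H1-H2 interval
        seq[60:68] = list("KAAAAKAH")
        rec = ProteinRecord(id="x", sequence="".join(seq))
        amap = AnchorMap(
            anchor_columns=(50, 86, 120, 159),
            per_sequence={"x": (50, 86, 120, 159)},
            his_fraction=(1.0,) * 4,
            sequences={"x": rec.sequence},
        )
        assert kxh_site(rec, amap) == []

    def test_recall_tracks_planted_probability(self):
        # the preset plants the motif in Group 4A with probability 6/7
        found = total = 0
        for seed in range(12):
            records, truth = simulate_family(default_insect_spec(seed=seed))
            amap = find_histidine_anchors(truth.alignment)
            for rec in records:
                if truth.sequences[rec.id].group != "Group 4A":
                    continue
                total += 1
                if kxh_site(rec, amap):
                    found += 1
        rate = found / total
        p = 6 / 7
        ci = 1.96 * (p * (1 - p) / total) ** 0.5
        assert abs(rate - p) <= ci + 1e-9


class TestDomon:
    def test_met_from_unique_pocket_match(self):
        rng = np.random.default_rng(1)
        background = "".join(
            rng.choice([r for r in RESIDUES if r not in "SDMG"], size=400)
        )
        seq_str = background[:280] + "SVDAAMGKD" + background[289:]
        rec = ProteinRecord(id="x", sequence=seq_str)
        met, his = domon_heme_ligands(rec, Span(200, 350))
        assert met == 286 and his is None

    def test_absent_pattern(self):
        rec = ProteinRecord(id="x", sequence="A" * 100)
        assert domon_heme_ligands(rec, Span(1, 100)) == (None, None)

    def test_multiple_matches_ambiguous(self):
        core = "SADAAMGAD"
        rec = ProteinRecord(id="x", sequence=core + "AAA" + core)
        assert domon_heme_ligands(rec, Span(1, len(rec))) == (None, None)

    def test_his_column_from_domon_alignment(self):
        # five DOMON rows sharing the pocket and a downstream His column
        rng = np.random.default_rng(2)
        rows = []
        for _ in range(5):
            pre = "".join(rng.choice([r for r in RESIDUES if r not in "SDMGH"], 20))
            post = "".join(rng.choice([r for r in RESIDUES if r not in "SDMGH"], 30))
            row = pre + "SADAAMGAD" + post[:20] + "H" + post[20:]
            rows.append(row)
        aln = AlignmentBlock(tuple(f"d{i}" for i in range(5)), tuple(rows))
        rec = aln.ungapped("d0")
        met, his = domon_heme_ligands(rec, Span(1, len(rec)), aln)
        assert met == 26  # M of the pocket at offset 5 from its start (21)
        assert his == 50
        assert rec.residue(his) == "H"

    def test_cybdom_family_pocket_recovered(self, cybdom_family):
        records, truth = cybdom_family
        for rec in records:
            motif = next(
                m for m in truth.sequences[rec.id].motifs if m[0] == "SXDXXMGXD"
            )
            met, _ = domon_heme_ligands(rec, Span(1, truth.template_segments[0][0]))
            assert met == motif[1] + 5


class TestCysteineLoops:
    def test_hand_built_loops(self):
        # segments of 20, loops exactly ACCA / AAA / CAC
        parts = []
        segs = []
        pos = 1
        loops = ["ACCA", "AAA", "CAC"]
        anchors = []
        for i in range(4):
            seg = ["M"] * 20
            seg[5] = "H"
            anchors.append(pos + 5)
            segs.append((pos, pos + 19))
            parts.append("".join(seg))
            pos += 20
            if i < 3:
                parts.append(loops[i])
                pos += len(loops[i])
        seq_str = "".join(parts)
        rec = ProteinRecord(id="x", sequence=seq_str)
        amap = AnchorMap(
            anchor_columns=tuple(anchors),
            per_sequence={"x": tuple(anchors)},
            his_fraction=(1.0,) * 4,
            sequences={"x": seq_str},
        )
        topo = TMTopology(
            segments=tuple(segs),
            n_terminus_side="cytoplasmic",
            region_sides=("cytoplasmic", "non-cytoplasmic", "cytoplasmic",
                          "non-cytoplasmic", "cytoplasmic"),
            core_register="TM1-TM4",
        )
        prof = cysteine_loop_profile(rec, amap, topo)
        assert prof["cys_counts"] == (2, 0, 2)
        assert prof["double_cys"] == (True, False, False)
        assert prof["nemy_like"]

    def test_cysteine_free_sequence(self, light_family):
        from cytb561.anchors import assign_sidedness, predict_tm_segments
        import warnings

        records, truth = light_family
        amap = find_histidine_anchors(truth.alignment)
        checked = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rec in records:
                if truth.sequences[rec.id].group != "CG1275":
                    continue
                topo = assign_sidedness(
                    predict_tm_segments(rec), amap, rec.id, "single-domain"
                )
                if topo.core_register == "undetermined":
                    continue
                prof = cysteine_loop_profile(rec, amap, topo)
                assert not prof["nemy_like"]
                checked += 1
        assert checked >= 3  # most of the group must be analyzable

    def test_undetermined_register_rejected(self):
        rec = ProteinRecord(id="x", sequence="M" * 100)
        amap = AnchorMap(
            anchor_columns=(10, 45, 80, 95),
            per_sequence={"x": (None, None, None, None)},
            his_fraction=(1.0,) * 4,
            sequences={"x": rec.sequence},
        )
        topo = TMTopology(segments=((1, 50),))
        with pytest.raises(ValueError, match="undetermined"):
            cysteine_loop_profile(rec, amap, topo)


class TestChecklist:
    def test_reference_template_passes_core4(self, insect_family):
        records, truth = insect_family
        amap = find_histidine_anchors(truth.alignment)
        for rec in records:
            if truth.sequences[rec.id].group not in ("CG1275", "Nemy"):
                continue
            report = ferric_reductase_checklist(rec, amap)
            assert report.core4_pass, rec.id
            for pos in ("H1+20", "H3+14", "H3-2", "H3-5", "H3+2"):
                assert report.item(pos).passed

    def test_cybdom_fails_nonpolar_h2_22(self, cybdom_family):
        records, truth = cybdom_family
        amap = find_histidine_anchors(truth.alignment)
        for rec in records:
            report = ferric_reductase_checklist(rec, amap)
            assert report.item("H2+22").observed == "L"
            assert not report.item("H2+22").passed
            assert not report.core4_pass

    def test_alanine_everywhere_fails_core4(self):
        seq = ["A"] * 220
        anchors = (50, 86, 120, 159)
        for a in anchors:
            seq[a - 1] = "H"
        rec = ProteinRecord(id="x", sequence="".join(seq))
        amap = AnchorMap(
            anchor_columns=anchors,
            per_sequence={"x": anchors},
            his_fraction=(1.0,) * 4,
            sequences={"x": rec.sequence},
        )
        report = ferric_reductase_checklist(rec, amap)
        assert not report.core4_pass
        for pos in ("H3+4", "H3+18", "H4+4", "H4+18"):
            assert report.item(pos).passed  # Ala allowed at small-residue items
        for pos in ("H2+21", "H3-3", "H4+25", "H1-3"):
            assert not report.item(pos).passed

    def test_offsets_outside_sequence_are_unresolvable_not_failed(self):
        anchors = (20, 56, 90, 129)
        seq = ["A"] * 132  # H4+25 leaves the sequence
        for a in anchors:
            seq[a - 1] = "H"
        rec = ProteinRecord(id="x", sequence="".join(seq))
        amap = AnchorMap(
            anchor_columns=anchors,
            per_sequence={"x": anchors},
            his_fraction=(1.0,) * 4,
            sequences={"x": rec.sequence},
        )
        report = ferric_reductase_checklist(rec, amap)
        item = report.item("H4+25")
        assert not item.resolvable and not item.passed
        assert not report.core4_pass

    def test_depends_only_on_sequence_and_anchors(self, insect_family):
        records, truth = insect_family
        amap = find_histidine_anchors(truth.alignment)
        rec = records[0]
        r1 = ferric_reductase_checklist(rec, amap)
        r2 = ferric_reductase_checklist(rec, amap)
        assert r1 == r2
        assert len(CHECKLIST_CATALOG) == len(r1.items)
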