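"""Pairwise identity, classification rules, and the NJ utility."""

import math

import numpy as np
import pandas as pd
import pytest

from cytb561.identity import (
    IdentityMatrix,
    Span,
    align_pair,
    alignment_score,
    best_match,
    common_region,
    flag_group4a,
    identity_matrix,
    identity_matrix_from_alignment,
    nj_tree,
    percent_identity,
    summarize_groups,
)
from cytb561.seqio import ProteinRecord, load_table1_fixture
from cytb561.simulate import FamilySpec, evolve_family, make_template

RNG = np.random.default_rng(2024)
RESIDUES = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_record(i, n=60):
    return ProteinRecord(id=f"r{i}", sequence="".join(RNG.choice(RESIDUES, size=n)))


class TestAlignPair:
    def test_identical_sequences_gap_free(self):
        a = _random_record(1)
        ra, rb = align_pair(a, a)
        assert ra == rb == a.sequence

    def test_hand_computed_affine_score(self):
        # A-A 4 + C-C 9 + E-E 5, one length-1 gap costing 10
        a = ProteinRecord(id="a", sequence="ACDE")
        b = ProteinRecord(id="b", sequence="ACE")
        assert alignment_score(a, b) == pytest.approx(4 + 9 + 5 - 10)
        ra, rb = align_pair(a, b)
        assert (ra, rb) == ("ACDE", "AC-E")

    def test_score_symmetry(self):
        for i in range(20):
            a, b = _random_record(2 * i), _random_record(2 * i + 1)
            assert alignment_score(a, b) == pytest.approx(alignment_score(b, a))


class TestPercentIdentity:
    def test_identical_rows(self):
        assert percent_identity("ACDEF", "ACDEF") == 100.0

    def test_four_of_five(self):
        assert percent_identity("ACDEF", "ACDFF") == pytest.approx(80.0)

    def test_gap_and_ambiguity_column_excluded_from_denominator(self):
        # the (-, X) column has a gap: 3 shared columns, 3 identical
        assert percent_identity("A-CD", "AXCD") == pytest.approx(100.0)

    def test_matches_brute_force_counter(self):
        rng = np.random.default_rng(7)
        alphabet = np.array(list("ACDE-"))
        for _ in range(50):
            n = int(rng.integers(5, 40))
            ra = "".join(rng.choice(alphabet, size=n))
            rb = "".join(rng.choice(alphabet, size=n))
            shared = sum(
                1 for x, y in zip(ra, rb) if x != "-" and y != "-"
            )
            ident = sum(
                1 for x, y in zip(ra, rb) if x != "-" and y != "-" and x == y
            )
            got = percent_identity(ra, rb)
            if shared == 0:
                assert math.isnan(got)
            else:
                assert got == pytest.approx(100.0 * ident / shared)
                # symmetry and all-gap-column invariance
                assert percent_identity(rb, ra) == pytest.approx(got)
                assert percent_identity(ra + "--", rb + "--") == pytest.approx(got)

    def test_no_shared_columns_is_nan(self):
        assert math.isnan(percent_identity("A--", "--C"))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            percent_identity("AC", "ACD")


class TestPercentIdentityProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    rows = st.text(alphabet="ACDE-", min_size=1, max_size=60)

    @given(rows, rows)
    @settings(derandomize=True, max_examples=200)
    def test_symmetry_and_range(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        got = percent_identity(a, b)
        rev = percent_identity(b, a)
        if math.isnan(got):
            assert math.isnan(rev)
        else:
            assert got == pytest.approx(rev)
            assert 0.0 <= got <= 100.0
            # appending matched all-gap columns never changes the value
            assert percent_identity(a + "---", b + "---") == pytest.approx(got)


class TestCommonRegion:
    def test_intersection(self):
        assert common_region([Span(44, 179), Span(40, 185)]) == Span(44, 179)

    def test_single_span(self):
        assert common_region([Span(5, 50)]) == Span(5, 50)

    def test_disjoint(self):
        with pytest.raises(ValueError, match="no common region"):
            common_region([Span(1, 10), Span(20, 30)])


class TestIdentityMatrix:
    def test_self_diagonal_100(self):
        recs = [_random_record(i) for i in range(4)]
        m = identity_matrix(recs, recs)
        for r in recs:
            assert m.cell(r.id, r.id) == pytest.approx(100.0)

    def test_planted_mutation_fraction(self):
        # identity to the template at substitution rate 0.2, no indels,
        # averages to ~80% across seeds (binomial tolerance)
        vals = []
        for seed in range(20):
            spec = FamilySpec(
                groups=(("G", 1),), site_mutation_rate=0.2,
                loop_indel_rate=0.0, seed=seed,
            )
            tpl, truth = make_template(spec)
            recs, _ = evolve_family(tpl, truth, spec)
            m = identity_matrix(recs, [tpl])
            vals.append(m.cell(recs[0].id, "template"))
        assert abs(np.mean(vals) - 80.0) <= 3.0

    def test_span_restricted_self_comparison_stays_100(self):
        rec = _random_record(9, n=100)
        spans = {rec.id: Span(20, 60)}
        m = identity_matrix([rec], [rec], spans)
        assert m.cell(rec.id, rec.id) == pytest.approx(100.0)

    def test_from_alignment_extracts_row_pairs(self):
        from cytb561.seqio import AlignmentBlock

        aln = AlignmentBlock(("x", "y"), ("ACDEF", "ACDFF"))
        m = identity_matrix_from_alignment(aln, ["x"], ["y"])
        assert m.cell("x", "y") == pytest.approx(80.0)


class TestBestMatch:
    def test_fixture_rows(self):
        fx = load_table1_fixture()
        m = IdentityMatrix(values=fx.matrix)
        assert best_match(m, "NP_611079.2") == ("SDR2", pytest.approx(37.0))
        assert best_match(m, "NP_728727.1") == ("Dcytb", pytest.approx(45.7))

    def test_tie_breaks_by_column_order(self):
        df = pd.DataFrame(
            {"Dcytb": [30.0], "Lcytb": [30.0], "CGcytb": [30.0],
             "TScytb": [30.0], "CYB561D1": [30.0], "SDR2": [30.0]},
            index=["x"],
        )
        assert best_match(IdentityMatrix(values=df), "x")[0] == "Dcytb"

    def test_all_missing_row(self):
        df = pd.DataFrame({"Dcytb": [math.nan]}, index=["x"])
        with pytest.raises(ValueError, match="missing"):
            best_match(IdentityMatrix(values=df), "x")


class TestGroup4A:
    def _matrices(self, human_best, dm_best):
        h = IdentityMatrix(values=pd.DataFrame({"TScytb": [human_best]}, index=["x"]))
        d = IdentityMatrix(
            values=pd.DataFrame({"NP_1": [dm_best], "NP_2": [dm_best - 5]}, index=["x"])
        )
        return h, d

    def test_strictly_greater_flags(self):
        h, d = self._matrices(30.0, 25.0)
        assert flag_group4a(h, d) == {"x": True}

    def test_equal_does_not_flag(self):
        h, d = self._matrices(30.0, 30.0)
        assert flag_group4a(h, d) == {"x": False}

    def test_monotonicity_raising_dm_clears_flag(self):
        h, d = self._matrices(30.0, 25.0)
        assert flag_group4a(h, d)["x"]
        d2 = IdentityMatrix(values=d.values.assign(NP_1=[31.0]))
        assert not flag_group4a(h, d2)["x"]

    def test_self_comparison_excluded(self):
        h = IdentityMatrix(values=pd.DataFrame({"TScytb": [30.0]}, index=["NP_1"]))
        d = IdentityMatrix(
            values=pd.DataFrame({"NP_1": [100.0], "NP_2": [20.0]}, index=["NP_1"])
        )
        assert flag_group4a(h, d) == {"NP_1": True}


class TestSummarizeGroups:
    def test_table1_group4_census(self):
        fx = load_table1_fixture()
        m = IdentityMatrix(values=fx.matrix)
        merged = {
            a: ("Group 4" if g.startswith("Group 4") else g)
            for a, g in fx.groups.items()
        }
        s = summarize_groups(m, merged)
        assert s.counts["Group 4"]["TScytb"] == 21
        assert s.counts["Group 4"]["CYB561D1"] == 2

    def test_table1_cg8399_range(self):
        fx = load_table1_fixture()
        s = summarize_groups(IdentityMatrix(values=fx.matrix), fx.groups)
        lo, hi = s.ranges["CG8399"]
        assert (lo, hi) == (pytest.approx(36.5), pytest.approx(43.4))

    def test_cg8399_rows_all_select_sdr2(self):
        fx = load_table1_fixture()
        s = summarize_groups(IdentityMatrix(values=fx.matrix), fx.groups)
        assert s.counts["CG8399"] == {"SDR2": 10}

    def test_cg1275_nemy_select_dcytb_like_references(self):
        fx = load_table1_fixture()
        s = summarize_groups(IdentityMatrix(values=fx.matrix), fx.groups)
        for g in ("CG1275", "Nemy"):
            assert set(s.counts[g]) <= {"Dcytb", "CGcytb", "Lcytb"}
        assert sum(s.counts["CG1275"].values()) == 11
        assert sum(s.counts["Nemy"].values()) == 8

    def test_single_row_group(self):
        df = pd.DataFrame({"Dcytb": [42.0], "SDR2": [10.0]}, index=["x"])
        s = summarize_groups(IdentityMatrix(values=df), {"x": "solo"})
        assert s.ranges["solo"] == (pytest.approx(42.0), pytest.approx(42.0))

    def test_unlabeled_row_rejected(self):
        df = pd.DataFrame({"Dcytb": [42.0]}, index=["x"])
        with pytest.raises(KeyError):
            summarize_groups(IdentityMatrix(values=df), {})


def _random_tree_distances(rng, n):
    """An additive distance matrix built from a random binary tree."""
    import dendropy

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        taxon_namespace=taxa, rng=rng,
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = round(float(rng.random()) + 0.1, 4)
    pdm = tree.phylogenetic_distance_matrix()
    labels = [t.label for t in taxa]
    d = np.zeros((n, n))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            if i != j:
                d[i, j] = pdm.distance(ti, tj)
    return pd.DataFrame(d, index=labels, columns=labels)


def _patristic_from_newick(newick, labels):
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                d[i, j] = pdm.distance(taxa[a], taxa[b])
    return d


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = pd.DataFrame(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        newick = nj_tree(d)
        # three-point formulas: la = (5+9-10)/2 = 2, lb = 3, lc = 7
        got = _patristic_from_newick(newick, ["a", "b", "c"])
        assert np.allclose(got, d.to_numpy())

    def test_additive_matrix_recovered_exactly(self):
        import random

        rng = random.Random(5)
        d = _random_tree_distances(rng, 5)
        newick = nj_tree(d)
        got = _patristic_from_newick(newick, list(d.index))
        assert np.allclose(got, d.to_numpy(), atol=1e-6)

    def test_ultrametric_pairs_closest_first(self):
        labels = list("abcd")
        d = pd.DataFrame(
            [[0, 2, 8, 8], [2, 0, 8, 8], [8, 8, 0, 4], [8, 8, 4, 0]],
            index=labels, columns=labels, dtype=float,
        )
        newick = nj_tree(d)
        assert "(a:" in newick.replace("b:", "a:") or "(a" in newick
        # a and b must be siblings
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        mrca = tree.mrca(taxon_labels=["a", "b"])
        assert {leaf.taxon.label for leaf in mrca.leaf_iter()} == {"a", "b"}

    def test_asymmetric_input_rejected(self):
        d = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(d, labels=list("abc"))

    def test_negative_branch_clamped_with_warning(self):
        # a non-additive matrix whose NJ solution has a negative branch
        d = pd.DataFrame(
            [[0, 0.869, 0.657, 0.390], [0.869, 0, 0.610, 0.257],
             [0.657, 0.610, 0, 0.164], [0.390, 0.257, 0.164, 0]],
            index=list("abcd"), columns=list("abcd"), dtype=float,
        )
        with pytest.warns(UserWarning, match="clamped"):
            newick = nj_tree(d)
        assert ":-" not in newick
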