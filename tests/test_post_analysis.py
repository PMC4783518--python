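import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trnaremold.core import Alignment, SpeciesTree
from trnaremold.post_analysis import (classify_anticodon_change, codon_shift,
                                      column_specificity, locus_geometry,
                                      normalized_difference, pre_state_check,
                                      quantile_flags, reverse_complement)

from conftest import make_gene


class TestAnticodonChange:
    def test_tryptophan_to_glycine(self):
        # W(UCA) ~> G(UCC): third anticodon position, A -> C
        c = classify_anticodon_change("UCA", "UCC")
        assert c.changed_positions == (3,)
        assert c.substitutions == ("A→C",)
        assert c.family_transition == "two→four"

    def test_serine2_to_tyrosine_changes_two_positions(self):
        # S2(UGA) ~> Y(GUA): wobble and middle positions change
        c = classify_anticodon_change("UGA", "GUA")
        assert c.changed_positions == (1, 2)

    def test_leucine_isoacceptor_switch(self):
        # L2(UAA) ~> L1(UAG): third position
        c = classify_anticodon_change("UAA", "UAG")
        assert c.changed_positions == (3,)
        # UAA reads UUA (two-codon Leu family), UAG reads CUA (CUN box,
        # four-fold Leu) in the mitochondrial codes
        assert c.family_transition == "two→four"

    def test_identical_anticodons_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            classify_anticodon_change("UCA", "UCA")

    def test_accepts_gene_records(self):
        donor = make_gene(gene_id="w", family="W", anticodon="UCA")
        acceptor = make_gene(gene_id="g", family="G", anticodon="UCC",
                             start=100, end=108)
        assert classify_anticodon_change(donor, acceptor).changed_positions \
            == (3,)

    def test_invertebrate_code_changes_degeneracy(self):
        # AGA/AGG are Ser in the invertebrate code (box of 4 Ser+Ser)
        # but stop in the vertebrate code (two-codon Ser family).
        c2 = classify_anticodon_change("GCU", "UGC", table_id=2)
        c5 = classify_anticodon_change("GCU", "UGC", table_id=5)
        assert c2.family_transition == "two→four"
        assert c5.family_transition == "four→four"


class TestLocusGeometry:
    def _gene(self, gene_id, start, end, strand="+", G=16000):
        return make_gene(gene_id=gene_id, family="W" if gene_id == "d" else "G",
                         anticodon="UCA" if gene_id == "d" else "UCC",
                         sequence="A" * (end - start), start=start, end=end,
                         strand=strand, genome_length=G)

    def test_adjacent_genes(self):
        d = self._gene("d", 100, 170)
        a = self._gene("a", 180, 250)
        geom = locus_geometry(d, a, [d, a])
        assert geom.separation == 10
        assert geom.n_intervening == 0 and geom.adjacent
        assert geom.same_strand

    def test_smaller_arc_crosses_origin(self):
        d = self._gene("d", 15950, 15980)
        a = self._gene("a", 100, 170)
        geom = locus_geometry(d, a, [d, a])
        assert geom.separation == 120  # 15980 -> 16000 -> 100

    def test_intervening_count_uses_sparser_arc(self):
        d = self._gene("d", 0, 70)
        a = self._gene("a", 8000, 8070)
        between = [make_gene(gene_id=f"b{i}", family="A", anticodon="UGC",
                             sequence="A" * 60, start=1000 * i,
                             end=1000 * i + 60, genome_length=16000)
                   for i in range(1, 8)]
        geom = locus_geometry(d, a, [d, a] + between)
        assert geom.n_intervening == 0  # the far arc holds no genes

    def test_opposite_strands_detected(self):
        d = self._gene("d", 100, 170)
        a = self._gene("a", 300, 370, strand="-")
        assert not locus_geometry(d, a, [d, a]).same_strand

    def test_overlap_gives_zero_separation(self, caplog):
        d = self._gene("d", 100, 170)
        a = self._gene("a", 150, 220)
        assert locus_geometry(d, a, [d, a]).separation == 0

    def test_clockwise_equals_counterclockwise_complement(self):
        G = 16000
        d = self._gene("d", 1000, 1070)
        a = self._gene("a", 9000, 9070)
        cw = (9000 - 1070) % G
        ccw = (1000 - 9070) % G
        geom = locus_geometry(d, a, [d, a])
        assert cw + ccw == G - 70 - 70
        assert geom.separation == min(cw, ccw)


class TestCodonShift:
    def _change(self):
        return classify_anticodon_change("UCA", "UCC")  # W ~> G

    def test_identical_frequencies_give_zero(self):
        counts = {"GGA": 5, "UGA": 5, "AAA": 10}
        s = codon_shift(counts, dict(counts), self._change())
        assert s.delta_codon == 0.0 and s.delta_box == 0.0

    def test_codon_absent_in_focal_gives_minus_one(self):
        focal = {"AAA": 10}
        ref = {"GGA": 5, "AAA": 5}
        s = codon_shift(focal, ref, self._change())
        assert s.acceptor_codon == "GGA"
        assert s.delta_codon == -1.0

    def test_hand_computed_example(self):
        change = classify_anticodon_change("UUU", "CUU")  # codon AAA vs AAG
        focal = {"AAA": 2, "AAG": 2}
        ref = {"AAA": 1, "AAG": 3}
        s = codon_shift(focal, ref, change)
        # acceptor anticodon CUU reads AAG: (0.5 - 0.75)/(1.25) = -0.2
        assert s.delta_codon == pytest.approx((0.5 - 0.75) / 1.25)

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            codon_shift({}, {"AAA": 1}, self._change())

    @given(f1=st.floats(0, 1), f2=st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_normalized_difference_antisymmetric(self, f1, f2):
        assert normalized_difference(f1, f2) == pytest.approx(
            -normalized_difference(f2, f1))
        assert -1 <= normalized_difference(f1, f2) <= 1


class TestQuantileFlags:
    def test_extreme_low_shifts_flagged_and_significant(self, rng):
        null = list(rng.uniform(-0.2, 0.2, size=30))
        rem = list(rng.uniform(-0.9, -0.5, size=8))
        report = quantile_flags(rem, null)
        assert all(f == "low" for f in report.flags)
        assert report.p_value < 0.01
        assert report.reliable

    def test_null_like_sample_flags_about_five_percent_per_tail(self, rng):
        null = list(rng.normal(size=400))
        rem = list(rng.normal(size=400))
        report = quantile_flags(rem, null)
        low = sum(f == "low" for f in report.flags) / len(rem)
        high = sum(f == "high" for f in report.flags) / len(rem)
        assert 0.0 < low < 0.12 and 0.0 < high < 0.12
        assert report.p_value > 0.05

    def test_empty_remolded_list(self):
        report = quantile_flags([], list(range(30)))
        assert report.flags == [] and report.p_value == 1.0

    def test_small_null_marked_unreliable(self):
        report = quantile_flags([0.1], [0.0] * 5)
        assert not report.reliable


class TestColumnSpecificity:
    def _aln(self, rows_a, rows_b):
        ids = [f"a{i}" for i in range(len(rows_a))] + \
              [f"b{i}" for i in range(len(rows_b))]
        groups = {i: ("donor" if i.startswith("a") else "acceptor")
                  for i in ids}
        return Alignment(ids=ids, rows=rows_a + rows_b, groups=groups)

    def test_fixed_difference_flagged(self):
        aln = self._aln(["GA", "GA", "GA"], ["UA", "UA", "UA"])
        res = column_specificity(aln)
        assert list(res.flagged) == [True, False]
        assert res.bits["donor"][0].max() == pytest.approx(2.0)

    def test_uniform_columns_not_flagged(self):
        aln = self._aln(["A", "C", "G", "U"], ["A", "C", "G", "U"])
        res = column_specificity(aln)
        assert not res.flagged.any()

    def test_half_split_sits_exactly_on_threshold(self):
        # 50/50 G/A gives I = 1 bit, bits(G) = 0.5: NOT > 0.5, so the
        # strict inequality leaves the column unflagged.
        aln = self._aln(["G", "G", "A", "A"], ["U", "U", "U", "U"])
        res = column_specificity(aln)
        assert res.bits["donor"][0, 2] == pytest.approx(0.5)
        assert not res.flagged[0]

    def test_row_order_and_duplication_invariance(self):
        base = self._aln(["GC", "GA"], ["UC", "UA"])
        res1 = column_specificity(base)
        shuffled = self._aln(["GA", "GC"], ["UA", "UC"])
        res2 = column_specificity(shuffled)
        doubled = self._aln(["GC", "GA"] * 2, ["UC", "UA"] * 2)
        res3 = column_specificity(doubled)
        assert list(res1.flagged) == list(res2.flagged) == list(res3.flagged)

    def test_gappy_column_masked(self):
        aln = self._aln(["G-", "G-", "GA"], ["U-", "UC", "U-"])
        res = column_specificity(aln)
        assert res.masked[1] and not res.flagged[1]

    def test_needs_exactly_two_groups(self):
        aln = Alignment(ids=["a", "b"], rows=["AC", "AC"],
                        groups={"a": "x", "b": "x"})
        with pytest.raises(ValueError):
            column_specificity(aln)


class TestPreStateCheck:
    def _setup(self):
        tree = SpeciesTree.from_newick("(((a,b),(c,d)),(e,f));")
        event_node = tree.mrca(["a", "b"]).node_id
        return tree, event_node

    def test_pre_duplication_when_acceptor_absent(self):
        tree, node = self._setup()
        copies = {sp: {"W": 1, "G": 1} for sp in tree.species}
        copies["c"] = copies["d"] = {"W": 1, "G": 0}
        out = pre_state_check(tree, node, copies, donor="W", acceptor="G")
        assert out["sister"] == "pre_duplication"
        assert out["parent_sister"] == "neither"

    def test_pre_deletion_when_donor_duplicated(self):
        tree, node = self._setup()
        copies = {sp: {"W": 1, "G": 1} for sp in tree.species}
        copies["e"] = copies["f"] = {"W": 2, "G": 1}
        out = pre_state_check(tree, node, copies, donor="W", acceptor="G")
        assert out["parent_sister"] == "pre_deletion"
        assert out["sister"] == "neither"

    def test_mixed_clade_is_neither(self):
        tree, node = self._setup()
        copies = {sp: {"W": 1, "G": 1} for sp in tree.species}
        copies["c"] = {"W": 1, "G": 0}
        out = pre_state_check(tree, node, copies, donor="W", acceptor="G")
        assert out["sister"] == "neither"

    def test_missing_annotation_reports_unknown(self):
        tree, node = self._setup()
        copies = {sp: {"W": 1, "G": 1} for sp in tree.species if sp != "c"}
        out = pre_state_check(tree, node, copies, donor="W", acceptor="G")
        assert out["sister"] == "unknown"


def test_reverse_complement():
    assert reverse_complement("UCA") == "UGA"
    assert reverse_complement("GUA") == "UAC"
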