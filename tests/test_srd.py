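import itertools
import math

import numpy as np
import pytest
from scipy import stats

from trnaremold.core import SpeciesTree
from trnaremold.similarity import SimilarityMatrix, score_matrix
from trnaremold.srd import (CandidatePair, DegenerateDistribution,
                            DirectionalVerdict, clean_gene_ids,
                            closest_clean_relative, find_candidates,
                            grubbs_max_test, run_srd, summarize_filter_losses, wilcoxon_one_sample)
from trnaremold.srd import test_direction as apply_direction
from trnaremold.synthetic_data import SimulationConfig, simulate

from conftest import make_gene


def grubbs_reference(values):
    """Independent closed-form evaluation of the one-sided max test."""
    x = np.asarray(values, dtype=float)
    n = x.size
    G = (x.max() - x.mean()) / x.std(ddof=1)
    denom = (n - 1) ** 2 - n * G * G
    if denom <= 0:
        return G, 0.0
    t = math.sqrt(n * (n - 2) * G * G / denom)
    return G, min(1.0, n * stats.t.sf(t, n - 2))


def signed_rank_enumeration(sample, value, alternative):
    """Full 2^n enumeration of the signed-rank null (midranks fixed)."""
    d = np.asarray(sample, dtype=float) - value
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(ranks)
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if alternative == "less":
            count += w <= w_obs + 1e-12
        else:
            count += w >= w_obs - 1e-12
    return count / 2 ** n


class TestGrubbs:
    def test_known_vector(self):
        G, p = grubbs_max_test([1, 2, 3, 10])
        assert G == pytest.approx(1.4696938, abs=1e-6)
        assert p == pytest.approx(0.04040821, abs=1e-7)

    def test_three_symmetric_values(self):
        G, p = grubbs_max_test([1, 2, 3])
        assert G == pytest.approx(1.0)
        assert p == pytest.approx(0.5)

    def test_zero_variance_fails(self):
        with pytest.raises(DegenerateDistribution):
            grubbs_max_test([5, 5, 5, 5])

    def test_too_few_values_fails(self):
        with pytest.raises(DegenerateDistribution):
            grubbs_max_test([1, 2])

    def test_huge_outlier_clamps_to_zero(self):
        G, p = grubbs_max_test([0.0, 0.0, 0.0, 1.0])
        assert p == 0.0  # G at its attainable maximum (n-1)/sqrt(n)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_independent_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=int(rng.integers(4, 40)))
        G, p = grubbs_max_test(x)
        G_ref, p_ref = grubbs_reference(x)
        assert G == pytest.approx(G_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)


class TestWilcoxon:
    def test_all_below_value_less(self):
        p = wilcoxon_one_sample([1, 2, 3, 4, 5, 6], 10, "less")
        assert p == pytest.approx(1 / 64)

    def test_all_below_value_greater_not_significant(self):
        p = wilcoxon_one_sample([1, 2, 3, 4, 5, 6], 10, "greater")
        assert p >= 1 - 1 / 64 and p > 0.05

    def test_symmetric_sample_not_significant(self):
        sample = np.concatenate([10 - np.arange(1, 14), 10 + np.arange(1, 14)])
        for alt in ("less", "greater"):
            assert wilcoxon_one_sample(sample, 10.0, alt) > 0.2

    def test_empty_effective_sample(self):
        assert wilcoxon_one_sample([3.0, 3.0], 3.0, "less") == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_mode_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        sample = np.round(rng.normal(size=n), 1)
        for alt in ("less", "greater"):
            got = wilcoxon_one_sample(sample, 0.0, alt)
            want = signed_rank_enumeration(sample, 0.0, alt)
            assert got == pytest.approx(want, abs=1e-12)

    def test_agrees_with_scipy_without_ties(self, rng):
        sample = rng.normal(size=15)
        for alt in ("less", "greater"):
            got = wilcoxon_one_sample(sample, 0.0, alt)
            want = stats.wilcoxon(sample, alternative=alt,
                                  method="exact").pvalue
            assert got == pytest.approx(want, abs=1e-12)

    def test_normal_approximation_mode_is_close(self, rng):
        sample = rng.normal(loc=-0.6, size=60)
        exact_ish = stats.wilcoxon(sample, alternative="less",
                                   method="approx", correction=True).pvalue
        got = wilcoxon_one_sample(sample, 0.0, "less")
        assert got == pytest.approx(exact_ish, rel=1e-6)


def _toy_genes_and_matrix(cross_scores):
    """Six one-gene families in one species with prescribed cross scores."""
    fams = ["A", "C", "D", "E", "F", "G"]
    anticodons = {"A": "UGC", "C": "GCA", "D": "GUC", "E": "UUC",
                  "F": "GAA", "G": "UCC"}
    genes = [make_gene(gene_id=f, species="sp1", family=f,
                       anticodon=anticodons[f], sequence="ACGU" * 17,
                       start=100 * i, end=100 * i + 68)
             for i, f in enumerate(fams)]
    mat = SimilarityMatrix()
    for f in fams:
        mat.set(f, f, 100.0)
    for (a, b), s in cross_scores.items():
        mat.set(a, b, s)
    return genes, mat


class TestFindCandidates:
    def test_extreme_pair_enters_P(self):
        cross = {}
        fams = ["A", "C", "D", "E", "F", "G"]
        jitter = {"D": 0.1, "E": -0.1, "F": 0.05, "G": -0.05, "A": 0.0,
                  "C": 0.0}
        for a in fams:
            for b in fams:
                if a != b:
                    cross[(a, b)] = 20.0 + jitter[b]
        cross[("A", "C")] = cross[("C", "A")] = 60.0
        genes, mat = _toy_genes_and_matrix(cross)
        P, N = find_candidates(mat, genes)
        assert len(P) == 1
        pair = next(iter(P.values()))
        assert pair.families == frozenset(("A", "C"))
        assert set(P) <= set(N)

    def test_identical_cross_scores_give_empty_P(self):
        fams = ["A", "C", "D", "E", "F", "G"]
        cross = {(a, b): 20.0 for a in fams for b in fams if a != b}
        genes, mat = _toy_genes_and_matrix(cross)
        P, N = find_candidates(mat, genes)
        assert P == {} and N == {}

    def test_small_species_skipped(self):
        genes, mat = _toy_genes_and_matrix({})
        P, N = find_candidates(mat, genes[:3])
        assert P == {} and N == {}

    def test_P_subset_of_N_on_simulated_data(self, default_dataset):
        scorer = score_matrix(default_dataset.genes)
        P, N = find_candidates(scorer, default_dataset.genes)
        assert set(P) <= set(N)

    def test_null_candidate_rate_is_alpha_like(self):
        """Without remolding, the per-gene-test rate of significant
        candidates stays below 10% (alpha = 0.05 one test per gene)."""
        tests = hits = 0
        for seed in range(25):
            ds = simulate(SimulationConfig(n_species=6, event=None,
                                           seed=9000 + seed))
            scorer = score_matrix(ds.genes)
            P, _ = find_candidates(scorer, ds.genes)
            tests += sum(1 for _ in ds.genes)
            hits += len(P)
        assert hits / tests < 0.10


class TestCleanAndReference:
    def _pair(self, species, gx, gy, flagged):
        pair = CandidatePair(species=species, gene_x=gx, gene_y=gy,
                             statistic=2.0, p_value=0.2)
        pair.flagged_models = set(flagged)
        return pair

    def test_clean_marks_only_flagging_models(self):
        ga = make_gene(gene_id="a", family="A")
        gc = make_gene(gene_id="c", family="C", anticodon="GCA")
        pair = self._pair("sp1", ga, gc, ["a"])
        clean = clean_gene_ids([ga, gc], {pair.key: pair})
        assert clean == frozenset({"c"})

    def test_closest_clean_relative_prefers_sister(self):
        tree = SpeciesTree.from_newick("((i,j),(k,l));")
        lookup, clean = {}, set()
        for sp in "ijkl":
            for fam, ac in (("A", "UGC"), ("C", "GCA")):
                g = make_gene(gene_id=f"{sp}{fam}", species=sp, family=fam,
                              anticodon=ac)
                lookup[(sp, fam)] = [g]
                clean.add(g.gene_id)
        assert closest_clean_relative(tree, "i", "A", "C", lookup,
                                      frozenset(clean)) == "j"
        # excluding the sister's gene moves to the next-nearest species
        clean2 = frozenset(clean - {"jA"})
        assert closest_clean_relative(tree, "i", "A", "C", lookup,
                                      clean2) in ("k", "l")
        # the focal species itself is never returned
        assert closest_clean_relative(tree, "i", "A", "C", lookup,
                                      frozenset({"iA", "iC"})) is None


def _direction_fixture(observed=50.0, other=10.0):
    species = list("ijklmn")
    tree = SpeciesTree.from_newick("(((i,j),(k,l)),(m,n));")
    lookup, genes = {}, []
    for sp in species:
        for fam, ac in (("A", "UGC"), ("C", "GCA")):
            g = make_gene(gene_id=f"{sp}{fam}", species=sp, family=fam,
                          anticodon=ac)
            lookup[(sp, fam)] = [g]
            genes.append(g)
    clean = frozenset(g.gene_id for g in genes)
    mat = SimilarityMatrix()
    bg1 = dict(zip(species, [5.0, 6.0, 7.0, 5.5, 6.5, 5.8]))
    for sp in species:
        mat.set(f"{sp}A", f"{sp}C", bg1[sp])          # criterion-(i) background
    sisters = {"i": "j", "j": "i", "k": "l", "l": "k", "m": "n", "n": "m"}
    for l, k in sisters.items():
        mat.set(f"{k}A", f"{l}A", 48.0 + 0.5 * species.index(l))
    mat.set("jA", "iC", observed)                      # S(Y_i | X_j)
    mat.set("jC", "iC", other)                         # S(Y_i | Y_j)
    pair = CandidatePair(species="i", gene_x=lookup[("i", "A")][0],
                         gene_y=lookup[("i", "C")][0],
                         statistic=3.0, p_value=0.001)
    return pair, mat, tree, lookup, clean


class TestDirectionalCriteria:
    def test_remolded_like_scores_pass_all_three(self):
        pair, mat, tree, lookup, clean = _direction_fixture()
        v = apply_direction(pair, "A", "C", mat, tree, lookup, clean)
        assert v.status == "tested" and v.reference_species == "j"
        assert v.passed1 and v.passed2 and v.passed3 and v.passed

    def test_observed_below_background_fails_criterion_one(self):
        pair, mat, tree, lookup, clean = _direction_fixture(observed=1.0,
                                                            other=0.5)
        v = apply_direction(pair, "A", "C", mat, tree, lookup, clean)
        assert not v.passed1 and v.criterion1_p > 0.9
        assert not v.passed2  # also far below the homolog background
        assert not v.passed

    def test_equal_scores_fail_strict_criterion_three(self):
        pair, mat, tree, lookup, clean = _direction_fixture(observed=50.0,
                                                            other=50.0)
        v = apply_direction(pair, "A", "C", mat, tree, lookup, clean)
        assert v.criterion3_delta == 0.0 and not v.passed3

    def test_missing_scores_yield_untestable(self):
        pair, mat, tree, lookup, clean = _direction_fixture()
        empty = SimilarityMatrix()
        v = apply_direction(pair, "A", "C", empty, tree, lookup, clean)
        assert v.status == "untestable"


class TestSummarize:
    def _verdict(self, failed):
        v = DirectionalVerdict(species="i", donor="A", acceptor="C",
                               reference_species="j")
        v.passed1 = "i" not in failed
        v.passed2 = "ii" not in failed
        v.passed3 = "iii" not in failed
        return v

    def test_constructed_combinations(self):
        verdicts = [self._verdict(("i", "ii")), self._verdict(("ii", "iii"))]
        table = summarize_filter_losses(verdicts)
        assert dict(zip(table.violated, table["count"])) == {
            "i+ii": 1, "ii+iii": 1}

    def test_all_pass_gives_empty_table(self):
        verdicts = [self._verdict(()), self._verdict(())]
        assert summarize_filter_losses(verdicts).empty

    def test_row_sums_conserved(self):
        verdicts = [self._verdict(("i",)), self._verdict(("ii", "iii")),
                    self._verdict(()), self._verdict(("i", "ii", "iii"))]
        table = summarize_filter_losses(verdicts)
        tested = len(verdicts)
        accepted = sum(v.passed for v in verdicts)
        assert table["count"].sum() == tested - accepted


class TestEndToEnd:
    def test_implanted_event_detected_with_correct_direction(self,
                                                             default_dataset):
        ds = default_dataset
        scorer = score_matrix(ds.genes)
        result = run_srd(ds.genes, ds.tree, scorer, seed=0)
        fams = frozenset(("W", "G"))
        affected = ds.event.affected_species
        assert any(p.families == fams and p.species in affected
                   for p in result.P.values())
        correct = [v for v in result.verdicts
                   if v.donor == "W" and v.acceptor == "G"
                   and v.species in affected]
        reverse = [v for v in result.verdicts
                   if v.donor == "G" and v.acceptor == "W"
                   and v.species in affected]
        assert any(v.passed for v in correct)
        assert not any(v.passed for v in reverse)
        # the reverse direction fails the strict similarity ordering
        for v in reverse:
            if v.status == "tested":
                assert not v.passed3
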