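"""Similarity-based remolding detection (SRD).

For each species *i* and tRNA gene ``X_i`` the set-score distribution
``{ S({X_i, Z_i} | X_i) : Z != X }`` over all alloacceptor partners is
examined; the maximum-scoring partner ``Y_i`` is tested as a one-sided
outlier with the Grubbs test.  Significant pairs form the candidate set P;
pairs whose maximum is a (not necessarily significant) high-side outlier
form the background set N, which defines the "clean" genes by exclusion.
Both directions of every candidate are then screened with three criteria
against score backgrounds from clean genes of closely related species; the
survivors form the verified set R.

Because the L1/L2 and S1/S2 isoacceptor families are annotated as separate
identities, switches between them count as alloacceptor remoldings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import SpeciesTree, TRNAGene, genes_by_species

logger = logging.getLogger(__name__)


class DegenerateDistribution(ValueError):
    """Raised when an outlier test is undefined (n < 3 or zero variance)."""


def grubbs_max_test(values) -> tuple[float, float]:
    """One-sided Grubbs test of the maximum.

    Returns ``(G, p)`` with ``G = (max - mean) / sd`` (sample sd) and the
    one-sided p-value for a single high outlier,
    ``p = n * P(T_{n-2} >= t)`` with
    ``t = sqrt(n (n-2) G^2 / ((n-1)^2 - n G^2))``, clamped to [0, 1];
    when ``(n-1)^2 - n G^2 <= 0`` (G at its attainable maximum), p = 0.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise DegenerateDistribution(f"Grubbs test needs n >= 3, got {n}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateDistribution("Grubbs test undefined for zero variance")
    G = float((x.max() - x.mean()) / sd)
    denom = (n - 1) ** 2 - n * G * G
    if denom <= 0:
        return G, 0.0
    t = math.sqrt(n * (n - 2) * G * G / denom)
    p = n * stats.t.sf(t, df=n - 2)
    return G, float(min(max(p, 0.0), 1.0))


def _signed_rank_exact(ranks2: np.ndarray, w2: float, alternative: str) -> float:
    """Exact null of the signed-rank sum by convolution.

    ``ranks2`` are doubled (mid)ranks, hence integers even under ties.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(w2))
    if alternative == "less":
        return float(dist[: w2 + 1].sum())
    return float(dist[w2:].sum())


def wilcoxon_one_sample(sample, value: float, alternative: str,
                        exact_limit: int = 25) -> float:
    """One-sample Wilcoxon signed-rank test of H0: median(sample) = value.

    ``alternative='less'`` means the sample tends below ``value``.  Elements
    equal to ``value`` are dropped; an empty effective sample yields p = 1
    with a warning.  The null distribution is exact (convolution over
    midranks) up to ``exact_limit`` observations and a normal approximation
    with continuity and tie correction above.
    """
    if alternative not in ("less", "greater"):
        raise ValueError("alternative must be 'less' or 'greater'")
    d = np.asarray(sample, dtype=float) - value
    d = d[d != 0]
    n = d.size
    if n == 0:
        logger.warning("signed-rank test on empty effective sample; p = 1")
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    if n <= exact_limit:
        ranks2 = np.round(2 * ranks).astype(int)
        return min(1.0, _signed_rank_exact(ranks2, 2 * w_plus, alternative))
    mean = n * (n + 1) / 4.0
    var = (ranks ** 2).sum() / 4.0
    if var == 0:
        return 1.0
    if alternative == "less":
        z = (w_plus - mean + 0.5) / math.sqrt(var)
        return float(min(1.0, stats.norm.cdf(z)))
    z = (w_plus - mean - 0.5) / math.sqrt(var)
    return float(min(1.0, stats.norm.sf(z)))


@dataclass
class CandidatePair:
    """An unordered exceptionally-similar alloacceptor pair of one species.

    ``flagged_models`` records from which gene's score distribution the
    high-side outlier was observed; a pair detected from both members'
    models carries both ids.
    """

    species: str
    gene_x: TRNAGene
    gene_y: TRNAGene
    statistic: float
    p_value: float
    flagged_models: set = field(default_factory=set)

    @property
    def key(self) -> tuple[str, frozenset]:
        return (self.species, frozenset((self.gene_x.gene_id, self.gene_y.gene_id)))

    @property
    def families(self) -> frozenset:
        return frozenset((self.gene_x.family, self.gene_y.family))


@dataclass
class DirectionalVerdict:
    """Outcome of the three directional criteria for one X~>Y hypothesis."""

    species: str
    donor: str                       # donor family X
    acceptor: str                    # acceptor family Y
    reference_species: str | None    # j = C_XY(i)
    observed: float | None = None    # S(Y_i | X_j)
    criterion1_p: float | None = None
    criterion2_p: float | None = None
    criterion3_delta: float | None = None   # S(Y_i|X_j) - S(Y_i|Y_j)
    passed1: bool = False
    passed2: bool = False
    passed3: bool = False
    status: str = "tested"           # "tested" | "untestable"
    reason: str | None = None

    @property
    def passed(self) -> bool:
        return (self.status == "tested"
                and self.passed1 and self.passed2 and self.passed3)

    @property
    def failed_criteria(self) -> tuple[str, ...]:
        if self.status != "tested":
            return ()
        out = []
        if not self.passed1:
            out.append("i")
        if not self.passed2:
            out.append("ii")
        if not self.passed3:
            out.append("iii")
        return tuple(out)


def _is_high_outlier(values: np.ndarray) -> bool:
    """Max-side outlier in the qualitative sense: max-mean > mean-min."""
    m = values.mean()
    return (values.max() - m) > (m - values.min())


def find_candidates(scores, genes, alpha: float = 0.05):
    """Build the candidate set P and the background set N.

    ``scores`` is a :class:`~trnaremold.similarity.SimilarityMatrix` or
    scorer holding the within-species blocks.  Returns ``(P, N)`` as dicts
    keyed by ``CandidatePair.key``.  Species with fewer than 4 tRNA genes
    are skipped (the outlier test needs at least 3 partners).
    """
    P: dict = {}
    N: dict = {}
    for species, sp_genes in sorted(genes_by_species(genes).items()):
        if len(sp_genes) < 4:
            logger.warning("species %s has < 4 tRNAs; skipped", species)
            continue
        sp_genes = sorted(sp_genes, key=lambda g: g.gene_id)
        for gx in sp_genes:
            partners = [g for g in sp_genes if g.family != gx.family]
            if len(partners) < 3:
                logger.warning("gene %s has < 3 alloacceptor partners; skipped",
                               gx.gene_id)
                continue
            vals = np.array([
                scores.score_set([gx.gene_id, gz.gene_id], gx.gene_id)
                for gz in partners
            ])
            order = np.argsort(vals)
            best = partners[int(order[-1])]
            # deterministic tie-break on equal maxima: smallest gene id
            top = [partners[int(k)] for k in np.flatnonzero(vals == vals.max())]
            best = min(top, key=lambda g: g.gene_id)
            try:
                G, p = grubbs_max_test(vals)
            except DegenerateDistribution as exc:
                logger.info("gene %s: %s; treated as p = 1", gx.gene_id, exc)
                continue
            pair = CandidatePair(species=species, gene_x=gx, gene_y=best,
                                 statistic=G, p_value=p)
            if _is_high_outlier(vals):
                prev = N.get(pair.key)
                if prev is None:
                    N[pair.key] = pair
                elif p < prev.p_value:
                    pair.flagged_models |= prev.flagged_models
                    N[pair.key] = pair
                else:
                    prev.flagged_models.add(gx.gene_id)
                N[pair.key].flagged_models.add(gx.gene_id)
            if p < alpha:
                prev = P.get(pair.key)
                if prev is None or p < prev.p_value:
                    P[pair.key] = pair
    return P, N


def clean_gene_ids(genes, N: dict) -> frozenset:
    """Genes not implicated in any N pair.

    A gene counts as implicated when its *own* score distribution flagged
    its maximum partner as a high-side outlier; a true remolding implicates
    both members through their own tests (each scores the other as its
    outlying maximum), whereas a gene that merely happens to be another
    gene's noisy maximum is not penalized.
    """
    unclean = set()
    for pair in N.values():
        unclean |= pair.flagged_models
    return frozenset(g.gene_id for g in genes) - frozenset(unclean)


def _clean_gene(lookup, clean: frozenset, species: str, family: str):
    """A clean gene of (species, family), or None."""
    for g in lookup.get((species, family), ()):  # sorted upstream
        if g.gene_id in clean:
            return g
    return None


def closest_clean_relative(tree: SpeciesTree, species: str, fam_x: str,
                           fam_y: str, lookup, clean: frozenset) -> str | None:
    """j = C_XY(i): the clean species at smallest patristic distance.

    Eligible species carry clean genes of both families; ties are broken by
    lexicographic species id.  Returns ``None`` when no species is eligible
    (the directional test is then untestable).
    """
    best = None
    for j in tree.species:
        if j == species:
            continue
        if _clean_gene(lookup, clean, j, fam_x) is None:
            continue
        if _clean_gene(lookup, clean, j, fam_y) is None:
            continue
        d = tree.patristic_distance(species, j)
        if best is None or (d, j) < best:
            best = (d, j)
    return best[1] if best else None


def _background_same_species(scores, lookup, clean, donor: str,
                             species_list) -> list[float]:
    """Criterion (i) background: {S(Z_k | X_k) : Z != X, both clean}."""
    out = []
    for k in species_list:
        gx = _clean_gene(lookup, clean, k, donor)
        if gx is None:
            continue
        for (sp, fam), gs in lookup.items():
            if sp != k or fam == donor:
                continue
            for gz in gs:
                if gz.gene_id in clean:
                    out.append(scores.get(gx.gene_id, gz.gene_id))
    return out


def _background_homolog(scores, tree, lookup, clean, donor: str, fam_y: str,
                        species_list) -> list[float]:
    """Criterion (ii) background: {S(X_l | X_k) : k = C_XY(l), both clean}."""
    out = []
    for l in species_list:
        gl = _clean_gene(lookup, clean, l, donor)
        if gl is None:
            continue
        k = closest_clean_relative(tree, l, donor, fam_y, lookup, clean)
        if k is None:
            continue
        gk = _clean_gene(lookup, clean, k, donor)
        out.append(scores.get(gk.gene_id, gl.gene_id))
    return out


def _subsample(values, cap: int, rng) -> list[float]:
    if cap and len(values) > cap:
        idx = rng.choice(len(values), size=cap, replace=False)
        return [values[i] for i in sorted(idx)]
    return list(values)


def test_direction(pair: CandidatePair, donor: str, acceptor: str, scores,
                   tree: SpeciesTree, lookup, clean: frozenset,
                   alpha: float = 0.05, background_cap: int = 500,
                   rng=None) -> DirectionalVerdict:
    """Apply the three directional criteria to the hypothesis X ~> Y.

    With ``j = C_XY(i)`` and observed ``S(Y_i | X_j)``:

    i.   the observed score significantly exceeds the background of clean
         within-species alloacceptor scores (signed-rank, background "less",
         p <= alpha);
    ii.  the observed score is NOT significantly below the background of
         clean cross-species donor-donor scores (signed-rank, background
         "greater", p > alpha);
    iii. ``S(Y_i | X_j) > S(Y_i | Y_j)`` strictly.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    i = pair.species
    gene_y = pair.gene_x if pair.gene_x.family == acceptor else pair.gene_y
    verdict = DirectionalVerdict(species=i, donor=donor, acceptor=acceptor,
                                 reference_species=None)
    j = closest_clean_relative(tree, i, donor, acceptor, lookup, clean)
    if j is None:
        verdict.status = "untestable"
        verdict.reason = "no clean reference species"
        return verdict
    verdict.reference_species = j
    gx_j = _clean_gene(lookup, clean, j, donor)
    gy_j = _clean_gene(lookup, clean, j, acceptor)
    try:
        observed = scores.get(gx_j.gene_id, gene_y.gene_id)
        other = scores.get(gy_j.gene_id, gene_y.gene_id)
    except KeyError as exc:
        verdict.status = "untestable"
        verdict.reason = f"missing score {exc}"
        return verdict
    verdict.observed = observed
    species_list = tree.species
    bg1 = _subsample(
        _background_same_species(scores, lookup, clean, donor, species_list),
        background_cap, rng)
    bg2 = _subsample(
        _background_homolog(scores, tree, lookup, clean, donor, acceptor,
                            species_list),
        background_cap, rng)
    if not bg1 or not bg2:
        verdict.status = "untestable"
        verdict.reason = "empty criterion background"
        return verdict
    verdict.criterion1_p = wilcoxon_one_sample(bg1, observed, "less")
    verdict.passed1 = verdict.criterion1_p <= alpha
    verdict.criterion2_p = wilcoxon_one_sample(bg2, observed, "greater")
    verdict.passed2 = verdict.criterion2_p > alpha
    verdict.criterion3_delta = observed - other
    verdict.passed3 = verdict.criterion3_delta > 0
    return verdict


def summarize_filter_losses(verdicts) -> pd.DataFrame:
    """Count rejected directions per violated-criteria combination.

    Row sums equal the number of tested directions minus the accepted ones,
    enabling the all-three / i+ii / ii+iii style breakdown.
    """
    counts: dict[str, int] = {}
    for v in verdicts:
        if v.status != "tested" or v.passed:
            continue
        key = "+".join(v.failed_criteria)
        counts[key] = counts.get(key, 0) + 1
    tested = sum(1 for v in verdicts if v.status == "tested")
    accepted = sum(1 for v in verdicts if v.passed)
    rows = [{"violated": k, "count": c,
             "fraction": c / max(1, tested - accepted)}
            for k, c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["violated", "count", "fraction"])


@dataclass
class SRDResult:
    """Full output of one SRD run."""

    P: dict
    N: dict
    clean: frozenset
    verdicts: list
    R: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.verdicts:
            rows.append({
                "species": v.species, "donor": v.donor, "acceptor": v.acceptor,
                "reference_species": v.reference_species,
                "observed_bits": v.observed,
                "criterion1_p": v.criterion1_p, "criterion2_p": v.criterion2_p,
                "criterion3_delta": v.criterion3_delta,
                "passed1": v.passed1, "passed2": v.passed2, "passed3": v.passed3,
                "status": v.status, "reason": v.reason, "accepted": v.passed,
            })
        return pd.DataFrame(rows)


def run_srd(genes, tree: SpeciesTree, scores, alpha: float = 0.05,
            background_cap: int = 500, seed: int = 0) -> SRDResult:
    """Full SRD pipeline: candidate search plus directional screening."""
    rng = np.random.default_rng(seed)
    P, N = find_candidates(scores, genes, alpha=alpha)
    clean = clean_gene_ids(genes, N)
    lookup: dict[tuple[str, str], list[TRNAGene]] = {}
    for g in sorted(genes, key=lambda g: g.gene_id):
        lookup.setdefault((g.species, g.family), []).append(g)
    verdicts = []
    for key in sorted(P, key=lambda k: (k[0], sorted(k[1]))):
        pair = P[key]
        fam_a, fam_b = sorted(pair.families)
        for donor, acceptor in ((fam_a, fam_b), (fam_b, fam_a)):
            verdicts.append(
                test_direction(pair, donor, acceptor, scores, tree, lookup,
                               clean, alpha=alpha, background_cap=background_cap,
                               rng=rng)
            )
    result = SRDResult(P=P, N=N, clean=clean, verdicts=verdicts)
    result.R = [v for v in verdicts if v.passed]
    return result
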