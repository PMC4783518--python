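"""Downstream characterization of detected remolding events.

Covers the anticodon-change classification (positions, nucleotides,
two-/four-codon family transitions), donor-acceptor locus geometry on the
circular mitogenome, codon-usage shifts relative to an unremolded close
relative, group-specific alignment columns (the 0.5-bit rule), and the
pre-duplication / pre-deletion intermediate-state checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from .core import Alignment, SpeciesTree, TRNAGene

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: NCBI translation table ids: 2 = vertebrate mito, 5 = invertebrate mito.
DEFAULT_CODE_TABLE = 2


def reverse_complement(rna: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(rna))


def anticodon_to_codon(anticodon: str) -> str:
    """The codon read by an anticodon (reverse complement, 5'->3')."""
    return reverse_complement(anticodon)


def codon_box(codon: str) -> tuple[str, ...]:
    """The four codons sharing the first two nucleotides."""
    return tuple(codon[:2] + n for n in "UCAG")


def _family_size(codon: str, table_id: int) -> int:
    """Number of codons in the box encoding the same meaning as ``codon``.

    Stop codons form their own 'meaning'.  Mitochondrial boxes split into
    two- and four-codon families; sizes 1-2 are classed as 'two', 3-4 as
    'four'.
    """
    table = CodonTable.unambiguous_rna_by_id[table_id]
    def meaning(c):
        return table.forward_table.get(c, "*")
    return sum(1 for c in codon_box(codon) if meaning(c) == meaning(codon))


@dataclass
class AnticodonChange:
    donor_anticodon: str
    acceptor_anticodon: str
    changed_positions: tuple[int, ...]        # 1-based; position 1 = wobble
    substitutions: tuple[str, ...]            # e.g. ("A→C",)
    family_transition: str                    # e.g. "two→four"


def classify_anticodon_change(donor: TRNAGene | str, acceptor: TRNAGene | str,
                              table_id: int = DEFAULT_CODE_TABLE) -> AnticodonChange:
    """Compare donor and acceptor anticodons position by position.

    Position 1 is the wobble position (anticodon position 34, pairing with
    codon position 3).  The codon-family transition is derived from the
    degeneracy of each anticodon's codon in the configured mitochondrial
    genetic code.
    """
    a = donor.anticodon if isinstance(donor, TRNAGene) else donor
    b = acceptor.anticodon if isinstance(acceptor, TRNAGene) else acceptor
    if len(a) != 3 or len(b) != 3:
        raise ValueError("anticodons must be 3 nt")
    if a == b:
        raise ValueError("identical anticodons: not an alloacceptor change")
    changed = tuple(i + 1 for i in range(3) if a[i] != b[i])
    subs = tuple(f"{a[i - 1]}→{b[i - 1]}" for i in changed)

    def family(ac):
        size = _family_size(anticodon_to_codon(ac), table_id)
        return "two" if size <= 2 else "four"

    return AnticodonChange(
        donor_anticodon=a, acceptor_anticodon=b,
        changed_positions=changed, substitutions=subs,
        family_transition=f"{family(a)}→{family(b)}",
    )


@dataclass
class LocusGeometry:
    separation: int              # nucleotides, minimum of the two arcs
    n_intervening: int           # genes on the arc with fewer genes
    same_strand: bool

    @property
    def adjacent(self) -> bool:
        return self.n_intervening == 0


def _arc_gap(end_a: int, start_b: int, genome_length: int) -> int:
    return (start_b - end_a) % genome_length


def _in_arc(pos: int, start: int, end: int, genome_length: int) -> bool:
    """Is ``pos`` inside the arc running from start to end (clockwise)?"""
    return (pos - start) % genome_length < (end - start) % genome_length


def locus_geometry(donor: TRNAGene, acceptor: TRNAGene,
                   all_genes) -> LocusGeometry:
    """Circular-genome geometry of the donor/acceptor loci.

    Separation is the boundary-to-boundary length of the smaller arc
    between the two annotations; the intervening count uses the arc with
    fewer annotated genes.  Overlapping annotations give separation 0 with
    a warning.
    """
    if donor.species != acceptor.species or \
            donor.genome_length != acceptor.genome_length:
        raise ValueError("donor and acceptor must come from the same genome")
    G = donor.genome_length
    s1, e1 = donor.start % G, donor.end % G
    s2, e2 = acceptor.start % G, acceptor.end % G
    overlap = (_in_arc(s2, s1, e1, G) or _in_arc(s1, s2, e2, G)
               or (s1 == s2))
    if overlap:
        logger.warning("overlapping annotations %s / %s; separation 0",
                       donor.gene_id, acceptor.gene_id)
        separation = 0
    else:
        separation = min(_arc_gap(e1, s2, G), _arc_gap(e2, s1, G))
    counts = [0, 0]
    for g in all_genes:
        if g.gene_id in (donor.gene_id, acceptor.gene_id):
            continue
        if g.species != donor.species:
            continue
        mid = (g.start + g.length // 2) % G
        if _in_arc(mid, e1 % G, s2, G):
            counts[0] += 1
        elif _in_arc(mid, e2 % G, s1, G):
            counts[1] += 1
    return LocusGeometry(
        separation=separation,
        n_intervening=min(counts),
        same_strand=donor.strand == acceptor.strand,
    )


@dataclass
class CodonShift:
    """Normalized codon-usage differences focal vs reference species."""

    acceptor_codon: str
    delta_codon: float           # for the codon read by the acceptor
    delta_box: float             # for the donor's codon box
    reference: str | None = None


def normalized_difference(f1: float, f2: float) -> float:
    """(f1 - f2) / (f1 + f2); zero when both frequencies vanish."""
    if f1 == 0 and f2 == 0:
        return 0.0
    return (f1 - f2) / (f1 + f2)


def codon_shift(focal_counts: dict[str, int], reference_counts: dict[str, int],
                change: AnticodonChange,
                reference: str | None = None) -> CodonShift:
    """Codon-usage shift for one remolding event.

    Compares the frequency of the precise codon read by the acceptor
    anticodon, and of the donor's entire codon box, between the focal
    species and an unremolded close relative.
    """
    tot_f = sum(focal_counts.values())
    tot_r = sum(reference_counts.values())
    if tot_f == 0 or tot_r == 0:
        raise ValueError("empty codon count table")

    def freq(counts, total, codon):
        return counts.get(codon, 0) / total

    acc_codon = anticodon_to_codon(change.acceptor_anticodon)
    delta_codon = normalized_difference(
        freq(focal_counts, tot_f, acc_codon),
        freq(reference_counts, tot_r, acc_codon),
    )
    box = codon_box(anticodon_to_codon(change.donor_anticodon))
    delta_box = normalized_difference(
        sum(freq(focal_counts, tot_f, c) for c in box),
        sum(freq(reference_counts, tot_r, c) for c in box),
    )
    return CodonShift(acceptor_codon=acc_codon, delta_codon=delta_codon,
                      delta_box=delta_box, reference=reference)


@dataclass
class QuantileReport:
    flags: list                  # per event: "low", "high" or None
    p_value: float               # one-sided rank-sum: remolded < null
    reliable: bool               # null sample large enough for quantiles


def quantile_flags(shifts_remolded, shifts_null,
                   lower: float = 0.05, upper: float = 0.95) -> QuantileReport:
    """Flag events outside the empirical null quantiles.

    ``shifts_*`` are normalized differences (floats).  Also reports a
    one-sided two-sample rank-sum p-value for the hypothesis that remolded
    shifts are smaller than unremolded ones.
    """
    null = np.asarray(list(shifts_null), dtype=float)
    rem = np.asarray(list(shifts_remolded), dtype=float)
    reliable = null.size >= 20
    if not reliable:
        logger.warning("null distribution has %d values; quantile flags "
                       "unreliable", null.size)
    if rem.size == 0 or null.size == 0:
        return QuantileReport(flags=[], p_value=1.0, reliable=reliable)
    qlo, qhi = np.quantile(null, [lower, upper])
    flags = ["low" if x < qlo else "high" if x > qhi else None for x in rem]
    p = stats.mannwhitneyu(rem, null, alternative="less").pvalue
    return QuantileReport(flags=flags, p_value=float(p), reliable=reliable)


@dataclass
class ColumnSpecificity:
    flagged: np.ndarray          # bool per column
    masked: np.ndarray           # bool per column (unreliable columns)
    bits: dict                   # group -> (n_columns, 4) bit table
    groups: tuple


def column_specificity(alignment: Alignment,
                       threshold: float = 0.5) -> ColumnSpecificity:
    """Group-specific alignment columns by the information-content rule.

    Per group and column the information content is ``I = 2 - H`` (log2,
    gaps excluded); a nucleotide's bit value is its frequency times I
    (sequence-logo convention).  A column is group-specific iff group 1
    has a nucleotide strictly above the threshold and group 2 has a
    *different* nucleotide strictly above it.  Columns with more than 50%
    gaps in either group are masked.
    """
    if not alignment.groups:
        raise ValueError("alignment must carry group tags")
    tags = sorted(set(alignment.groups.values()))
    if len(tags) != 2:
        raise ValueError(f"column specificity needs exactly 2 groups, got {tags}")
    L = alignment.n_columns
    nts = "ACGU"
    bits = {g: np.zeros((L, 4)) for g in tags}
    masked = np.zeros(L, dtype=bool)
    rows_by_group = {g: [] for g in tags}
    for sid, row in zip(alignment.ids, alignment.rows):
        rows_by_group[alignment.groups[sid]].append(row)
    for g in tags:
        if not rows_by_group[g]:
            raise ValueError(f"group {g!r} has no sequences")
    for col in range(L):
        for g in tags:
            chars = [r[col] for r in rows_by_group[g]]
            ungapped = [c for c in chars if c in nts]
            if len(ungapped) == 0 or len(ungapped) <= len(chars) / 2:
                masked[col] = True
                continue
            freqs = np.array([ungapped.count(n) / len(ungapped) for n in nts])
            nz = freqs[freqs > 0]
            info = 2.0 + float((nz * np.log2(nz)).sum())
            bits[g][col] = freqs * info
    flagged = np.zeros(L, dtype=bool)
    g1, g2 = tags
    for col in range(L):
        if masked[col]:
            continue
        top1 = [n for n in range(4) if bits[g1][col, n] > threshold]
        top2 = [n for n in range(4) if bits[g2][col, n] > threshold]
        flagged[col] = any(a != b for a in top1 for b in top2)
    return ColumnSpecificity(flagged=flagged, masked=masked, bits=bits,
                             groups=tuple(tags))


def pre_state_check(tree: SpeciesTree, event_node_id: int,
                    copy_numbers: dict[str, dict[str, int]],
                    donor: str, acceptor: str) -> dict[str, str]:
    """Intermediate-state check for the duplication-mutation-loss mechanism.

    For the sister clade of the event edge and the sister of its parent:
    ``pre_duplication`` iff every member species lacks the acceptor family;
    ``pre_deletion`` iff every member carries >= 2 donor copies; otherwise
    ``neither``; ``unknown`` when a member species has no annotation entry.
    ``copy_numbers`` maps species -> family -> gene copy count.
    """
    node = tree.node(event_node_id)

    def sister_of(n):
        if n.parent is None:
            return None
        sibs = [c for c in n.parent.children if c is not n]
        return sibs[0] if sibs else None

    clades = {}
    sis = sister_of(node)
    if sis is not None:
        clades["sister"] = sis
    if node.parent is not None:
        aunt = sister_of(node.parent)
        if aunt is not None:
            clades["parent_sister"] = aunt

    out = {}
    for label, clade in clades.items():
        members = sorted(clade.leaf_names())
        if any(sp not in copy_numbers for sp in members):
            out[label] = "unknown"
            continue
        acc_absent = all(copy_numbers[sp].get(acceptor, 0) == 0
                         for sp in members)
        donor_dup = all(copy_numbers[sp].get(donor, 0) >= 2
                        for sp in members)
        out[label] = ("pre_duplication" if acc_absent
                      else "pre_deletion" if donor_dup else "neither")
    return out
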