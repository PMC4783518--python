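"""Asymmetric bitscore function S(P | X_i) between tRNA genes.

The detection stage only consumes a bitscore interface: an asymmetric,
additive-over-sets log-odds score (in bits) of a target tRNA against a
model built from one gene.  Scores computed externally with a covariance
model aligner can be imported from TSV (:func:`import_scores`); the
built-in scorer is a single-sequence, structure-informed profile:

* match score at model position p for nucleotide n is
  ``log2(q(n|p) / b(n))`` with ``q`` putting weight 1-epsilon on the model
  nucleotide and epsilon/3 elsewhere, background ``b`` uniform;
* a model position that is base-paired in the model gene's secondary
  structure earns an additive bonus (default +0.5 bit) when the aligned
  target nucleotide equals the model nucleotide.  The bonus is applied per
  position, which keeps alignment scoring local and the dynamic program
  exact;
* targets are aligned to the model globally with affine gap costs (Gotoh).

Insertions relative to the model score the background log-odds, i.e. zero
bits, beyond the affine gap cost.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .core import TRNAGene, parse_dotbracket

logger = logging.getLogger(__name__)

NT_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
_MISSING = 4  # N or any non-ACGU character: scores zero everywhere


@dataclass(frozen=True)
class ScoringParams:
    """Configuration of the built-in profile scorer (all values in bits)."""

    epsilon: float = 0.15
    pair_bonus: float = 0.5
    gap_open: float = 3.0
    gap_extend: float = 1.0


@dataclass
class GeneModel:
    """Position-specific scoring profile built from a single gene."""

    model_gene_id: str
    match_scores: np.ndarray          # (L, 4) bits
    paired: np.ndarray                # (L,) bool
    partner: np.ndarray               # (L,) int, -1 when unpaired
    gap_open: float
    gap_extend: float
    model_seq: str

    def __post_init__(self):
        if self.match_scores.shape != (len(self.model_seq), 4):
            raise ValueError("match score table shape mismatch")
        if not np.all(np.isfinite(self.match_scores)):
            raise ValueError("non-finite match scores")

    @property
    def n_positions(self) -> int:
        return len(self.model_seq)

    @property
    def extended_scores(self) -> np.ndarray:
        """(L, 5) table with a zero column for missing characters."""
        return np.hstack([self.match_scores, np.zeros((self.n_positions, 1))])


def encode(seq: str) -> np.ndarray:
    return np.array([NT_INDEX.get(c, _MISSING) for c in seq], dtype=np.int64)


def build_model(gene: TRNAGene, params: ScoringParams | None = None) -> GeneModel:
    """Build the profile model of one gene (its ``covariance-model`` stand-in)."""
    params = params or ScoringParams()
    if not gene.sequence:
        raise ValueError("cannot build a model from an empty sequence")
    L = len(gene.sequence)
    eps = params.epsilon
    on = math.log2((1.0 - eps) / 0.25)
    off = math.log2((eps / 3.0) / 0.25)
    scores = np.full((L, 4), off)
    enc = encode(gene.sequence)
    paired = np.zeros(L, dtype=bool)
    partner = np.full(L, -1, dtype=np.int64)
    if gene.structure is not None:
        for i, j in parse_dotbracket(gene.structure):
            paired[i] = paired[j] = True
            partner[i], partner[j] = j, i
    for p in range(L):
        if enc[p] == _MISSING:
            scores[p, :] = 0.0  # uninformative position
            continue
        scores[p, enc[p]] = on
        if paired[p]:
            scores[p, enc[p]] += params.pair_bonus
    return GeneModel(
        model_gene_id=gene.gene_id,
        match_scores=scores,
        paired=paired,
        partner=partner,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
        model_seq=gene.sequence,
    )


def _gotoh_batch(model: GeneModel, encoded: list[np.ndarray]) -> np.ndarray:
    """Score several targets against one model in a single vectorized DP.

    Global alignment, affine gaps, gap-type switches allowed.  The
    horizontal (model-consuming) state is filled per row with a running
    maximum, exploiting that an affine gap cost is linear in the gap end.
    """
    open_, ext = model.gap_open, model.gap_extend
    L = model.n_positions
    table = model.extended_scores  # (L, 5)
    lens = np.array([len(s) for s in encoded])
    T = len(encoded)
    n = int(lens.max()) if T else 0
    pad = np.full((T, n), _MISSING, dtype=np.int64)
    for t, s in enumerate(encoded):
        pad[t, : len(s)] = s

    jj = np.arange(L)
    M = np.full((T, L + 1), -np.inf)
    M[:, 0] = 0.0
    D = np.full((T, L + 1), -np.inf)
    D[:, 1:] = -(open_ + jj * ext)
    I = np.full((T, L + 1), -np.inf)
    out = np.full(T, np.nan)
    if (lens == 0).any():
        out[lens == 0] = max(0.0, -(open_ + (L - 1) * ext)) if L else 0.0

    for i in range(1, n + 1):
        chars = pad[:, i - 1]
        emit = table[:, chars].T                       # (T, L)
        In = np.maximum(np.maximum(M, D) - open_, I - ext)
        In[:, 0] = -(open_ + (i - 1) * ext)
        prev = np.maximum(np.maximum(M, D), I)
        Mn = np.full((T, L + 1), -np.inf)
        Mn[:, 1:] = emit + prev[:, :-1]
        base = np.maximum(Mn, In)[:, :-1] + jj * ext
        run = np.maximum.accumulate(base, axis=1)
        Dn = np.full((T, L + 1), -np.inf)
        Dn[:, 1:] = run - open_ - jj * ext
        M, D, I = Mn, Dn, In
        fin = lens == i
        if fin.any():
            out[fin] = np.maximum(np.maximum(M[fin, L], D[fin, L]), I[fin, L])
    return out


def score(target: TRNAGene | str, model: GeneModel) -> float:
    """Bitscore of one target against one model (may be negative)."""
    seq = target.sequence if isinstance(target, TRNAGene) else target
    return float(_gotoh_batch(model, [encode(seq)])[0])


def align_to_model(target: TRNAGene | str, model: GeneModel) -> tuple[str, float]:
    """Model-column alignment of a target (insertions dropped).

    Returns a string of length ``model.n_positions`` — the target character
    matched to each model position, ``-`` where the model position is
    deleted — plus the alignment score.  Traceback ties prefer
    match > delete > insert.  Used to build the combined donor-model
    alignment consumed by the likelihood stage.
    """
    seq = target.sequence if isinstance(target, TRNAGene) else target
    enc = encode(seq)
    open_, ext = model.gap_open, model.gap_extend
    L = model.n_positions
    table = model.extended_scores
    n = len(enc)
    NEG = -np.inf
    M = np.full((n + 1, L + 1), NEG)
    D = np.full((n + 1, L + 1), NEG)
    I = np.full((n + 1, L + 1), NEG)
    M[0, 0] = 0.0
    for j in range(1, L + 1):
        D[0, j] = -(open_ + (j - 1) * ext)
    for i in range(1, n + 1):
        I[i, 0] = -(open_ + (i - 1) * ext)
    for i in range(1, n + 1):
        for j in range(0, L + 1):
            if j > 0:
                M[i, j] = table[j - 1, enc[i - 1]] + max(
                    M[i - 1, j - 1], D[i - 1, j - 1], I[i - 1, j - 1]
                )
                D[i, j] = max(M[i, j - 1] - open_, I[i, j - 1] - open_,
                              D[i, j - 1] - ext)
            I[i, j] = max(I[i, j], M[i - 1, j] - open_, D[i - 1, j] - open_,
                          I[i - 1, j] - ext)
    i, j = n, L
    best = max(M[i, j], D[i, j], I[i, j])
    state = "M" if M[i, j] == best else ("D" if D[i, j] == best else "I")
    cols = ["-"] * L
    while i > 0 or j > 0:
        if state == "M":
            cols[j - 1] = seq[i - 1]
            prev = max(M[i - 1, j - 1], D[i - 1, j - 1], I[i - 1, j - 1])
            state = ("M" if M[i - 1, j - 1] == prev
                     else "D" if D[i - 1, j - 1] == prev else "I")
            i, j = i - 1, j - 1
        elif state == "D":
            if M[i, j - 1] - open_ == D[i, j]:
                state = "M"
            elif D[i, j - 1] - ext == D[i, j]:
                state = "D"
            else:
                state = "I"
            j -= 1
        else:
            if M[i - 1, j] - open_ == I[i, j]:
                state = "M"
            elif D[i - 1, j] - open_ == I[i, j]:
                state = "D"
            else:
                state = "I"
            i -= 1
        if i == 0 and j == 0:
            break
        if j == 0:
            state = "I"
        elif i == 0:
            state = "D"
    return "".join(cols), float(best)


class SimilarityMatrix:
    """Sparse map (model_gene_id, target_gene_id) -> bitscore.

    Generally asymmetric; set scores are sums over members, matching the
    per-sequence bitscore reporting of structural aligners.
    """

    def __init__(self):
        self._scores: dict[tuple[str, str], float] = {}

    def __len__(self):
        return len(self._scores)

    def __contains__(self, key):
        return key in self._scores

    def items(self):
        return self._scores.items()

    def set(self, model_gene_id: str, target_gene_id: str, bits: float):
        self._scores[(model_gene_id, target_gene_id)] = float(bits)

    def get(self, model_gene_id: str, target_gene_id: str) -> float:
        return self._scores[(model_gene_id, target_gene_id)]

    def score_set(self, member_ids, model_gene_id: str) -> float:
        """S({...} | model) = sum of per-member bitscores."""
        return sum(self.get(model_gene_id, t) for t in member_ids)

    def to_tsv(self, path: str):
        with open(path, "w") as fh:
            fh.write("model_gene_id\ttarget_gene_id\tbits\n")
            for (m, t), b in sorted(self._scores.items()):
                fh.write(f"{m}\t{t}\t{b:.6f}\n")


def import_scores(path: str) -> SimilarityMatrix:
    """Load externally computed bitscores (e.g. from a CM aligner) from TSV."""
    matrix = SimilarityMatrix()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: k for k, name in enumerate(header)}
        for col in ("model_gene_id", "target_gene_id", "bits"):
            if col not in idx:
                raise ValueError(f"score table misses column {col!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            m, t = fields[idx["model_gene_id"]], fields[idx["target_gene_id"]]
            try:
                bits = float(fields[idx["bits"]])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric bitscore {fields[idx['bits']]!r}"
                ) from None
            if (m, t) in matrix:
                logger.warning("duplicate score row for (%s, %s); last wins", m, t)
            matrix.set(m, t, bits)
    return matrix


class SimilarityScorer:
    """Lazily computed similarity matrix backed by the built-in scorer.

    Implements the same ``get``/``score_set`` interface as
    :class:`SimilarityMatrix` but computes missing entries on demand,
    batching all targets requested against one model into a single
    vectorized DP.
    """

    def __init__(self, genes, params: ScoringParams | None = None):
        self.params = params or ScoringParams()
        self.genes: dict[str, TRNAGene] = {g.gene_id: g for g in genes}
        self.matrix = SimilarityMatrix()
        self._models: dict[str, GeneModel] = {}
        self._encoded: dict[str, np.ndarray] = {}

    def model(self, gene_id: str) -> GeneModel:
        if gene_id not in self._models:
            self._models[gene_id] = build_model(self.genes[gene_id], self.params)
        return self._models[gene_id]

    def _enc(self, gene_id: str) -> np.ndarray:
        if gene_id not in self._encoded:
            self._encoded[gene_id] = encode(self.genes[gene_id].sequence)
        return self._encoded[gene_id]

    def ensure(self, model_gene_id: str, target_gene_ids):
        todo = [t for t in target_gene_ids if (model_gene_id, t) not in self.matrix]
        if not todo:
            return
        values = _gotoh_batch(self.model(model_gene_id), [self._enc(t) for t in todo])
        for t, v in zip(todo, values):
            self.matrix.set(model_gene_id, t, float(v))

    def get(self, model_gene_id: str, target_gene_id: str) -> float:
        if (model_gene_id, target_gene_id) not in self.matrix:
            self.ensure(model_gene_id, [target_gene_id])
        return self.matrix.get(model_gene_id, target_gene_id)

    def score_set(self, member_ids, model_gene_id: str) -> float:
        member_ids = list(member_ids)
        self.ensure(model_gene_id, member_ids)
        return self.matrix.score_set(member_ids, model_gene_id)


def score_matrix(genes, params: ScoringParams | None = None) -> SimilarityScorer:
    """Compute the within-species all-vs-all score blocks.

    Returns a :class:`SimilarityScorer` whose matrix holds every
    within-species (model, target) combination; cross-species scores needed
    by the directional criteria are computed lazily through the same object.
    """
    scorer = SimilarityScorer(genes, params)
    by_species: dict[str, list[str]] = {}
    for g in genes:
        by_species.setdefault(g.species, []).append(g.gene_id)
    for ids in by_species.values():
        for m in ids:
            scorer.ensure(m, ids)
    return scorer
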