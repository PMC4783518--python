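# Methods notes

This note records the models, parameter choices and numerical decisions
behind the package, including the places where the design was genuinely
open and the package's own conventions apply.

## Bitscore surrogate

The detection stage consumes only a bitscore interface: an asymmetric,
additive-over-sets log-odds score S(P | X_i) in bits.  Scores produced by
a covariance-model aligner can be imported verbatim from TSV
(`similarity.import_scores`), which is the highest-fidelity path for real
data.  The built-in surrogate is a single-sequence, structure-informed
profile:

* match score at position p for nucleotide n: `log2(q(n|p) / 0.25)` with
  q putting 1 − ε on the model nucleotide and ε/3 elsewhere
  (ε default 0.15 ⇒ on-model score ≈ 1.77 bits);
* a base-paired model position gains `pair_bonus` (default 0.5 bit) when
  the aligned target nucleotide equals the model nucleotide.  The bonus
  is **per position**, not conditional on the partner position also
  matching: a partner-conditional bonus is non-local, cannot be maximized
  exactly by a Gotoh recursion, and would break the equivalence between
  the scorer and exhaustive alignment enumeration that the test suite
  verifies.  At the self-score the two conventions coincide;
* global alignment with affine gaps (open 3 bits, extend 1 bit,
  insertions emit background odds = 0 bits).  Gap-type switches are
  allowed.  The DP is vectorized over targets and over model columns (the
  affine horizontal state is a running maximum because the gap cost is
  linear in the gap end), which makes a 22 × 22 within-species block a
  few tens of milliseconds.

These defaults are not tuned to any dataset; they are generic log-odds
settings.  The scorer is *not* a covariance model: it has no emission
covariation between paired columns and no calibrated E-values.

## Candidate sets and "clean" genes

𝒫 contains, per gene X_i, its maximum-scoring alloacceptor partner when
the Grubbs test of the maximum is significant at α = 0.05.  The Grubbs
p-value follows the closed form p = n·P(T₍n−2₎ ≥ t) with
t = √(n(n−2)G² / ((n−1)² − nG²)), clamped to [0, 1] and set to 0 when G
reaches its attainable maximum.  Zero-variance or n < 3 distributions are
reported as untestable (treated as p = 1 upstream).

𝒩 contains the maximum pair whenever the maximum side is the qualitative
outlier side (max − mean > mean − min), with no significance threshold.
A gene is **unclean** when *its own* score distribution flagged its
maximum partner.  Marking both members of every 𝒩 pair would leave
essentially no clean genes in a clade-sized dataset (~25% measured on
12-species simulations), making the reference species C_XY(i)
nonexistent; own-test marking loses nothing for true remoldings, because
both partners of a real event flag each other through their own maxima.

Backgrounds for the directional criteria are built over all clean species
in the dataset and capped at 500 values (seeded subsample) for
tractability.  The Wilcoxon signed-rank test is one-sample (background
versus the observed scalar), exact up to n = 25 via convolution over
doubled midranks — ties are handled exactly, which is why the test is
implemented here rather than delegated — and a continuity-corrected
normal approximation above.  No multiple-testing correction is applied
across species.

## MLRD

The doubled gene tree joins a donor copy and an acceptor copy of the
species tree under one root; species missing a gene are pruned from that
copy only.  Moves are enumerated for every acceptor-copy node except the
copy root (moving it reproduces the baseline's unrooted shape), giving
2n − 2 candidates.

**Evaluation uses fixed branch lengths by default.**  Every topology is
scored with the species-tree branch lengths multiplied by a single global
rate scale (ML-fitted on the baseline, bounded Brent on the log scale),
unit placeholders of 0.1 on taxonomy trees; the root bridge joining the
two copies is initialized at 5 expected substitutions/site (the two
families share at most a very distant ancestor) and regraft junction
edges at 0.1.  Free per-branch optimization is available
(`optimize=True`) but is *not* the default because it de-calibrates the
null: a falsely moved clade can escape through a saturating attachment
branch, so the maximum over ~2n moves exceeds the baseline by pure
placement noise; and coordinate ascent can decouple the two copies
through deep within-copy edges instead of the root bridge, an observable
local optimum.  With fixed lengths all candidates are compared on equal
footing and the no-event profile stays below baseline.

The likelihood engine implements the pruning algorithm for reversible
models (JC69, GTR with empirical or supplied frequencies, optional
discrete-Γ with mean-per-quantile category rates), gaps and N as missing
data.  Branch-length optimization, when requested, is round-robin: each
sweep recomputes post-order partials and then walks the tree in
pre-order, keeping up-conditionals incremental so that every single-edge
Brent step is exact for the current state of all other edges (monotone by
construction); per-edge optimization uses staged geometric grids over
[10⁻⁶, 10] followed by a bounded Brent refine.  Convergence: logL
improvement < 10⁻⁴ or 20 sweeps.  Likelihoods are computed in float64
without scaling, adequate for the tens-of-leaves, ~70-site trees this
tool targets; site likelihoods are floored at 10⁻³⁰⁰.

The combined alignment defaults to the raw sequences when all genes have
equal length, and otherwise projects every gene onto the model columns of
a donor gene's profile (insertions dropped), mirroring a model-based
combined alignment.

## Simulator

The generator emulates the study conditions at clade scale: a Yule tree
(birth rate 1, tips extended by the waiting time to the next unrealized
speciation so the youngest cherry is not zero-length), 22 tRNA families
evolving independently at rate 0.05 substitutions/site/unit from random
68–72 nt cloverleaf ancestors (acceptor stem 7 bp, D stem 4 bp, anticodon
and T stems 5 bp, variable loop 0–4 nt; anticodon fixed at template
positions 34–36), JC substitutions with the anticodon frozen — family
identity is stable under background evolution.  The remolding event
replaces the acceptor lineage's sequence at the event point with the
donor lineage's current sequence carrying the acceptor anticodon
(duplication and loss collapsed to an instantaneous swap).  Genes are
laid out on a circular genome with ~400 nt spacing; below the event the
acceptor gene is placed directly downstream of the donor on the donor's
strand, matching the local-duplication geometry.  Codon-count tables draw
3800 codons per species from a shared Dirichlet(5) base usage over the
sense codons of the configured mitochondrial code; below the event the
acceptor's codon probability is multiplied by 1 − m and the donor's codon
box by 1 − m/2 before renormalization, so the expected normalized
difference at m = 0.5 is ≈ −1/3.

The simulator also provides the ground-truth combined alignment on the
template columns (variable loop padded to 4), i.e. the alignment a
correct structural model would produce.  The benchmarks use it: aligning
simulated genes of *different* var-loop lengths through the profile
surrogate places gaps arbitrarily for unrelated sequences and corrupts
within-family homology, which is a property of the surrogate aligner, not
of the detectors.

What the simulator does **not** emulate: insertions/deletions during
background evolution, structure-constrained (paired-site) substitution,
armless or truncated tRNAs, gene loss and duplication outside the
implanted event, genome rearrangement beyond donor/acceptor placement,
and base-compositional bias.  Passing tests therefore demonstrate
correctness of the statistical machinery and recoverability of implanted
events under idealized sequence evolution — not performance on real
annotation noise.

## Problem sizes used by tests and the reproduction script

Simulated clades use 8–12 species; SRD benchmarks run 50 replicates with
an implanted event and 50 without; MLRD benchmarks 50 with and 100
without; codon-shift recovery aggregates 20 replicates.  Oracle checks
use 200 random trees with ≤ 5 leaves and ≤ 10 sites (likelihood), 100
random vectors (Grubbs) and full 2ⁿ enumerations up to n = 12
(signed-rank).  These sizes give stable pass/fail behaviour at desk
scale; all randomness is seeded.

## Known limitations

* One remolding event per analysis is assumed; nested or repeated events
  require iteratively removing detected remolded subtrees.
* SRD's directional step is deliberately conservative: when no species
  with both families clean exists (common in small clades whose
  family-similarity structure is shared clade-wide), the candidate is
  reported untestable rather than guessed — expect false negatives, not
  false positives.
* The built-in scorer's alignments of *unrelated* sequences are
  arbitrary; for real data the import path (external CM bitscores and
  alignments) is preferred.
* Grubbs and Wilcoxon p-values are not corrected for multiple testing
  across genes or species.
* The polytomy resolution rule (sort children by smallest leaf label,
  nest left-to-right) is this package's convention for reproducible node
  ids on taxonomy trees.
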