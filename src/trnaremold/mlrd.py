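"""Maximum-likelihood remolding detection (MLRD).

A remolding X ~> Y on the edge leading to a clade makes the trnY genes of
that clade homologous to trnX.  Given a species tree, the expected gene
phylogeny is scored directly instead of reconstructed: a *doubled* gene
tree joins a donor copy and an acceptor copy of the species tree under a
common root, and for every node N in the acceptor copy a candidate
topology is produced by regrafting the clade below N next to its donor
counterpart.  Each candidate is scored by its optimized pruning
log-likelihood on the combined donor/acceptor alignment; moves scoring
above the unmoved baseline support a remolding on the corresponding edge.

A single remolding event per analysis is assumed; nested events should be
handled by iteratively removing detected remolded subtrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as _opt

from .core import SpeciesTree, TreeNode, TRNAGene
from .phylo import LikelihoodEngine, SubstitutionModel
from .similarity import ScoringParams, align_to_model, build_model

logger = logging.getLogger(__name__)

DEFAULT_BL = 0.1
#: Initial length of the two root edges joining the copies: the donor and
#: acceptor families share at most an extremely distant ancestor, so the
#: bridge starts long; branch optimization can shorten it if the data
#: disagree.  A short initial bridge invites a local optimum in which deep
#: within-copy edges saturate instead, decoupling each copy internally.
ROOT_BL = 5.0


def _copy_species_tree(tree: SpeciesTree, role: str,
                       keep_species) -> TreeNode | None:
    """Clone the species tree for one gene copy, pruning absent species.

    Leaves are renamed ``role::species``; every node records its species
    tree node id and role in ``meta``.  Degree-one internals left by
    pruning are suppressed (lengths merged).
    """

    def clone(node):
        new = TreeNode(
            name=f"{role}::{node.name}" if node.is_leaf else None,
            length=(node.length if tree.has_branch_lengths else DEFAULT_BL),
        )
        new.meta = {"sp_node_id": node.node_id, "role": role,
                    "edge_kind": "species"}
        for child in node.children:
            sub = clone(child)
            if sub is not None:
                new.add_child(sub)
        if node.is_leaf:
            return new if node.name in keep_species else None
        if not new.children:
            return None
        if len(new.children) == 1:
            child = new.children[0]
            child.length = (child.length or 0.0) + (new.length or 0.0)
            child.parent = None
            return child
        return new

    return clone(tree.root)


@dataclass
class DoubledGeneTree:
    """Two copies of the species tree under a common root."""

    root: TreeNode
    donor_root: TreeNode
    acceptor_root: TreeNode
    leaf_seqs: dict[str, str]

    def acceptor_nodes(self):
        """Movable acceptor-copy nodes (the copy root itself is excluded:
        moving it merely reproduces the baseline unrooted shape)."""
        return [n for n in self.acceptor_root.postorder()
                if n is not self.acceptor_root]


def build_doubled_tree(tree: SpeciesTree,
                       donor_genes: dict[str, TRNAGene],
                       acceptor_genes: dict[str, TRNAGene],
                       aligned: dict[str, str] | None = None) -> DoubledGeneTree:
    """Join donor and acceptor copies of the species tree under one root.

    ``donor_genes`` / ``acceptor_genes`` map species to genes; species
    lacking a gene are pruned from that copy only.  ``aligned`` optionally
    maps gene ids to aligned rows (defaults to raw sequences, which must
    then be of equal length).
    """
    donor = _copy_species_tree(tree, "donor", set(donor_genes))
    acceptor = _copy_species_tree(tree, "acceptor", set(acceptor_genes))
    for role, sub, genes in (("donor", donor, donor_genes),
                             ("acceptor", acceptor, acceptor_genes)):
        if sub is None or len(sub.leaves()) < 2:
            raise ValueError(f"fewer than 2 species carry the {role} gene")
    root = TreeNode()
    root.meta = {"role": "root", "sp_node_id": None}
    for sub in (donor, acceptor):
        sub.length = ROOT_BL
        sub.meta["edge_kind"] = "bridge"
        root.add_child(sub)
    leaf_seqs = {}
    for role, genes in (("donor", donor_genes), ("acceptor", acceptor_genes)):
        for sp, gene in genes.items():
            row = (aligned[gene.gene_id] if aligned is not None
                   else gene.sequence)
            leaf_seqs[f"{role}::{sp}"] = row
    present = {leaf.name for leaf in root.leaves()}
    leaf_seqs = {k: v for k, v in leaf_seqs.items() if k in present}
    return DoubledGeneTree(root=root, donor_root=donor,
                           acceptor_root=acceptor, leaf_seqs=leaf_seqs)


def _find(root: TreeNode, role: str, sp_node_id: int) -> TreeNode | None:
    for node in root.postorder():
        if node.meta.get("role") == role and \
                node.meta.get("sp_node_id") == sp_node_id:
            return node
    return None


def _detach(node: TreeNode):
    """Remove ``node`` from its parent and suppress the degree-2 remnant."""
    parent = node.parent
    parent.children.remove(node)
    node.parent = None
    if len(parent.children) == 1 and parent.parent is not None:
        child = parent.children[0]
        grand = parent.parent
        if child.meta.get("edge_kind") == parent.meta.get("edge_kind"):
            child.length = (child.length or 0.0) + (parent.length or 0.0)
        else:
            # merging a species edge into the root bridge: the remnant
            # still separates the two families, keep the bridge scale
            child.length = ROOT_BL
            child.meta["edge_kind"] = "bridge"
        grand.children[grand.children.index(parent)] = child
        child.parent = grand


def _regraft_next_to(moved: TreeNode, counterpart: TreeNode):
    """Make ``moved`` and ``counterpart`` children of a new node that takes
    the counterpart's place under its parent."""
    parent = counterpart.parent
    joint = TreeNode()
    joint.meta = {"role": counterpart.meta.get("role"), "sp_node_id": None,
                  "edge_kind": counterpart.meta.get("edge_kind")}
    joint.length = counterpart.length
    parent.children[parent.children.index(counterpart)] = joint
    joint.parent = parent
    counterpart.length = DEFAULT_BL
    counterpart.meta["edge_kind"] = "junction"
    moved.length = DEFAULT_BL
    moved.meta["edge_kind"] = "junction"
    joint.add_child(counterpart)
    joint.add_child(moved)


def enumerate_move_topologies(dtree: DoubledGeneTree):
    """One regrafted topology per movable acceptor-copy node.

    For a strictly bifurcating acceptor copy with ``n`` leaves this yields
    ``2 n - 2`` topologies.  Nodes whose donor counterpart was pruned away
    are skipped with a warning.
    """
    out = []
    for node in dtree.acceptor_nodes():
        sp_id = node.meta["sp_node_id"]
        root = dtree.root.copy()
        moved = _find(root, "acceptor", sp_id)
        target = _find(root, "donor", sp_id)
        if target is None:
            logger.warning("acceptor node %s has no donor counterpart; "
                           "move skipped", sp_id)
            continue
        _detach(moved)
        _regraft_next_to(moved, target)
        out.append((sp_id, root))
    return out


def combined_alignment(donor_genes: dict[str, TRNAGene],
                       acceptor_genes: dict[str, TRNAGene],
                       params: ScoringParams | None = None) -> dict[str, str]:
    """Align all genes to the model of a donor gene (model columns only).

    If every sequence already has the same length the sequences are used
    verbatim (positional homology assumed).  Otherwise each gene is aligned
    to the profile of the lexicographically first donor gene and reported
    on its model columns, mirroring a model-based combined alignment.
    """
    genes = list(donor_genes.values()) + list(acceptor_genes.values())
    lengths = {len(g.sequence) for g in genes}
    if len(lengths) == 1:
        return {g.gene_id: g.sequence for g in genes}
    ref = donor_genes[min(donor_genes)]
    model = build_model(ref, params)
    return {g.gene_id: align_to_model(g, model)[0] for g in genes}


@dataclass
class ProfileEntry:
    node_id: int                 # species-tree node id of the moved clade
    species: frozenset           # leaves of the moved clade
    loglik: float
    delta: float                 # loglik - baseline


@dataclass
class LikelihoodProfile:
    """Baseline plus one optimized log-likelihood per enumerated move."""

    baseline: float
    entries: list
    model_name: str

    @property
    def best_node_id(self) -> int | None:
        if not self.entries:
            return None
        return max(self.entries, key=lambda e: (e.delta, -e.node_id)).node_id

    @property
    def supported(self) -> list:
        return [e for e in self.entries if e.delta > 0]

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "node_id": e.node_id,
            "clade": ",".join(sorted(e.species)),
            "loglik": e.loglik,
            "delta": e.delta,
        } for e in self.entries]
        return pd.DataFrame(rows, columns=["node_id", "clade", "loglik", "delta"])


def _species_edge_mask(engine: LikelihoodEngine) -> np.ndarray:
    return np.array([
        node.parent is not None and node.meta.get("edge_kind") == "species"
        for node in engine.nodes
    ])


def _scaled_lengths(engine: LikelihoodEngine, scale: float) -> np.ndarray:
    """Species-tree edges in time units get the rate scale; the root bridge
    and regraft junction edges are already on the substitution scale."""
    mask = _species_edge_mask(engine)
    lengths = np.where(mask, engine.lengths * scale, engine.lengths)
    lengths = np.clip(lengths, engine.MIN_BL, engine.MAX_BL)
    lengths[engine.root_idx] = 0.0
    return lengths


def _fit_global_scale(engine: LikelihoodEngine) -> float:
    """One multiplicative rate scale for the species-tree edges, ML-fitted.

    Converts species-tree time units into expected substitutions per site
    without giving any topology extra per-branch freedom.
    """

    def nll(log_s):
        return -engine.loglik(_scaled_lengths(engine, float(np.exp(log_s))))

    res = _opt.minimize_scalar(nll, bounds=(np.log(1e-3), np.log(1e3)),
                               method="bounded", options={"xatol": 1e-3})
    return float(np.exp(res.x))


def mlrd_profile(tree: SpeciesTree,
                 donor_genes: dict[str, TRNAGene],
                 acceptor_genes: dict[str, TRNAGene],
                 model: SubstitutionModel | None = None,
                 alignment: dict[str, str] | None = None,
                 params: ScoringParams | None = None,
                 optimize: bool = False,
                 opt_tol: float = 1e-2, opt_sweeps: int = 6,
                 opt_xatol: float = 1e-3) -> LikelihoodProfile:
    """Score every candidate remolding placement on the species tree.

    The baseline is the log-likelihood of the unmoved doubled tree; one
    log-likelihood is computed per enumerated move.  Moves with positive
    delta support a remolding on the edge leading to the moved clade; the
    argmax is the best placement.

    By default every topology is evaluated with *fixed* branch lengths
    (species-tree lengths times one global rate scale fitted on the
    baseline, unit placeholders for taxonomy trees), so all candidates are
    compared on equal footing.  Free per-branch optimization
    (``optimize=True``) lets a falsely moved clade escape through a
    saturating attachment branch, which de-calibrates the null profile —
    the maximum over moves then exceeds the baseline by pure placement
    noise.

    The per-topology optimization budget (``opt_tol``, ``opt_sweeps``,
    ``opt_xatol``) only applies with ``optimize=True``; profile deltas of
    interest are tens of log units, so coarse settings are ample.
    """
    model = model or SubstitutionModel.jc69()
    if alignment is None:
        alignment = combined_alignment(donor_genes, acceptor_genes, params)
    dtree = build_doubled_tree(tree, donor_genes, acceptor_genes,
                               aligned=alignment)

    scale = 1.0
    if not optimize:
        scale = _fit_global_scale(
            LikelihoodEngine(dtree.root.copy(), dtree.leaf_seqs, model))

    def score(root):
        engine = LikelihoodEngine(root, dtree.leaf_seqs, model)
        if optimize:
            _, ll, _ = engine.optimize(tol=opt_tol, max_sweeps=opt_sweeps,
                                       xatol=opt_xatol)
            return ll
        return engine.loglik(_scaled_lengths(engine, scale))

    baseline = score(dtree.root.copy())
    entries = []
    for sp_id, root in enumerate_move_topologies(dtree):
        ll = score(root)
        clade = tree.clade_species(sp_id)
        entries.append(ProfileEntry(node_id=sp_id, species=clade,
                                    loglik=ll, delta=ll - baseline))
    return LikelihoodProfile(baseline=baseline, entries=entries,
                             model_name=model.name)


def select_outgroup(tree: SpeciesTree, clade_species, eligible_species,
                    n: int = 2) -> list[str]:
    """The ``n`` eligible species outside the clade closest to its root.

    Distance is measured from each candidate leaf to the clade MRCA; ties
    break lexicographically.  Fewer than ``n`` eligible species yields a
    shorter list with a warning.
    """
    clade_species = set(clade_species)
    outside = [s for s in eligible_species
               if s not in clade_species and s in tree.species]
    if not outside:
        logger.warning("no eligible outgroup species")
        return []
    mrca = tree.mrca(sorted(clade_species))
    scored = []
    for s in outside:
        node = tree.leaf(s)
        # distance leaf -> MRCA via their common ancestor
        anc = {id(x) for x in tree._path_to_root(mrca)}
        d, cur = 0.0, node
        while id(cur) not in anc:
            d += tree._edge_weight(cur)
            cur = cur.parent
        # climb remaining path from mrca up to the meeting point
        meet = cur
        cur = mrca
        while cur is not meet:
            d += tree._edge_weight(cur)
            cur = cur.parent
        scored.append((d, s))
    scored.sort()
    chosen = [s for _, s in scored[:n]]
    if len(chosen) < n:
        logger.warning("only %d outgroup species available", len(chosen))
    return chosen
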