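"""Seeded simulator of mitochondrial tRNA complements with remolding.

Emulates the duplication-anticodon-mutation-loss mechanism on a Yule
species tree: each of the 22 tRNA families evolves independently from a
random cloverleaf-shaped ancestral sequence under JC substitutions (the
anticodon is held invariant — family identity is stable in background
evolution); at the implanted event point the acceptor lineage's sequence
is replaced by the donor lineage's current sequence with the anticodon
switched to the acceptor identity, i.e. duplication and loss are collapsed
into an instantaneous swap.  The generator provides ground truth for the
detection stages and, optionally, per-species codon-count tables with an
injected usage shift below the event edge.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (FAMILIES, SpeciesTree, TreeNode, TRNAGene,
                   write_annotations)
from .post_analysis import anticodon_to_codon, codon_box

#: Standard metazoan mitochondrial anticodons per family.
ANTICODONS = {
    "A": "UGC", "C": "GCA", "D": "GUC", "E": "UUC", "F": "GAA", "G": "UCC",
    "H": "GUG", "I": "GAU", "K": "UUU", "L1": "UAG", "L2": "UAA", "M": "CAU",
    "N": "GUU", "P": "UGG", "Q": "UUG", "R": "UCG", "S1": "GCU", "S2": "UGA",
    "T": "UGU", "V": "UAC", "W": "UCA", "Y": "GUA",
}

#: Families encoded on the minus strand in the canonical vertebrate layout.
MINUS_STRAND = frozenset({"Q", "A", "N", "C", "Y", "S1", "E", "P"})

_NT = "ACGU"
_COMP = np.array([3, 2, 1, 0])  # A<->U, C<->G

ANTICODON_START = 33  # 0-based position of the anticodon in the template


def cloverleaf_structure(var_loop: int) -> str:
    """Dot-bracket cloverleaf template; total length 68 + var_loop.

    Acceptor stem 7 bp, D stem 4 bp, anticodon stem 5 bp, T stem 5 bp;
    the anticodon sits at template positions 33-35 for every var-loop size.
    """
    if not 0 <= var_loop <= 4:
        raise ValueError("var_loop must be in [0, 4]")
    return (
        "(" * 7 + ".." + "(" * 4 + "." * 8 + ")" * 4 + "." +
        "(" * 5 + "." * 7 + ")" * 5 + "." * var_loop +
        "(" * 5 + "." * 7 + ")" * 5 + ")" * 7 + "."
    )


@dataclass(frozen=True)
class RemoldingSpec:
    """Which families remold and where on the tree."""

    donor: str = "W"
    acceptor: str = "G"
    edge_node_id: int | None = None   # None: drawn among small clades
    time_fraction: float = 0.5        # position of the event on the edge

    def __post_init__(self):
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor families must differ")
        if not 0.0 <= self.time_fraction <= 1.0:
            raise ValueError("time_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one simulated clade."""

    n_species: int = 12
    birth_rate: float = 1.0
    rate: float = 0.05                # substitutions/site/unit branch length
    event: RemoldingSpec | None = RemoldingSpec()
    max_event_clade: int | None = None  # default n_species // 3
    codon_shift_magnitude: float | None = None
    n_codons: int = 3800              # codons per species (13 CDS scale)
    code_table: int = 2
    seed: int = 0


@dataclass
class TrueEvent:
    donor: str
    acceptor: str
    edge_node_id: int
    time_fraction: float
    affected_species: frozenset


@dataclass
class SyntheticDataset:
    tree: SpeciesTree
    genes: list
    event: TrueEvent | None
    config: SimulationConfig
    codon_counts: dict | None = None

    def genes_of(self, species: str, family: str) -> list:
        return [g for g in self.genes
                if g.species == species and g.family == family]


def _yule_tree(n_species: int, birth_rate: float, rng_seed: int) -> SpeciesTree:
    from dendropy.simulate import treesim
    pyrng = random.Random(rng_seed)
    t = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0,
        num_extant_tips=n_species, rng=pyrng,
    )
    # the simulator stops exactly at the n-th split, leaving the youngest
    # cherry with zero-length tip edges; extend all tips by the waiting
    # time to the (unrealized) next event to keep the tree ultrametric
    extra = pyrng.expovariate(n_species * birth_rate)
    for leaf in t.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    width = len(str(n_species))
    for i, leaf in enumerate(sorted(t.leaf_node_iter(),
                                    key=lambda l: l.taxon.label)):
        leaf.taxon.label = f"s{i + 1:0{width}d}"
    newick = t.as_string(schema="newick", suppress_rooting=True)
    return SpeciesTree.from_newick(newick)


def _evolve(seq: np.ndarray, t: float, rate: float, rng,
            frozen: np.ndarray | None = None) -> np.ndarray:
    """JC evolution for time t; positions in ``frozen`` do not change."""
    p = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * t))
    hit = rng.random(seq.size) < p
    if frozen is not None:
        hit[frozen] = False
    out = seq.copy()
    # conditional on change, the new state is uniform over the other three
    out[hit] = (seq[hit] + 1 + rng.integers(0, 3, size=int(hit.sum()))) % 4
    return out


def _ancestral_sequence(length: int, pairs, anticodon: str, rng) -> np.ndarray:
    seq = rng.integers(0, 4, size=length)
    for i, j in pairs:
        seq[j] = _COMP[seq[i]]
    for k, c in enumerate(anticodon):
        seq[ANTICODON_START + k] = _NT.index(c)
    return seq


def _decode(seq: np.ndarray) -> str:
    return "".join(_NT[c] for c in seq)


def _simulate_family(tree: SpeciesTree, root_seq: np.ndarray, rate: float,
                     rng, frozen: np.ndarray,
                     event_edge: int | None = None,
                     event_fraction: float = 0.5):
    """Evolve one family along the tree; returns (leaf states, event state).

    When ``event_edge`` is given, the state midway (``event_fraction``)
    along the edge leading to that node is also recorded — the donor
    sequence captured by the remolding.
    """
    states: dict[int, np.ndarray] = {}
    event_state = None
    order = [tree.root] + [n for n in tree.root.preorder() if n.parent]
    states[tree.root.node_id] = root_seq
    for node in order:
        if node.parent is None:
            continue
        t = node.length if tree.has_branch_lengths else 1.0
        start = states[node.parent.node_id]
        if event_edge is not None and node.node_id == event_edge:
            mid = _evolve(start, event_fraction * t, rate, rng, frozen)
            event_state = mid
            states[node.node_id] = _evolve(mid, (1 - event_fraction) * t,
                                           rate, rng, frozen)
        else:
            states[node.node_id] = _evolve(start, t, rate, rng, frozen)
    leaves = {leaf.name: states[leaf.node_id] for leaf in tree.root.leaves()}
    return leaves, event_state


def _pick_event_edge(tree: SpeciesTree, rng, max_clade: int) -> int:
    candidates = [n.node_id for n in tree.root.postorder()
                  if n.parent is not None
                  and len(n.leaves()) <= max_clade]
    return int(candidates[rng.integers(0, len(candidates))])


def simulate(config: SimulationConfig) -> SyntheticDataset:
    """Run one seeded simulation; byte-identical for identical configs."""
    rng = np.random.default_rng(config.seed)
    tree = _yule_tree(config.n_species, config.birth_rate,
                      int(rng.integers(0, 2 ** 31)))

    var_loops = {fam: int(rng.integers(0, 5)) for fam in FAMILIES}
    structures = {fam: cloverleaf_structure(var_loops[fam]) for fam in FAMILIES}
    from .core import parse_dotbracket
    pairs = {fam: parse_dotbracket(structures[fam]) for fam in FAMILIES}
    roots = {fam: _ancestral_sequence(len(structures[fam]), pairs[fam],
                                      ANTICODONS[fam], rng)
             for fam in FAMILIES}
    frozen_mask = {fam: np.zeros(len(structures[fam]), dtype=bool)
                   for fam in FAMILIES}
    for fam in FAMILIES:
        frozen_mask[fam][ANTICODON_START:ANTICODON_START + 3] = True

    event = config.event
    event_edge = None
    if event is not None:
        if event.edge_node_id is not None:
            if event.edge_node_id not in [n.node_id
                                          for n in tree.root.postorder()
                                          if n.parent is not None]:
                raise ValueError(f"no such edge: node {event.edge_node_id}")
            event_edge = event.edge_node_id
        else:
            max_clade = config.max_event_clade or max(1, config.n_species // 3)
            event_edge = _pick_event_edge(tree, rng, max_clade)

    leaf_states: dict[str, dict[str, np.ndarray]] = {}
    donor_event_state = None
    for fam in FAMILIES:
        want_mid = event is not None and fam == event.donor
        leaves, mid = _simulate_family(
            tree, roots[fam], config.rate, rng, frozen_mask[fam],
            event_edge=event_edge if want_mid else None,
            event_fraction=event.time_fraction if event else 0.5,
        )
        leaf_states[fam] = leaves
        if want_mid:
            donor_event_state = mid

    affected: frozenset = frozenset()
    true_event = None
    if event is not None:
        affected = tree.clade_species(event_edge)
        # remolded acceptor: donor sequence at the event with the acceptor
        # anticodon, evolved onward below the event edge
        remold_root = donor_event_state.copy()
        for k, c in enumerate(ANTICODONS[event.acceptor]):
            remold_root[ANTICODON_START + k] = _NT.index(c)
        node = tree.node(event_edge)
        sub_states = {node.node_id: _evolve(
            remold_root,
            (1 - event.time_fraction) * (node.length
                                         if tree.has_branch_lengths else 1.0),
            config.rate, rng, frozen_mask[event.donor])}
        for n in node.preorder():
            if n is node:
                continue
            t = n.length if tree.has_branch_lengths else 1.0
            sub_states[n.node_id] = _evolve(sub_states[n.parent.node_id], t,
                                            config.rate, rng,
                                            frozen_mask[event.donor])
        for leaf in node.leaves():
            leaf_states[event.acceptor][leaf.name] = sub_states[leaf.node_id]
        true_event = TrueEvent(
            donor=event.donor, acceptor=event.acceptor,
            edge_node_id=event_edge, time_fraction=event.time_fraction,
            affected_species=affected,
        )

    genes = _layout_genomes(tree, leaf_states, structures, affected, event)
    dataset = SyntheticDataset(tree=tree, genes=genes, event=true_event,
                               config=config)
    if config.codon_shift_magnitude is not None:
        if true_event is None:
            raise ValueError("codon shift injection requires an event")
        dataset = inject_codon_shift(dataset, config.codon_shift_magnitude)
    return dataset


def _layout_genomes(tree, leaf_states, structures, affected, event):
    """Place the 22 genes on a circular genome per species.

    In species below the event edge the acceptor gene is moved directly
    downstream of the donor (local-duplication geometry) and put on the
    donor's strand; its sequence/structure are the donor-template ones.
    """
    spacing = 400
    genes = []
    for sp in sorted(leaf_states[FAMILIES[0]]):
        order = list(FAMILIES)
        if event is not None and sp in affected:
            order.remove(event.acceptor)
            order.insert(order.index(event.donor) + 1, event.acceptor)
        cursor = 150
        placed = []
        for fam in order:
            seq = _decode(leaf_states[fam][sp])
            remolded = (event is not None and sp in affected
                        and fam == event.acceptor)
            struct = structures[event.donor] if remolded else structures[fam]
            strand = "-" if fam in MINUS_STRAND else "+"
            if remolded:
                strand = "-" if event.donor in MINUS_STRAND else "+"
            anticodon = ANTICODONS[fam]
            placed.append(dict(
                gene_id=f"{sp}_{fam}", species=sp, family=fam,
                anticodon=anticodon, sequence=seq, structure=struct,
                start=cursor, end=cursor + len(seq), strand=strand,
            ))
            cursor += len(seq) + spacing
        genome_length = cursor + 150
        for spec in placed:
            genes.append(TRNAGene(genome_length=genome_length, **spec))
    return genes


def inject_codon_shift(dataset: SyntheticDataset,
                       magnitude: float) -> SyntheticDataset:
    """Attach per-species codon-count tables with a usage shift.

    Counts are multinomial draws from a shared Dirichlet base usage over
    the sense codons of the configured code; in species below the event
    edge the probability of the codon read by the acceptor anticodon is
    multiplied by ``1 - magnitude`` and the donor codon box by
    ``1 - magnitude / 2``, then renormalized.
    """
    if not 0.0 <= magnitude < 1.0:
        raise ValueError("magnitude must be in [0, 1)")
    if dataset.event is None:
        raise ValueError("dataset has no implanted event")
    from Bio.Data import CodonTable
    table = CodonTable.unambiguous_rna_by_id[dataset.config.code_table]
    sense = sorted(table.forward_table)
    rng = np.random.default_rng(dataset.config.seed + 10_000)
    base = rng.dirichlet(np.full(len(sense), 5.0))
    acc_codon = anticodon_to_codon(ANTICODONS[dataset.event.acceptor])
    donor_box = set(codon_box(anticodon_to_codon(ANTICODONS[dataset.event.donor])))
    counts: dict[str, dict[str, int]] = {}
    for sp in dataset.tree.species:
        probs = base.copy()
        if sp in dataset.event.affected_species:
            for k, codon in enumerate(sense):
                if codon == acc_codon:
                    probs[k] *= 1.0 - magnitude
                if codon in donor_box:
                    probs[k] *= 1.0 - magnitude / 2.0
            probs /= probs.sum()
        draw = rng.multinomial(dataset.config.n_codons, probs)
        counts[sp] = {c: int(n) for c, n in zip(sense, draw)}
    dataset.codon_counts = counts
    return dataset


#: Canonical template column count: 68 core positions + up to 4 var-loop nt.
TEMPLATE_COLUMNS = 72
_VAR_LOOP_START = 43


def template_alignment(genes) -> dict[str, str]:
    """Ground-truth combined alignment on the cloverleaf template columns.

    Every simulated gene is positionally homologous up to its var-loop
    size, so padding the variable loop to 4 columns aligns all families
    exactly — the alignment a correct structure model would produce.
    """
    out = {}
    for g in genes:
        v = len(g.sequence) - 68
        if not 0 <= v <= 4:
            raise ValueError(f"gene {g.gene_id!r} is not template-shaped")
        out[g.gene_id] = (g.sequence[:_VAR_LOOP_START + v]
                          + "-" * (4 - v)
                          + g.sequence[_VAR_LOOP_START + v:])
    return out


def emit(dataset: SyntheticDataset, directory: str) -> dict[str, str]:
    """Write the dataset in the formats the pipeline consumes.

    Produces ``tree.nwk``, ``genes.fa``, ``annotations.tsv``, ``truth.tsv``
    and, when present, ``codon_counts.tsv``; returns the path map.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {
        "tree": os.path.join(directory, "tree.nwk"),
        "fasta": os.path.join(directory, "genes.fa"),
        "annotations": os.path.join(directory, "annotations.tsv"),
        "truth": os.path.join(directory, "truth.tsv"),
    }
    dataset.tree.write(paths["tree"])
    write_annotations(dataset.genes, paths["annotations"], paths["fasta"])
    rows = []
    if dataset.event is not None:
        rows.append({
            "donor": dataset.event.donor,
            "acceptor": dataset.event.acceptor,
            "edge_node_id": dataset.event.edge_node_id,
            "time_fraction": dataset.event.time_fraction,
            "affected_species": ",".join(sorted(dataset.event.affected_species)),
        })
    pd.DataFrame(rows, columns=["donor", "acceptor", "edge_node_id",
                                "time_fraction", "affected_species"]) \
        .to_csv(paths["truth"], sep="\t", index=False)
    if dataset.codon_counts is not None:
        paths["codon_counts"] = os.path.join(directory, "codon_counts.tsv")
        rows = [{"species": sp, "codon": c, "count": n}
                for sp in sorted(dataset.codon_counts)
                for c, n in sorted(dataset.codon_counts[sp].items())]
        pd.DataFrame(rows).to_csv(paths["codon_counts"], sep="\t", index=False)
    return paths


def read_codon_counts(path: str) -> dict[str, dict[str, int]]:
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "codon": str})
    out: dict[str, dict[str, int]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.species, {})[row.codon] = int(row.count)
    return out
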