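"""Domain types and I/O shared by all analysis stages.

Mitochondrial tRNA genes are represented by :class:`TRNAGene`; the species
phylogeny by :class:`SpeciesTree`, a rooted (strictly bifurcating after
normalization) tree with optional branch lengths.  Taxonomy-derived trees
without branch lengths are legal; in that case every edge counts one unit
when patristic distances are computed.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy
import pandas as pd
from Bio import AlignIO, SeqIO

logger = logging.getLogger(__name__)

#: The 22 tRNA identities of a canonical metazoan mitochondrial genome.
#: L1/L2 are the UAG/UAA leucine isoacceptors, S1/S2 the GCU/UGA serines.
FAMILIES = (
    "A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
    "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y",
)
_FAMILY_SET = frozenset(FAMILIES)

_RNA = frozenset("ACGUN")

_OPEN = {"(": ")", "<": ">", "[": "]", "{": "}"}
_CLOSE = {v: k for k, v in _OPEN.items()}


def normalize_rna(seq: str) -> str:
    """Uppercase and map DNA T to RNA U."""
    return seq.upper().replace("T", "U")


def parse_dotbracket(structure: str) -> list[tuple[int, int]]:
    """Return base-pair index tuples (i, j), i < j, from a dot-bracket string.

    Supports (), <>, [] and {} bracket types; any other character is treated
    as unpaired.  Raises ``ValueError`` on unbalanced brackets.
    """
    stacks: dict[str, list[int]] = {k: [] for k in _OPEN}
    pairs = []
    for i, ch in enumerate(structure):
        if ch in _OPEN:
            stacks[ch].append(i)
        elif ch in _CLOSE:
            stack = stacks[_CLOSE[ch]]
            if not stack:
                raise ValueError(f"unbalanced structure at position {i}")
            pairs.append((stack.pop(), i))
    for k, stack in stacks.items():
        if stack:
            raise ValueError(f"unbalanced structure: unclosed '{k}'")
    return sorted(pairs)


@dataclass
class TRNAGene:
    """One annotated mitochondrial tRNA gene.

    Coordinates are 0-based half-open on a circular genome; a gene spanning
    the origin is stored with ``end > genome_length`` and interpreted modulo
    ``genome_length``.
    """

    gene_id: str
    species: str
    family: str
    anticodon: str
    sequence: str
    start: int
    end: int
    strand: str
    genome_length: int
    structure: str | None = None

    def __post_init__(self):
        if self.family not in _FAMILY_SET:
            raise ValueError(
                f"unknown tRNA family {self.family!r} for gene {self.gene_id!r}"
            )
        self.sequence = normalize_rna(self.sequence)
        self.anticodon = normalize_rna(self.anticodon)
        if not self.sequence:
            raise ValueError(f"gene {self.gene_id!r} has an empty sequence")
        if not set(self.sequence) <= _RNA:
            bad = set(self.sequence) - _RNA
            raise ValueError(f"gene {self.gene_id!r}: non-RNA characters {bad}")
        if len(self.anticodon) != 3 or not set(self.anticodon) <= set("ACGU"):
            raise ValueError(
                f"gene {self.gene_id!r}: anticodon must be 3 nt over ACGU, "
                f"got {self.anticodon!r}"
            )
        self.strand = {"-": "-", "+": "+", "−": "-"}.get(self.strand, self.strand)
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        if self.genome_length <= 0:
            raise ValueError(f"gene {self.gene_id!r}: non-positive genome length")
        if not 0 <= self.start < self.genome_length:
            raise ValueError(
                f"gene {self.gene_id!r}: start {self.start} outside "
                f"[0, {self.genome_length})"
            )
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: empty or inverted interval "
                f"[{self.start}, {self.end})"
            )
        if self.structure is not None:
            if len(self.structure) != len(self.sequence):
                raise ValueError(
                    f"gene {self.gene_id!r}: structure length differs from sequence"
                )
            parse_dotbracket(self.structure)  # raises if unbalanced

    @property
    def length(self) -> int:
        return self.end - self.start


class TreeNode:
    """Light rooted-tree node used for species trees and gene trees."""

    __slots__ = ("name", "length", "children", "parent", "node_id", "meta")

    def __init__(self, name=None, length=None, children=None):
        self.name = name
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.node_id: int | None = None
        self.meta: dict = {}
        for child in children or ():
            self.add_child(child)

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> frozenset:
        return frozenset(n.name for n in self.leaves())

    def copy(self) -> "TreeNode":
        new = TreeNode(name=self.name, length=self.length)
        new.node_id = self.node_id
        new.meta = dict(self.meta)
        for child in self.children:
            new.add_child(child.copy())
        return new

    def to_newick(self, lengths: bool = True) -> str:
        def fmt(node):
            if node.is_leaf:
                label = node.name or ""
            else:
                label = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if lengths and node.length is not None and node.parent is not None:
                label += f":{node.length:.10g}"
            return label

        return fmt(self) + ";"

    def __repr__(self):  # pragma: no cover - debug aid
        return f"TreeNode({self.name or self.node_id}, n_leaves={len(self.leaves())})"


def _min_leaf_label(node: TreeNode, cache: dict) -> str:
    if id(node) in cache:
        return cache[id(node)]
    if node.is_leaf:
        label = node.name
    else:
        label = min(_min_leaf_label(c, cache) for c in node.children)
    cache[id(node)] = label
    return label


class SpeciesTree:
    """Rooted species tree with deterministic normalization.

    Normalization sorts the children of every node by the lexicographically
    smallest leaf label in their clade and resolves polytomies left-to-right
    into a ladder; node ids are then assigned in post-order.  The procedure
    is idempotent and independent of the input child order, so downstream
    node references (MLRD move enumeration, reference-species selection) are
    reproducible.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        labels = [leaf.name for leaf in root.leaves()]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        self._normalize()
        self.has_branch_lengths = all(
            n.length is not None for n in self.root.postorder() if n.parent is not None
        )
        if not self.has_branch_lengths:
            # all-or-nothing: a single missing length puts the whole tree
            # into taxonomy (unit-edge) mode
            for node in self.root.postorder():
                node.length = None
        self._assign_ids()
        self._leaves = {leaf.name: leaf for leaf in self.root.leaves()}
        self._nodes = {node.node_id: node for node in self.root.postorder()}

    # -- construction ---------------------------------------------------
    @classmethod
    def from_newick(cls, source: str) -> "SpeciesTree":
        """Read a Newick tree from a path or a Newick string."""
        from dendropy.dataio.newickreader import NewickReader
        try:
            if source.strip().startswith("(") or source.strip().endswith(";"):
                dtree = dendropy.Tree.get(
                    data=source, schema="newick", preserve_underscores=True
                )
            else:
                dtree = dendropy.Tree.get(
                    path=source, schema="newick", preserve_underscores=True
                )
        except NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate leaf labels: {exc}") from None

        def convert(dnode):
            name = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = TreeNode(name=name, length=dnode.edge.length)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dtree.seed_node))

    def _normalize(self):
        cache: dict = {}
        for node in list(self.root.postorder()):
            if len(node.children) < 2:
                if node.children and node.parent is not None:
                    raise ValueError("unifurcation in input tree")
                continue
            node.children.sort(key=lambda c: _min_leaf_label(c, cache))
            while len(node.children) > 2:
                left = TreeNode(children=node.children[:2])
                left.length = 0.0 if all(
                    c.length is not None for c in node.children[:2]
                ) else None
                node.children = [left] + node.children[2:]
                for c in node.children:
                    c.parent = node
                cache[id(left)] = _min_leaf_label(left, cache)

    def _assign_ids(self):
        for i, node in enumerate(self.root.postorder()):
            node.node_id = i

    # -- queries ---------------------------------------------------------
    @property
    def species(self) -> list[str]:
        return sorted(self._leaves)

    def leaf(self, name: str) -> TreeNode:
        try:
            return self._leaves[name]
        except KeyError:
            raise KeyError(f"unknown species {name!r}") from None

    def node(self, node_id: int) -> TreeNode:
        return self._nodes[node_id]

    def clade_species(self, node_id: int) -> frozenset:
        return self._nodes[node_id].leaf_names()

    def _path_to_root(self, node: TreeNode) -> list[TreeNode]:
        path = [node]
        while path[-1].parent is not None:
            path.append(path[-1].parent)
        return path

    def mrca(self, names) -> TreeNode:
        names = list(names)
        paths = [set(id(n) for n in self._path_to_root(self.leaf(x))) for x in names]
        common = set.intersection(*paths)
        node = self.leaf(names[0])
        while id(node) not in common:
            node = node.parent
        return node

    def _edge_weight(self, node: TreeNode) -> float:
        return node.length if self.has_branch_lengths else 1.0

    def patristic_distance(self, a: str, b: str) -> float:
        """Branch-length sum on the a-b path (edge count in taxonomy mode)."""
        if a == b:
            self.leaf(a)
            return 0.0
        na, nb = self.leaf(a), self.leaf(b)
        anc_a = {id(n): i for i, n in enumerate(self._path_to_root(na))}
        dist = 0.0
        node = nb
        while id(node) not in anc_a:
            dist += self._edge_weight(node)
            node = node.parent
        up = self._path_to_root(na)[: anc_a[id(node)]]
        for n in up:
            dist += self._edge_weight(n)
        return dist

    def distance_to_node(self, species: str, target: TreeNode) -> float:
        """Path length from a leaf up to an ancestor node ``target``."""
        node = self.leaf(species)
        dist = 0.0
        while node is not target:
            if node.parent is None:
                raise ValueError(f"{target!r} is not an ancestor of {species!r}")
            dist += self._edge_weight(node)
            node = node.parent
        return dist

    def to_newick(self) -> str:
        return self.root.to_newick(lengths=self.has_branch_lengths)

    def write(self, path: str):
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


@dataclass
class Alignment:
    """Ordered gapped sequences with optional group tags and consensus structure."""

    ids: list[str]
    rows: list[str]
    groups: dict[str, str] | None = None
    consensus_structure: str | None = None

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")
        self.rows = [normalize_rna(r).replace(".", "-") for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    @classmethod
    def from_file(cls, path: str, fmt: str = "fasta",
                  groups: dict[str, str] | None = None) -> "Alignment":
        """Read an aligned FASTA or Stockholm file.

        For Stockholm input the ``#=GC SS_cons`` line, when present, becomes
        the consensus structure.
        """
        aln = AlignIO.read(path, fmt)
        consensus = None
        if fmt == "stockholm":
            consensus = aln.column_annotations.get("secondary_structure")
        return cls(
            ids=[rec.id for rec in aln],
            rows=[str(rec.seq) for rec in aln],
            groups=groups,
            consensus_structure=consensus,
        )


ANNOTATION_COLUMNS = (
    "gene_id", "species", "family", "anticodon",
    "start", "end", "strand", "genome_length",
)


def read_annotations(path: str, fasta: str) -> list[TRNAGene]:
    """Read the annotation TSV plus gene FASTA into validated records.

    The TSV must carry the columns ``gene_id species family anticodon start
    end strand genome_length`` (a ``structure`` column is optional); FASTA
    ids must match ``gene_id``.  A gene without a sequence is a hard error.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table misses columns {missing}")
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta, "fasta")}
    genes = []
    for row in table.itertuples(index=False):
        gene_id = row.gene_id
        if gene_id not in seqs:
            raise ValueError(f"no sequence for annotated gene {gene_id!r}")
        structure = getattr(row, "structure", None)
        if isinstance(structure, float) or structure in ("", None, "nan"):
            structure = None
        genes.append(
            TRNAGene(
                gene_id=gene_id,
                species=row.species,
                family=row.family,
                anticodon=row.anticodon,
                sequence=seqs[gene_id],
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                genome_length=int(row.genome_length),
                structure=structure,
            )
        )
    ids = [g.gene_id for g in genes]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate gene_id in annotation table")
    return genes


def write_annotations(genes, tsv_path: str, fasta_path: str):
    """Inverse of :func:`read_annotations` (structure column included)."""
    rows = []
    for g in genes:
        rows.append({
            "gene_id": g.gene_id, "species": g.species, "family": g.family,
            "anticodon": g.anticodon, "start": g.start, "end": g.end,
            "strand": g.strand, "genome_length": g.genome_length,
            "structure": g.structure or "",
        })
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    with open(fasta_path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n{g.sequence}\n")


def read_species_tree(path: str) -> SpeciesTree:
    """Read and normalize a Newick species tree (polytomies resolved)."""
    return SpeciesTree.from_newick(path)


def genes_by_species(genes) -> dict[str, list[TRNAGene]]:
    out: dict[str, list[TRNAGene]] = {}
    for g in genes:
        out.setdefault(g.species, []).append(g)
    return out


def gene_lookup(genes) -> dict[tuple[str, str], list[TRNAGene]]:
    """Map (species, family) -> genes (several on family duplication)."""
    out: dict[tuple[str, str], list[TRNAGene]] = {}
    for g in genes:
        out.setdefault((g.species, g.family), []).append(g)
    return out
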