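"""Shared containers: alignments, phylogenies, rate vectors.

An :class:`Alignment` is a set of equal-length, taxon-keyed sequences
(amino-acid or in-frame codon). A :class:`Phylogeny` is a rooted tree with
named tips and non-negative branch lengths; branches are identified by the
id of the node they lead into, and branch depth counts edges from the root
(a root-adjacent branch has depth 1). These two objects flow through every
stage of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = frozenset("-?.X")


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    """Taxon-keyed equal-length sequences.

    Parameters
    ----------
    taxa : list of str
        Unique taxon names, one per sequence.
    sequences : list of str
        Upper-case sequence strings, all the same length. For
        ``molecule="codon"`` the length must be divisible by 3.
    molecule : {"amino", "codon"}
    gene_set : str, optional
        Label of the gene set the alignment belongs to (e.g. ``"mt"``).
    offsets : dict, optional
        For concatenated alignments, maps each source gene to its
        0-based start column.
    """

    taxa: list[str]
    sequences: list[str]
    molecule: str = "amino"
    gene_set: str | None = None
    offsets: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise InvalidInputError("taxa and sequences differ in count")
        if len(set(self.taxa)) != len(self.taxa):
            raise InvalidInputError("taxon names must be unique")
        if self.molecule not in ("amino", "codon"):
            raise InvalidInputError(f"unknown molecule type {self.molecule!r}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise InvalidInputError("sequences must be equal length")
        if self.molecule == "codon" and self.sequences and self.length % 3:
            raise InvalidInputError("codon alignment length not divisible by 3")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def sequence_of(self, taxon: str) -> str:
        try:
            return self.sequences[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(taxon) from None

    def subset(self, taxa: list[str]) -> "Alignment":
        """Restrict to the given taxa (order preserved)."""
        return Alignment(
            taxa=list(taxa),
            sequences=[self.sequence_of(t) for t in taxa],
            molecule=self.molecule,
            gene_set=self.gene_set,
            offsets=dict(self.offsets),
        )

    def codons(self, taxon: str) -> list[str]:
        if self.molecule != "codon":
            raise InvalidInputError("codons() requires a codon alignment")
        s = self.sequence_of(taxon)
        return [s[i:i + 3] for i in range(0, len(s), 3)]

    # -- IO -----------------------------------------------------------------

    @classmethod
    def from_fasta(cls, path, molecule: str = "amino",
                   gene_set: str | None = None) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise InvalidInputError(f"no FASTA records in {path}")
        return cls(
            taxa=[r.id for r in records],
            sequences=[str(r.seq).upper() for r in records],
            molecule=molecule,
            gene_set=gene_set,
        )

    def to_fasta(self, path) -> None:
        records = [SeqRecord(Seq(s), id=t, description="")
                   for t, s in zip(self.taxa, self.sequences)]
        SeqIO.write(records, str(path), "fasta")


def is_gap(state: str) -> bool:
    return any(c in GAP_CHARS for c in state)


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------

@dataclass
class _Node:
    id: int
    name: str | None = None
    parent: int = -1
    children: list[int] = field(default_factory=list)
    length: float = 0.0
    depth: int = 0

    @property
    def is_tip(self) -> bool:
        return not self.children


class Phylogeny:
    """Rooted tree; nodes stored in preorder with the root at index 0.

    Branch *b* is the edge into node *b*; its depth equals the node's depth
    (number of edges from the root), so root-adjacent branches have depth 1.
    Branch lengths are expected substitutions per site and must be >= 0.
    """

    def __init__(self, nodes: list[_Node]):
        self.nodes = nodes
        self._recompute_depths()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls.from_dendropy(tree)

    @classmethod
    def from_newick_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes: list[_Node] = []
        index: dict[int, int] = {}
        for dnode in tree.preorder_node_iter():
            nid = len(nodes)
            index[id(dnode)] = nid
            parent = index[id(dnode.parent_node)] if dnode.parent_node else -1
            name = None
            if dnode.taxon is not None:
                name = dnode.taxon.label
            elif dnode.label:
                name = dnode.label
            length = dnode.edge.length if dnode.edge.length is not None else 0.0
            node = _Node(id=nid, name=name, parent=parent, length=float(length))
            nodes.append(node)
            if parent >= 0:
                nodes[parent].children.append(nid)
        return cls(nodes)

    def _recompute_depths(self) -> None:
        for node in self.nodes:  # preorder: parent precedes child
            node.depth = 0 if node.parent < 0 else self.nodes[node.parent].depth + 1

    # -- basic queries -------------------------------------------------------

    @property
    def root(self) -> _Node:
        return self.nodes[0]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def tip_ids(self) -> list[int]:
        return [n.id for n in self.nodes if n.is_tip]

    @property
    def tip_names(self) -> list[str]:
        return [n.name for n in self.nodes if n.is_tip]

    @property
    def branch_ids(self) -> list[int]:
        """Every non-root node id (the edge leading into it)."""
        return [n.id for n in self.nodes if n.parent >= 0]

    def tip_id(self, name: str) -> int:
        for n in self.nodes:
            if n.is_tip and n.name == name:
                return n.id
        raise KeyError(name)

    def postorder(self) -> list[int]:
        return [n.id for n in reversed(self.nodes)]

    def preorder(self) -> list[int]:
        return [n.id for n in self.nodes]

    def path_to_tip(self, tip: int | str) -> list[int]:
        """Branch ids on the unique root-to-tip path, root end first."""
        nid = self.tip_id(tip) if isinstance(tip, str) else tip
        path = []
        while self.nodes[nid].parent >= 0:
            path.append(nid)
            nid = self.nodes[nid].parent
        return path[::-1]

    def root_to_tip_distance(self, tip: int | str) -> float:
        return sum(self.nodes[b].length for b in self.path_to_tip(tip))

    def subtree_tips(self, node_id: int) -> list[int]:
        """Tip ids in the clade subtended by *node_id*."""
        out, stack = [], [node_id]
        while stack:
            nid = stack.pop()
            node = self.nodes[nid]
            if node.is_tip:
                out.append(nid)
            else:
                stack.extend(node.children)
        return out

    def is_ancestor_branch(self, anc: int, desc: int) -> bool:
        """True if branch *anc* lies on the root path of branch *desc*."""
        nid = desc
        while nid >= 0:
            if nid == anc:
                return True
            nid = self.nodes[nid].parent
        return False

    def total_length(self) -> float:
        return sum(n.length for n in self.nodes if n.parent >= 0)

    def copy(self) -> "Phylogeny":
        nodes = [_Node(id=n.id, name=n.name, parent=n.parent,
                       children=list(n.children), length=n.length,
                       depth=n.depth) for n in self.nodes]
        return Phylogeny(nodes)

    def drop_tip(self, name: str) -> "Phylogeny":
        """Remove one tip and suppress the resulting unifurcation.

        Used to drop the outgroup before rate correlation. Lengths of a
        suppressed node's two incident edges are summed.
        """
        tree = self.to_dendropy()
        taxon = tree.taxon_namespace.get_taxon(name)
        if taxon is None:
            raise KeyError(name)
        tree.prune_taxa([taxon])
        return Phylogeny.from_dendropy(tree)

    # -- IO -----------------------------------------------------------------

    def to_newick(self) -> str:
        def render(nid: int) -> str:
            node = self.nodes[nid]
            if node.is_tip:
                label = node.name or ""
            else:
                label = "(" + ",".join(render(c) for c in node.children) + ")"
                if node.name:
                    label += node.name
            if node.parent >= 0:
                label += f":{node.length:.10g}"
            return label

        return render(0) + ";"

    def to_newick_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    def to_dendropy(self) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                 preserve_underscores=True)


# ---------------------------------------------------------------------------
# Rate vectors
# ---------------------------------------------------------------------------

@dataclass
class RateVector:
    """Per-taxon root-to-tip evolutionary distance for one gene set."""

    gene_set: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        for taxon, v in self.values.items():
            if v < 0:
                raise InvalidInputError(
                    f"negative root-to-tip distance for {taxon}")

    @property
    def taxa(self) -> list[str]:
        return list(self.values)

    def __getitem__(self, taxon: str) -> float:
        return self.values[taxon]

    def scaled(self, factor: float) -> "RateVector":
        return RateVector(self.gene_set,
                          {t: v * factor for t, v in self.values.items()})


def rate_vector_from_tree(tree: Phylogeny, gene_set: str) -> RateVector:
    """Root-to-tip path sums for every tip of a length-annotated tree."""
    return RateVector(gene_set, {
        tree.nodes[t].name: tree.root_to_tip_distance(t)
        for t in tree.tip_ids
    })
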