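"""Mitonuclear contact pairs from a 3D complex structure.

A residue of a mitochondrially encoded chain and a residue of a
nuclear-encoded chain form a contact pair when their minimum heavy-atom
Euclidean distance is at or below the cutoff (default 5.0 Å, boundary
inclusive); intra-genome pairs are never reported. An optional
van-der-Waals overlap criterion (``overlap = r_i + r_j - d >= threshold``,
the sign convention in which -1 Å means a 1 Å gap allowance) is provided
for users wanting the Chimera-style setting.

Structure residues are mapped to alignment columns through a global
pairwise alignment of the chain sequence against a reference taxon's
ungapped row, so that contact sites can be located in the alignments the
rest of the pipeline uses. PDB author residue numbering is preserved
end-to-end; alignment columns are 1-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .core import Alignment, InvalidInputError

logger = logging.getLogger("mitonuc.contacts")

# Bondi-style van der Waals radii (Å) for heavy elements seen in proteins
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
             "SE": 1.90}
_DEFAULT_VDW = 1.70


class ConfigurationError(ValueError):
    """A chain lacks a gene/genome mapping."""


@dataclass
class Residue:
    chain: str
    number: int                 # author numbering
    name: str                   # three-letter code
    one_letter: str
    coords: np.ndarray          # (n_heavy_atoms, 3)
    elements: list[str]


@dataclass
class Structure:
    chains: dict[str, list[Residue]]
    chain_to_gene: dict[str, str] = field(default_factory=dict)
    gene_to_genome: dict[str, str] = field(default_factory=dict)

    def chain_sequence(self, chain: str) -> str:
        return "".join(r.one_letter for r in self.chains[chain])

    def genome_of_chain(self, chain: str) -> str:
        if chain not in self.chain_to_gene:
            raise ConfigurationError(f"chain {chain!r} has no gene mapping")
        gene = self.chain_to_gene[chain]
        if gene not in self.gene_to_genome:
            raise ConfigurationError(f"gene {gene!r} has no genome mapping")
        return self.gene_to_genome[gene]


@dataclass
class ContactPair:
    mt_gene: str
    mt_chain: str
    mt_residue: int
    n_gene: str
    n_chain: str
    n_residue: int
    distance: float
    mt_column: int | None = None    # 1-based alignment column
    n_column: int | None = None


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_structure(path, chain_to_gene: dict[str, str] | None = None,
                    gene_to_genome: dict[str, str] | None = None) -> Structure:
    """Read a PDB coordinate file.

    Keeps heavy atoms of standard amino-acid ATOM records (hydrogens
    ignored); for alternate locations the highest-occupancy conformer is
    kept. HETATM-only files are rejected.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = parser.get_structure("s", str(path))[0]
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues = []
        for res in chain:
            hetflag, resseq, _ = res.id
            if hetflag.strip():
                continue
            name = res.get_resname().strip()
            one = protein_letters_3to1.get(name, "X")
            coords, elements = [], []
            for atom in res:
                if atom.is_disordered():
                    atom = max(atom.disordered_get_list(),
                               key=lambda a: a.get_occupancy() or 0)
                element = (atom.element or "").strip().upper()
                if element == "H" or element == "D":
                    continue
                coords.append(atom.get_coord())
                elements.append(element)
            if not coords:
                continue
            residues.append(Residue(
                chain=chain.id, number=int(resseq), name=name,
                one_letter=one, coords=np.asarray(coords, dtype=float),
                elements=elements))
        if residues:
            chains[chain.id] = residues
    if not chains:
        raise InvalidInputError(f"no ATOM records in {path}")
    return Structure(chains, chain_to_gene or {}, gene_to_genome or {})


# ---------------------------------------------------------------------------
# Contact detection
# ---------------------------------------------------------------------------

def _min_distance(a: Residue, b: Residue) -> float:
    diff = a.coords[:, None, :] - b.coords[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).min())


def _max_overlap(a: Residue, b: Residue) -> float:
    ra = np.array([VDW_RADII.get(e, _DEFAULT_VDW) for e in a.elements])
    rb = np.array([VDW_RADII.get(e, _DEFAULT_VDW) for e in b.elements])
    diff = a.coords[:, None, :] - b.coords[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    return float((ra[:, None] + rb[None, :] - d).max())


def find_contact_pairs(structure: Structure, cutoff: float = 5.0,
                       criterion: str = "distance",
                       overlap_threshold: float = -1.0) -> list[ContactPair]:
    """All mt:nuclear residue pairs within the contact criterion.

    ``criterion="distance"`` (primary): minimum heavy-atom distance
    <= ``cutoff`` (inclusive). ``criterion="vdw"``: maximum pairwise
    van-der-Waals overlap >= ``overlap_threshold``.
    """
    if criterion not in ("distance", "vdw"):
        raise InvalidInputError(f"unknown criterion {criterion!r}")
    genomes = {c: structure.genome_of_chain(c) for c in structure.chains}
    pairs: list[ContactPair] = []
    chain_ids = sorted(structure.chains)
    for i, ca in enumerate(chain_ids):
        for cb in chain_ids[i + 1:]:
            if genomes[ca] == genomes[cb]:
                continue
            mt_chain, n_chain = (ca, cb) if genomes[ca] == "mt" else (cb, ca)
            for rm in structure.chains[mt_chain]:
                for rn in structure.chains[n_chain]:
                    d = _min_distance(rm, rn)
                    if criterion == "distance":
                        hit = d <= cutoff
                    else:
                        hit = _max_overlap(rm, rn) >= overlap_threshold
                    if hit:
                        pairs.append(ContactPair(
                            mt_gene=structure.chain_to_gene[mt_chain],
                            mt_chain=mt_chain, mt_residue=rm.number,
                            n_gene=structure.chain_to_gene[n_chain],
                            n_chain=n_chain, n_residue=rn.number,
                            distance=d))
    pairs.sort(key=lambda p: (p.mt_gene, p.mt_residue, p.n_gene, p.n_residue))
    return pairs


# ---------------------------------------------------------------------------
# Residue -> alignment column mapping
# ---------------------------------------------------------------------------

def map_residue_to_column(chain_sequence: str, residue_index: int,
                          alignment: Alignment, reference_taxon: str,
                          min_identity: float = 0.5) -> int | None:
    """Map a 1-based chain residue index to a 1-based alignment column.

    The chain sequence is globally aligned (match 1, mismatch -1, gap -2)
    against the reference taxon's ungapped row; the residue position is
    carried through that alignment and then through the reference row's
    gaps. Returns ``None`` (with a warning) when the residue falls in an
    unaligned region; refuses outright if the chain and reference share
    <50% identity, which suggests a wrong chain/gene pairing.
    """
    if not 1 <= residue_index <= len(chain_sequence):
        raise InvalidInputError("residue index outside chain")
    row = alignment.sequence_of(reference_taxon)
    ungapped = "".join(c for c in row if c not in "-.")
    # alignment-column index of each ungapped residue
    col_of = [i + 1 for i, c in enumerate(row) if c not in "-."]

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aln = aligner.align(chain_sequence, ungapped)[0]

    chain_to_ref: dict[int, int] = {}
    matches = 0
    aligned_cols = 0
    for (a_start, a_end), (b_start, b_end) in zip(*aln.aligned):
        for k in range(a_end - a_start):
            ai, bi = a_start + k, b_start + k
            chain_to_ref[ai] = bi
            aligned_cols += 1
            if chain_sequence[ai] == ungapped[bi]:
                matches += 1
    identity = matches / max(aligned_cols, 1)
    if identity < min_identity:
        raise InvalidInputError(
            f"chain/reference identity {identity:.0%} below "
            f"{min_identity:.0%}: wrong chain or gene pairing suspected")
    ref_pos = chain_to_ref.get(residue_index - 1)
    if ref_pos is None:
        logger.warning("residue %d not aligned to the reference",
                       residue_index)
        return None
    return col_of[ref_pos]


def map_pairs_to_columns(pairs: list[ContactPair], structure: Structure,
                         alignments: dict[str, Alignment],
                         reference_taxon: str) -> list[ContactPair]:
    """Fill in mt/n alignment columns for every contact pair in place.

    ``alignments`` maps gene name to its amino-acid alignment. Pairs
    whose residue cannot be mapped keep ``None`` columns.
    """
    seq_cache: dict[str, str] = {}
    index_cache: dict[tuple[str, int], int | None] = {}
    for pair in pairs:
        for side in ("mt", "n"):
            chain = getattr(pair, f"{side}_chain")
            gene = getattr(pair, f"{side}_gene")
            resnum = getattr(pair, f"{side}_residue")
            if gene not in alignments:
                continue
            key = (chain, resnum)
            if key not in index_cache:
                if chain not in seq_cache:
                    seq_cache[chain] = structure.chain_sequence(chain)
                numbers = [r.number for r in structure.chains[chain]]
                try:
                    idx = numbers.index(resnum) + 1
                except ValueError:
                    index_cache[key] = None
                else:
                    index_cache[key] = map_residue_to_column(
                        seq_cache[chain], idx, alignments[gene],
                        reference_taxon)
            setattr(pair, f"{side}_column", index_cache[key])
    return pairs


# ---------------------------------------------------------------------------
# Gene classification
# ---------------------------------------------------------------------------

def classify_contact_genes(pairs: list[ContactPair], genes: list[str],
                           gene_lengths: dict[str, int] | None = None
                           ) -> tuple[dict[str, str], dict[str, float]]:
    """Contact/non-contact gene labels and per-gene contact fractions.

    A gene is "contact" iff it appears in at least one pair. The fraction
    is the number of distinct contact residues over the gene length
    (available only when ``gene_lengths`` is given).
    """
    residues: dict[str, set[int]] = {g: set() for g in genes}
    for p in pairs:
        if p.mt_gene in residues:
            residues[p.mt_gene].add(p.mt_residue)
        if p.n_gene in residues:
            residues[p.n_gene].add(p.n_residue)
    labels = {g: ("contact" if residues[g] else "non-contact")
              for g in genes}
    fractions = {}
    for g in genes:
        if gene_lengths and gene_lengths.get(g):
            fractions[g] = len(residues[g]) / gene_lengths[g]
    return labels, fractions


def pairs_to_tsv(pairs: list[ContactPair], path) -> None:
    """Write the contact-pair table (author residue numbering, 1-based columns)."""
    with open(path, "w") as fh:
        fh.write("mt_gene\tmt_residue\tmt_column\t"
                 "n_gene\tn_residue\tn_column\tdistance_A\n")
        for p in pairs:
            fh.write(f"{p.mt_gene}\t{p.mt_residue}\t"
                     f"{'' if p.mt_column is None else p.mt_column}\t"
                     f"{p.n_gene}\t{p.n_residue}\t"
                     f"{'' if p.n_column is None else p.n_column}\t"
                     f"{p.distance:.3f}\n")


def pairs_from_tsv(path) -> list[ContactPair]:
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(ContactPair(
            mt_gene=str(row.mt_gene), mt_chain="", mt_residue=int(row.mt_residue),
            n_gene=str(row.n_gene), n_chain="", n_residue=int(row.n_residue),
            distance=float(row.distance_A),
            mt_column=None if pd.isna(row.mt_column) else int(row.mt_column),
            n_column=None if pd.isna(row.n_column) else int(row.n_column)))
    return out
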