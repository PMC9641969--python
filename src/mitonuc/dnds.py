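"""Gene-wise dN/dS by Nei–Gojobori (1986) counting and group comparisons.

Per-codon synonymous/nonsynonymous *sites* are counted fractionally over
the nine single-nucleotide neighbors of each codon (mutations to stop
codons are excluded from the denominator). *Differences* between two
codons that differ at more than one position are averaged over all
minimal mutational pathways, excluding pathways that pass through a stop
codon. Proportions are corrected with the Jukes–Cantor formula
``d = -(3/4) ln(1 - (4/3) p)``; a pair with ``p >= 3/4`` is saturated and
excluded (never truncated). A gene's dN and dS are means over all
unordered taxon pairs and its omega is the ratio of those means.

Mitochondrial genes are translated with the vertebrate mitochondrial
code, nuclear genes with the standard code.

Group contrasts of gene-wise omegas (e.g. N-mt OXPHOS versus glycolysis)
use one-way ANOVA with Tukey HSD adjusted pairwise comparisons, and the
relationship between omega and a gene's fraction of structural contact
residues is summarized by ordinary least squares.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from .core import Alignment, InvalidInputError, is_gap

logger = logging.getLogger("mitonuc.dnds")

STANDARD_CODE = 1
VERTEBRATE_MITO_CODE = 2

_DNA = "TCAG"


@lru_cache(maxsize=None)
def _code(table_id: int):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), frozenset(table.stop_codons)


@dataclass
class DnDsResult:
    gene: str
    syn_sites: float            # S
    nonsyn_sites: float         # N
    syn_diffs: float            # Sd
    nonsyn_diffs: float         # Nd
    d_s: float | None
    d_n: float | None
    omega: float | None         # None when dS = 0 or saturated
    n_pairs: int = 1
    n_saturated: int = 0
    saturated: bool = False


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    mean_difference: float
    p_adjusted: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_adjusted <= 1.0000001:
            raise InvalidInputError("adjusted P outside [0, 1]")


# ---------------------------------------------------------------------------
# Site and difference counting
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def count_sites_ng86(codon: str, table_id: int = STANDARD_CODE
                     ) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Each position contributes the fraction of its non-stop
    single-nucleotide changes that are synonymous; the two fractions sum
    to 1 per position, so syn + nonsyn = 3 for every codon.
    """
    codon = codon.upper()
    fwd, stops = _code(table_id)
    if codon in stops:
        raise InvalidInputError(f"stop codon {codon}")
    if codon not in fwd:
        raise InvalidInputError(f"not a codon: {codon!r}")
    syn = 0.0
    for pos in range(3):
        n_ok = 0
        n_syn = 0
        for nt in _DNA:
            if nt == codon[pos]:
                continue
            mutant = codon[:pos] + nt + codon[pos + 1:]
            if mutant in stops:
                continue
            n_ok += 1
            if fwd[mutant] == fwd[codon]:
                n_syn += 1
        if n_ok:
            syn += n_syn / n_ok
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def count_diffs_ng86(codon_a: str, codon_b: str,
                     table_id: int = STANDARD_CODE
                     ) -> tuple[float, float] | None:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged over all minimal mutational pathways; pathways through a
    stop codon are excluded. Returns ``None`` when every pathway is
    blocked by stops (the codon pair is then skipped).
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    fwd, stops = _code(table_id)
    for c in (codon_a, codon_b):
        if c in stops:
            raise InvalidInputError(f"stop codon {c}")
        if c not in fwd:
            raise InvalidInputError(f"not a codon: {c!r}")
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0
    totals = []
    for order in permutations(positions):
        cur = codon_a
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in stops:
                blocked = True
                break
            if fwd[nxt] == fwd[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if not blocked:
            totals.append((syn, nonsyn))
    if not totals:
        return None
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def _jc_correct(p: float) -> float | None:
    if p < 0:
        raise InvalidInputError("negative proportion")
    if p >= 0.75:
        return None  # saturated
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def pairwise_dnds_ng86(seq_a: str, seq_b: str,
                       table_id: int = STANDARD_CODE,
                       gene: str = "pair") -> DnDsResult:
    """NG86 dN/dS between two aligned in-frame nucleotide sequences.

    Codons containing gaps or ambiguity in either sequence are skipped,
    as are the (rare) codon pairs whose every minimal pathway passes
    through a stop codon.
    """
    if len(seq_a) != len(seq_b):
        raise InvalidInputError("sequences differ in length")
    if len(seq_a) % 3:
        raise InvalidInputError("length not divisible by 3")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    fwd, stops = _code(table_id)
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        if is_gap(ca) or is_gap(cb) or ca not in fwd or cb not in fwd:
            continue
        diffs = count_diffs_ng86(ca, cb, table_id)
        if diffs is None:
            logger.debug("codon pair %s/%s skipped: all pathways hit stops",
                         ca, cb)
            continue
        sa, na = count_sites_ng86(ca, table_id)
        sb, nb = count_sites_ng86(cb, table_id)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        Sd += diffs[0]
        Nd += diffs[1]
    if S == 0 and N == 0:
        raise InvalidInputError("no comparable codons")
    p_s = Sd / S if S > 0 else 0.0
    p_n = Nd / N if N > 0 else 0.0
    d_s = _jc_correct(p_s)
    d_n = _jc_correct(p_n)
    saturated = d_s is None or d_n is None
    omega = None
    if not saturated and d_s is not None and d_s > 0:
        omega = d_n / d_s
    return DnDsResult(gene=gene, syn_sites=S, nonsyn_sites=N,
                      syn_diffs=Sd, nonsyn_diffs=Nd, d_s=d_s, d_n=d_n,
                      omega=omega, saturated=saturated)


def geneset_dnds(alignment: Alignment, table_id: int = STANDARD_CODE,
                 gene: str | None = None) -> DnDsResult:
    """Gene-level dN/dS: mean pairwise dN and dS over unordered taxon pairs.

    Saturated pairs are excluded and counted; omega is the ratio of the
    mean dN to the mean dS. A gene whose every pair is saturated is
    flagged (``saturated=True``) and excluded from group tests upstream.
    """
    if alignment.molecule != "codon":
        raise InvalidInputError("geneset_dnds requires a codon alignment")
    if alignment.n_taxa < 2:
        raise InvalidInputError("need >= 2 taxa")
    name = gene or alignment.gene_set or "gene"
    results = []
    n_sat = 0
    for a, b in combinations(range(alignment.n_taxa), 2):
        res = pairwise_dnds_ng86(alignment.sequences[a],
                                 alignment.sequences[b], table_id, name)
        if res.saturated:
            n_sat += 1
        else:
            results.append(res)
    if not results:
        return DnDsResult(gene=name, syn_sites=0, nonsyn_sites=0,
                          syn_diffs=0, nonsyn_diffs=0, d_s=None, d_n=None,
                          omega=None, n_pairs=0, n_saturated=n_sat,
                          saturated=True)
    d_n = float(np.mean([r.d_n for r in results]))
    d_s = float(np.mean([r.d_s for r in results]))
    omega = d_n / d_s if d_s > 0 else None
    return DnDsResult(
        gene=name,
        syn_sites=float(np.mean([r.syn_sites for r in results])),
        nonsyn_sites=float(np.mean([r.nonsyn_sites for r in results])),
        syn_diffs=float(np.mean([r.syn_diffs for r in results])),
        nonsyn_diffs=float(np.mean([r.nonsyn_diffs for r in results])),
        d_s=d_s, d_n=d_n, omega=omega, n_pairs=len(results),
        n_saturated=n_sat)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

def branchwise_dnds(states: dict[int, list[str | None]], tree,
                    table_id: int = STANDARD_CODE,
                    gene: str = "gene") -> DnDsResult:
    """NG86 over reconstructed ancestor->descendant codon changes.

    Optional branch-wise mode: sums fractional synonymous/nonsynonymous
    differences over every branch of the tree (per-branch sites weighted
    by branch length are not needed here — the counts are summed over
    actual reconstructed changes and the site opportunities averaged
    over node states). Useful when pairwise comparisons would saturate.
    """
    fwd, stops = _code(table_id)
    S = N = Sd = Nd = 0.0
    n_cols = len(states[0])
    n_states = 0
    for node in tree.nodes:
        for col in range(n_cols):
            c = states[node.id][col]
            if c is None or c in stops or c not in fwd:
                continue
            s, n = count_sites_ng86(c, table_id)
            S += s
            N += n
            n_states += 1
        if node.parent < 0:
            continue
        for col in range(n_cols):
            a = states[node.parent][col]
            b = states[node.id][col]
            if a is None or b is None or a in stops or b in stops:
                continue
            d = count_diffs_ng86(a, b, table_id)
            if d is not None:
                Sd += d[0]
                Nd += d[1]
    if n_states == 0:
        raise InvalidInputError("no reconstructed codon states")
    # average per-codon opportunities over all node states
    S, N = S / len(tree.nodes), N / len(tree.nodes)
    p_s = Sd / S if S > 0 else 0.0
    p_n = Nd / N if N > 0 else 0.0
    d_s, d_n = _jc_correct(p_s), _jc_correct(p_n)
    saturated = d_s is None or d_n is None
    omega = d_n / d_s if not saturated and d_s > 0 else None
    return DnDsResult(gene=gene, syn_sites=S, nonsyn_sites=N, syn_diffs=Sd,
                      nonsyn_diffs=Nd, d_s=d_s, d_n=d_n, omega=omega,
                      saturated=saturated)


def compare_groups(omega_by_gene: dict[str, float],
                   groups: dict[str, str]) -> list[GroupComparison]:
    """One-way ANOVA over gene-wise omegas with Tukey HSD pairwise tests.

    Groups with fewer than 2 genes are excluded with a warning.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    by_group: dict[str, list[float]] = {}
    for gene, omega in omega_by_gene.items():
        if gene not in groups or omega is None:
            continue
        by_group.setdefault(groups[gene], []).append(omega)
    kept = {g: v for g, v in by_group.items() if len(v) >= 2}
    for g in by_group:
        if g not in kept:
            logger.warning("group %s excluded: fewer than 2 genes", g)
    if len(kept) < 2:
        raise InvalidInputError("need >= 2 groups with >= 2 genes each")

    values = np.concatenate([np.asarray(v, dtype=float)
                             for v in kept.values()])
    labels = np.concatenate([[g] * len(v) for g, v in kept.items()])
    if np.ptp(values) == 0:
        # identical omegas everywhere: all differences 0, all P = 1
        return [GroupComparison(a, b, 0.0, 1.0)
                for a, b in combinations(sorted(kept), 2)]
    res = pairwise_tukeyhsd(values, labels)
    pairs = list(combinations(range(len(res.groupsunique)), 2))
    return [GroupComparison(str(res.groupsunique[i]),
                            str(res.groupsunique[j]),
                            float(diff), float(p))
            for (i, j), diff, p in zip(pairs, res.meandiffs, res.pvalues)]


def contact_fraction_trend(omega_by_gene: dict[str, float],
                           contact_fraction_by_gene: dict[str, float]
                           ) -> tuple[float, float, float]:
    """OLS slope of omega on per-gene contact-residue fraction.

    Returns (slope, Pearson r, two-sided P).
    """
    genes = [g for g in omega_by_gene
             if g in contact_fraction_by_gene and omega_by_gene[g] is not None]
    if len(genes) < 3:
        raise InvalidInputError("need >= 3 genes with both values")
    x = np.array([contact_fraction_by_gene[g] for g in genes])
    y = np.array([omega_by_gene[g] for g in genes])
    if np.ptp(x) == 0:
        raise InvalidInputError("degenerate input: constant contact fraction")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue), float(res.pvalue)
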