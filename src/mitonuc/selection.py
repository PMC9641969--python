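"""Site-level positive selection and functional-nodal-mutation flags.

Positive selection at a codon site is detected by a counting test in the
spirit of SLAC: substitutions at the site are replayed over the
reconstructed ancestral codons (optionally restricted to a foreground
set of branches), split into synonymous and nonsynonymous changes, and
compared with the split expected from the site's NG86 mutational
opportunities under neutrality via a one-sided binomial test for
nonsynonymous excess. This is a deliberate, documented stand-in for
likelihood branch-site machinery: it preserves the comparison structure
(two reporting tiers, a foreground-branch mask) but makes no claim of
categorical agreement with codeml site lists.

The functional-nodal-mutation (FNM) flag is reduced to the frequency
component of predictive deleteriousness models: a substitution is
flagged ("frequency-FNM") when its derived amino acid is rare (below a
threshold proportion) among the non-gap residues of its alignment
column. The structural-stability component requires per-species
structures and is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special

from .core import Alignment, InvalidInputError, Phylogeny, is_gap
from .dnds import STANDARD_CODE, _code, count_diffs_ng86, count_sites_ng86
from .ordering import OrderingTestResult, SubstitutionEvent, \
    fisher_mtfirst_enrichment

logger = logging.getLogger("mitonuc.selection")


@dataclass
class SiteSelectionResult:
    gene: str
    site: int                     # 0-based codon index
    n_changes: float
    nonsyn_changes: float
    nonsyn_opportunity: float     # expected nonsyn fraction under neutrality
    excess: float                 # observed - expected nonsyn fraction
    p_value: float
    selected: bool
    stringent: bool

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1.0000001:
            raise InvalidInputError("P outside [0, 1]")
        if self.stringent and not self.selected:
            raise InvalidInputError("stringent implies selected")


@dataclass
class FnmFlag:
    gene: str
    column: int
    derived_state: str
    frequency: float
    threshold: float
    flagged: bool


# ---------------------------------------------------------------------------
# Site selection test
# ---------------------------------------------------------------------------

def _branch_set(tree: Phylogeny,
                foreground: set[int] | None) -> set[int]:
    """Foreground branches plus all their descendants (whole tree if None)."""
    if foreground is None:
        return set(tree.branch_ids)
    out: set[int] = set()
    for b in foreground:
        out.add(b)
        stack = list(tree.nodes[b].children)
        while stack:
            nid = stack.pop()
            out.add(nid)
            stack.extend(tree.nodes[nid].children)
    return out


def site_selection_test(states: dict[int, list[str | None]],
                        tree: Phylogeny, site: int,
                        gene: str = "gene",
                        foreground: set[int] | None = None,
                        alpha: float = 0.05,
                        stringent_alpha: float = 0.01,
                        table_id: int = STANDARD_CODE) -> SiteSelectionResult:
    """Binomial test for nonsynonymous excess at one codon site.

    ``states`` is a codon-level ancestral reconstruction (as produced by
    :func:`mitonuc.ordering.reconstruct_ancestral` on a codon
    alignment). Changes on branches outside the foreground set (a set of
    node ids whose subtrees form the foreground) are ignored. Fractional
    counts from multi-nucleotide codon changes are handled through the
    regularized incomplete beta form of the binomial tail.
    """
    branches = _branch_set(tree, foreground)
    fwd, stops = _code(table_id)
    syn = nonsyn = 0.0
    opp_syn = opp_nonsyn = 0.0
    for node in tree.nodes[1:]:
        if node.id not in branches:
            continue
        a = states[node.parent][site]
        b = states[node.id][site]
        if a is None or b is None or a in stops or b in stops:
            continue
        if a != b:
            diffs = count_diffs_ng86(a, b, table_id)
            if diffs is None:
                continue
            syn += diffs[0]
            nonsyn += diffs[1]
        # mutational opportunity accumulates along every examined branch
        s_sites, n_sites = count_sites_ng86(a, table_id)
        opp_syn += s_sites * node.length
        opp_nonsyn += n_sites * node.length
    n_changes = syn + nonsyn
    opp_total = opp_syn + opp_nonsyn
    p_nonsyn = opp_nonsyn / opp_total if opp_total > 0 else 0.75
    if n_changes == 0:
        return SiteSelectionResult(gene, site, 0.0, 0.0, p_nonsyn, 0.0, 1.0,
                                   False, False)
    # P(X >= nonsyn) for X ~ Binomial(n_changes, p_nonsyn), continuous in
    # the fractional counts: I_p(k, n - k + 1)
    k = nonsyn
    n = n_changes
    if k <= 0:
        p = 1.0
    else:
        p = float(special.betainc(k, n - k + 1.0, p_nonsyn))
    excess = (nonsyn / n_changes) - p_nonsyn
    return SiteSelectionResult(gene, site, n_changes, nonsyn, p_nonsyn,
                               excess, p,
                               selected=p < alpha,
                               stringent=p < min(stringent_alpha, alpha))


def scan_sites(states: dict[int, list[str | None]], tree: Phylogeny,
               gene: str = "gene", foreground: set[int] | None = None,
               alpha: float = 0.05, stringent_alpha: float = 0.01,
               table_id: int = STANDARD_CODE) -> list[SiteSelectionResult]:
    n_sites = len(states[0])
    return [site_selection_test(states, tree, s, gene, foreground,
                                alpha, stringent_alpha, table_id)
            for s in range(n_sites)]


# ---------------------------------------------------------------------------
# Proportions and enrichment
# ---------------------------------------------------------------------------

def proportion_selected(results: list[SiteSelectionResult],
                        partition: dict[tuple[str, int], str]
                        ) -> dict[str, dict]:
    """Fraction of sites selected per partition cell (e.g. contact vs not).

    ``partition`` maps (gene, site) to a cell label; cells with no
    tested sites are reported as absent.
    """
    cells: dict[str, list[bool]] = {}
    for r in results:
        label = partition.get((r.gene, r.site))
        if label is None:
            continue
        cells.setdefault(label, []).append(r.selected)
    return {label: {"n": len(v), "selected": int(sum(v)),
                    "proportion": sum(v) / len(v)}
            for label, v in cells.items()}


def contact_enrichment(results: list[SiteSelectionResult],
                       contact: dict[tuple[str, int], bool]
                       ) -> OrderingTestResult:
    """Fisher exact test: selection status x contact status over sites."""
    table = np.zeros((2, 2), dtype=int)
    for r in results:
        is_contact = contact.get((r.gene, r.site))
        if is_contact is None:
            continue
        table[0 if is_contact else 1][0 if r.selected else 1] += 1
    return fisher_mtfirst_enrichment(table)


# ---------------------------------------------------------------------------
# Functional nodal mutations (frequency proxy)
# ---------------------------------------------------------------------------

def flag_functional_nodal(event: SubstitutionEvent, alignment: Alignment,
                          threshold: float = 0.05) -> FnmFlag | None:
    """Flag a substitution whose derived residue is rare in its column.

    The derived state's frequency is computed among non-gap residues of
    the event's column across all taxa; the event is flagged
    ("frequency-FNM") iff that frequency is strictly below ``threshold``.
    Returns ``None`` for an all-gap column.
    """
    if not 0 <= threshold <= 1:
        raise InvalidInputError("threshold must be in [0, 1]")
    col = event.column
    if alignment.molecule == "codon":
        residues = [seq[col * 3:(col + 1) * 3] for seq in alignment.sequences]
    else:
        residues = [seq[col] for seq in alignment.sequences]
    observed = [r for r in residues if not is_gap(r)]
    if not observed:
        logger.warning("all-gap column %d: cannot flag", col)
        return None
    freq = observed.count(event.to_state) / len(observed)
    return FnmFlag(gene=event.gene, column=col,
                   derived_state=event.to_state, frequency=freq,
                   threshold=threshold, flagged=freq < threshold)
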