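"""Branch lengths on a fixed topology and root-to-tip evolutionary rates.

The species topology is taken as known (as when rate estimation is
constrained to an accepted species tree) and only branch lengths are
estimated, by maximizing the Felsenstein pruning likelihood under a
20-state equal-exchangeability (Poisson) amino-acid model, optionally with
4-category discrete-gamma rate variation or a user-supplied 20x20
exchangeability matrix. Root-to-tip path sums of the fitted lengths are
the per-lineage evolutionary rates consumed by the ERC stage.

Gaps and ambiguity codes are treated as missing data (partial likelihood
1 for every state).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from .core import (AMINO_ACIDS, Alignment, InvalidInputError, Phylogeny,
                   RateVector, rate_vector_from_tree)

logger = logging.getLogger("mitonuc.rates")

_N = len(AMINO_ACIDS)
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


# ---------------------------------------------------------------------------
# Concatenation
# ---------------------------------------------------------------------------

def concatenate_alignments(alignments: list[Alignment],
                           gene_set: str | None = None,
                           max_gap_fraction: float = 0.5) -> Alignment:
    """Concatenate per-gene alignments into one rate-estimation unit.

    Taxa missing from a gene are padded with gaps for that gene's block;
    taxa whose total padded fraction exceeds ``max_gap_fraction`` are
    dropped (and logged). Per-gene column offsets are recorded on the
    result.
    """
    if not alignments:
        raise InvalidInputError("no alignments to concatenate")
    molecule = alignments[0].molecule
    if any(a.molecule != molecule for a in alignments):
        raise InvalidInputError("molecule types differ across alignments")

    taxa: list[str] = []
    for aln in alignments:
        for t in aln.taxa:
            if t not in taxa:
                taxa.append(t)

    offsets: dict[str, int] = {}
    blocks: dict[str, list[str]] = {t: [] for t in taxa}
    padded: dict[str, int] = {t: 0 for t in taxa}
    offset = 0
    for k, aln in enumerate(alignments):
        name = aln.gene_set or f"gene{k}"
        if name in offsets:
            name = f"{name}.{k}"
        offsets[name] = offset
        offset += aln.length
        for t in taxa:
            if t in aln.taxa:
                blocks[t].append(aln.sequence_of(t))
            else:
                blocks[t].append("-" * aln.length)
                padded[t] += aln.length
                logger.info("taxon %s missing from %s: padded %d columns",
                            t, name, aln.length)

    total = offset
    kept = [t for t in taxa if padded[t] / total <= max_gap_fraction]
    for t in taxa:
        if t not in kept:
            logger.warning("taxon %s excluded: %.0f%% gap padding",
                           t, 100 * padded[t] / total)
    return Alignment(
        taxa=kept, sequences=["".join(blocks[t]) for t in kept],
        molecule=molecule,
        gene_set=gene_set or (alignments[0].gene_set if len(alignments) == 1
                              else "concatenated"),
        offsets=offsets)


# ---------------------------------------------------------------------------
# Substitution model
# ---------------------------------------------------------------------------

class AminoModel:
    """Reversible 20-state amino-acid model with uniform frequencies.

    The default has equal exchangeabilities, for which the transition
    matrix has the closed form
    ``P(t) = e^{-mu t} I + (1 - e^{-mu t})/20 J`` with ``mu = 20/19``
    (branch lengths in expected substitutions per site). Passing
    ``gamma_alpha`` averages the likelihood over 4 equal-probability
    discrete-gamma rate categories (category rates at quantile midpoints,
    rescaled to mean 1). An arbitrary symmetric exchangeability matrix may
    be supplied for LG/mtART-like behavior.
    """

    def __init__(self, gamma_alpha: float | None = None, n_categories: int = 4,
                 exchangeabilities: np.ndarray | None = None):
        self.gamma_alpha = gamma_alpha
        if gamma_alpha is None:
            self.category_rates = np.array([1.0])
        else:
            if gamma_alpha <= 0:
                raise InvalidInputError("gamma alpha must be > 0")
            q = (np.arange(n_categories) + 0.5) / n_categories
            r = gamma_dist.ppf(q, a=gamma_alpha, scale=1.0 / gamma_alpha)
            self.category_rates = r / r.mean()
        self._eig = None
        if exchangeabilities is not None:
            S = np.asarray(exchangeabilities, dtype=float)
            if S.shape != (_N, _N) or not np.allclose(S, S.T):
                raise InvalidInputError(
                    "exchangeability matrix must be symmetric 20x20")
            Q = S / _N
            np.fill_diagonal(Q, 0.0)
            np.fill_diagonal(Q, -Q.sum(axis=1))
            mean_rate = -np.mean(np.diag(Q))
            Q = Q / mean_rate
            # symmetric under uniform frequencies -> real eigen system
            w, V = np.linalg.eigh(Q)
            self._eig = (w, V)

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        t = max(t, 0.0) * rate
        if self._eig is None:
            mu = _N / (_N - 1)
            e = np.exp(-mu * t)
            return e * np.eye(_N) + (1.0 - e) / _N * np.ones((_N, _N))
        w, V = self._eig
        return (V * np.exp(w * t)) @ V.T


def _resolve_model(model, gamma_alpha=None,
                   exchangeabilities=None) -> AminoModel:
    if isinstance(model, AminoModel):
        return model
    if model == "poisson":
        return AminoModel(exchangeabilities=exchangeabilities)
    if model == "poisson_gamma":
        alpha = 0.5 if gamma_alpha is None else gamma_alpha
        return AminoModel(gamma_alpha=alpha,
                          exchangeabilities=exchangeabilities)
    raise InvalidInputError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def _site_patterns(alignment: Alignment,
                   tree: Phylogeny) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Compress columns to unique patterns.

    Returns (patterns, weights, tip_ids): patterns is an integer array of
    shape (n_patterns, n_tips) with -1 for missing states, ordered to
    match ``tip_ids``.
    """
    tip_ids = tree.tip_ids
    try:
        rows = [alignment.sequence_of(tree.nodes[t].name) for t in tip_ids]
    except KeyError as exc:
        raise InvalidInputError(f"tree tip {exc} absent from alignment")
    mat = np.full((alignment.length, len(tip_ids)), -1, dtype=np.int8)
    for j, row in enumerate(rows):
        for i, c in enumerate(row):
            mat[i, j] = _AA_INDEX.get(c, -1)
    patterns, weights = np.unique(mat, axis=0, return_counts=True)
    return patterns, weights, tip_ids


def pruning_log_likelihood(alignment: Alignment, tree: Phylogeny,
                           model="poisson", gamma_alpha: float | None = None,
                           exchangeabilities=None) -> float:
    """Exact log-likelihood of the alignment on the tree.

    Post-order pruning with uniform stationary frequencies; all-gap
    columns contribute 0 by the missing-data convention.
    """
    if alignment.length == 0:
        raise InvalidInputError("zero-length alignment")
    m = _resolve_model(model, gamma_alpha, exchangeabilities)
    patterns, weights, tip_ids = _site_patterns(alignment, tree)
    lengths = {b: tree.nodes[b].length for b in tree.branch_ids}
    return _pruning_ll(patterns, weights, tree, tip_ids, lengths, m)


def _pruning_ll(patterns, weights, tree, tip_ids, lengths,
                model: AminoModel) -> float:
    n_pat = patterns.shape[0]
    tip_col = {t: j for j, t in enumerate(tip_ids)}
    cat_site_l = np.zeros((len(model.category_rates), n_pat))
    for k, rate in enumerate(model.category_rates):
        P = {b: model.transition_matrix(lengths[b], rate)
             for b in tree.branch_ids}
        partial = {}
        scale = np.zeros(n_pat)
        for nid in tree.postorder():
            node = tree.nodes[nid]
            if node.is_tip:
                states = patterns[:, tip_col[nid]]
                part = np.ones((n_pat, _N))
                known = states >= 0
                part[known] = 0.0
                part[known, states[known]] = 1.0
            else:
                part = np.ones((n_pat, _N))
                for c in node.children:
                    part *= partial.pop(c) @ P[c].T
                mx = part.max(axis=1)
                mx[mx == 0] = 1.0
                part /= mx[:, None]
                scale += np.log(mx)
            partial[nid] = part
        root_l = partial[0].mean(axis=1)  # uniform 1/20 prior
        cat_site_l[k] = np.log(root_l) + scale

    # average likelihood over categories (equal probability)
    mx = cat_site_l.max(axis=0)
    site_ll = mx + np.log(np.mean(np.exp(cat_site_l - mx), axis=0))
    return float(np.dot(weights, site_ll))


# ---------------------------------------------------------------------------
# Branch length estimation
# ---------------------------------------------------------------------------

def estimate_branch_lengths(alignment: Alignment, topology: Phylogeny,
                            model="poisson", gamma_alpha: float | None = None,
                            exchangeabilities=None, tol: float = 1e-6,
                            max_rounds: int = 25,
                            start_length: float = 0.1,
                            max_length: float = 10.0) -> Phylogeny:
    """Maximum-likelihood branch lengths with the topology fixed.

    Coordinate ascent: each branch is optimized in turn by bounded Brent
    search on [0, ``max_length``], in rounds, until the round-over-round
    log-likelihood improvement falls below ``tol``. Existing positive
    lengths on the topology are used as starting values; otherwise every
    branch starts at ``start_length``.
    """
    m = _resolve_model(model, gamma_alpha, exchangeabilities)
    patterns, weights, tip_ids = _site_patterns(alignment, tree := topology.copy())
    lengths = {}
    for b in tree.branch_ids:
        cur = tree.nodes[b].length
        lengths[b] = cur if cur > 0 else start_length

    def ll() -> float:
        return _pruning_ll(patterns, weights, tree, tip_ids, lengths, m)

    last = ll()
    for rnd in range(max_rounds):
        for b in tree.branch_ids:
            def neg(t, _b=b):
                lengths[_b] = t
                return -_pruning_ll(patterns, weights, tree, tip_ids,
                                    lengths, m)

            current = lengths[b]
            current_ll = -neg(current)
            res = minimize_scalar(neg, bounds=(0.0, max_length),
                                  method="bounded",
                                  options={"xatol": 1e-7})
            lengths[b] = float(res.x) if -res.fun >= current_ll else current
        cur = ll()
        logger.debug("branch-length round %d: logL %.6f", rnd + 1, cur)
        if cur - last < tol:
            last = cur
            break
        last = cur
    else:
        raise RuntimeError(
            f"branch-length optimization did not converge in {max_rounds} "
            f"rounds (last logL {last:.6f})")

    for b, t in lengths.items():
        # bounded Brent cannot land exactly on the boundary; snap
        # negligible lengths (< 1e-5 subs/site) to zero
        tree.nodes[b].length = 0.0 if t < 1e-5 else t
    return tree


# ---------------------------------------------------------------------------
# Root-to-tip rates
# ---------------------------------------------------------------------------

def root_to_tip_distances(tree: Phylogeny,
                          gene_set: str = "rates") -> RateVector:
    """Per-tip sum of branch lengths along the unique root path."""
    if any(tree.nodes[b].length < 0 for b in tree.branch_ids):
        raise InvalidInputError("negative branch length")
    return rate_vector_from_tree(tree, gene_set)


def rates_to_tsv(vectors: list[RateVector], path) -> None:
    with open(path, "w") as fh:
        fh.write("taxon\tgene_set\tdistance\n")
        for vec in vectors:
            for taxon, d in vec.values.items():
                fh.write(f"{taxon}\t{vec.gene_set}\t{d:.8g}\n")


def rates_from_tsv(path) -> dict[str, RateVector]:
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    out = {}
    for gs, grp in df.groupby("gene_set"):
        out[gs] = RateVector(str(gs),
                             dict(zip(grp["taxon"], grp["distance"])))
    return out
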