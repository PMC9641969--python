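"""Evolutionary rate covariation (ERC).

Lineage rates of a target gene set are divided by the rates of a
background set of random nuclear orthologs, removing genome-wide effects
(demography, per-lineage mutation rate), and the normalized rates of two
gene sets are compared by Spearman rank correlation across taxa. To avoid
autocorrelation the background orthologs are split into two halves:
Nrand1 normalizes the mitochondrial set, Nrand2 the nuclear target sets.

Differences between two correlations (e.g. mt~N-mt versus mt~glycolysis)
are tested by jointly resampling taxa with replacement and forming a BCa
(bias-corrected and accelerated) bootstrap interval of the difference: a
difference whose 95% interval excludes zero is called statistically
robust. A phylogenetically corrected correlation via Felsenstein
independent contrasts is available as a sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import InvalidInputError, Phylogeny, RateVector

logger = logging.getLogger("mitonuc.erc")


@dataclass
class NormalizedRates:
    """Target/background rate ratios over the shared taxa."""

    gene_set: str
    values: dict[str, float]

    @property
    def taxa(self) -> list[str]:
        return list(self.values)

    def __getitem__(self, taxon: str) -> float:
        return self.values[taxon]


@dataclass
class ErcResult:
    gene_set_x: str
    gene_set_y: str
    r_s: float
    n: int
    method: str = "spearman"
    p_value: float | None = None
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not -1.0000001 <= self.r_s <= 1.0000001:
            raise InvalidInputError("correlation out of [-1, 1]")
        if self.ci is not None and self.ci[0] > self.ci[1]:
            raise InvalidInputError("CI bounds out of order")


@dataclass
class DifferenceResult:
    label_a: str
    label_b: str
    delta_r_s: float
    ci: tuple[float, float]
    n_boot: int
    ci_type: str = "bca"
    n_dropped: int = 0

    @property
    def robust(self) -> bool:
        """True when the 95% interval excludes a zero difference."""
        return self.ci[0] > 0 or self.ci[1] < 0


# ---------------------------------------------------------------------------
# Background split and normalization
# ---------------------------------------------------------------------------

def split_random_orthologs(genes: list[str],
                           seed: int) -> tuple[list[str], list[str]]:
    """Seeded split of the random orthologs into Nrand1 and Nrand2.

    Nrand1 normalizes the mt gene set and Nrand2 the nuclear target sets,
    so no target is ever normalized by the same genes as its partner.
    """
    if len(genes) < 2:
        raise InvalidInputError("need at least 2 genes to split")
    rng = np.random.default_rng(seed)
    order = list(genes)
    rng.shuffle(order)
    half = (len(order) + 1) // 2
    return order[:half], order[half:]


def normalize_rates(target: RateVector,
                    background: RateVector) -> NormalizedRates:
    """Divide target root-to-tip rates by background rates, taxon-wise.

    Taxa absent from either vector are ignored; taxa with a zero
    background rate are dropped with a warning.
    """
    shared = [t for t in target.taxa if t in background.values]
    if not shared:
        raise InvalidInputError("no shared taxa between target and background")
    values = {}
    for t in shared:
        if background[t] <= 0:
            logger.warning("taxon %s dropped: background rate is 0", t)
            continue
        values[t] = target[t] / background[t]
    if not values:
        raise InvalidInputError("all shared taxa had zero background rate")
    return NormalizedRates(target.gene_set, values)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------

def _paired(x: NormalizedRates, y: NormalizedRates,
            taxa: list[str] | None = None):
    shared = [t for t in x.taxa if t in y.values]
    if taxa is not None:
        shared = [t for t in shared if t in taxa]
    return (shared, np.array([x[t] for t in shared]),
            np.array([y[t] for t in shared]))


def spearman_erc(x: NormalizedRates, y: NormalizedRates,
                 taxa: list[str] | None = None) -> ErcResult:
    """Spearman rank correlation of two normalized rate vectors.

    Ties receive average ranks. Restricting ``taxa`` supports
    lineage-subset analyses (minimum 5 taxa enforced there by the
    pipeline; 3 here as the mathematical floor).
    """
    shared, xv, yv = _paired(x, y, taxa)
    if len(shared) < 3:
        raise InvalidInputError("need >= 3 shared taxa")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise InvalidInputError("degenerate input: constant ranks")
    r, p = stats.spearmanr(xv, yv)
    return ErcResult(x.gene_set, y.gene_set, float(r), len(shared),
                     p_value=float(p))


def _spearman_rows(xm: np.ndarray, ym: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation of two equally shaped matrices."""
    rx = stats.rankdata(xm, axis=1)
    ry = stats.rankdata(ym, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def bootstrap_difference(mt: NormalizedRates, set_a: NormalizedRates,
                         set_b: NormalizedRates, n_boot: int = 10000,
                         ci: str = "bca", seed: int = 0,
                         alpha: float = 0.05,
                         taxa: list[str] | None = None) -> DifferenceResult:
    """BCa bootstrap CI for r_s(mt, A) - r_s(mt, B).

    Taxa are resampled with replacement jointly (paired rows across the
    three vectors); each replicate recomputes both correlations.
    Replicates with constant ranks are dropped and counted; more than 10%
    dropped raises a diagnostic error. Bias correction z0 comes from the
    fraction of replicates below the point estimate; acceleration from a
    leave-one-taxon-out jackknife.
    """
    if n_boot < 2:
        raise InvalidInputError("n_boot must be >= 2")
    if ci not in ("bca", "percentile"):
        raise InvalidInputError(f"unknown ci type {ci!r}")
    shared = [t for t in mt.taxa
              if t in set_a.values and t in set_b.values]
    if taxa is not None:
        shared = [t for t in shared if t in taxa]
    n = len(shared)
    if n < 4:
        raise InvalidInputError("need >= 4 taxa shared across all vectors")

    xv = np.array([mt[t] for t in shared])
    av = np.array([set_a[t] for t in shared])
    bv = np.array([set_b[t] for t in shared])

    def delta(x, a, b) -> float:
        return (stats.spearmanr(x, a).statistic
                - stats.spearmanr(x, b).statistic)

    theta = delta(xv, av, bv)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    reps = (_spearman_rows(xv[idx], av[idx])
            - _spearman_rows(xv[idx], bv[idx]))
    ok = np.isfinite(reps)
    n_dropped = int(n_boot - ok.sum())
    if n_dropped > 0.1 * n_boot:
        raise RuntimeError(
            f"{n_dropped}/{n_boot} degenerate bootstrap replicates")
    reps = reps[ok]

    if ci == "percentile":
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        return DifferenceResult(set_a.gene_set, set_b.gene_set,
                                float(theta), (float(lo), float(hi)),
                                n_boot, "percentile", n_dropped)

    # BCa
    prop = np.mean(reps < theta)
    prop = min(max(prop, 1.0 / (len(reps) + 1)), 1 - 1.0 / (len(reps) + 1))
    z0 = stats.norm.ppf(prop)
    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        jack[i] = delta(xv[mask], av[mask], bv[mask])
        mask[i] = True
    jm = jack.mean()
    num = ((jm - jack) ** 3).sum()
    den = 6.0 * (((jm - jack) ** 2).sum()) ** 1.5
    a = 0.0 if den == 0 else num / den
    z_lo, z_hi = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    q_lo = stats.norm.cdf(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo)))
    q_hi = stats.norm.cdf(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi)))
    lo, hi = np.quantile(reps, [q_lo, q_hi])
    return DifferenceResult(set_a.gene_set, set_b.gene_set, float(theta),
                            (float(lo), float(hi)), n_boot, "bca", n_dropped)


def lineage_subset_erc(x: NormalizedRates, y: NormalizedRates,
                       taxa: list[str], subset_name: str = "subset",
                       min_size: int = 5) -> ErcResult:
    """ERC restricted to a named lineage (e.g. one mammalian order).

    The taxon filter is applied before correlation; subsets smaller than
    ``min_size`` are refused since a rank correlation over a handful of
    taxa is uninformative.
    """
    shared = [t for t in taxa if t in x.values and t in y.values]
    if len(shared) < min_size:
        raise InvalidInputError(
            f"lineage subset {subset_name!r} has {len(shared)} taxa; "
            f"minimum is {min_size}")
    res = spearman_erc(x, y, taxa=shared)
    res.method = f"spearman[{subset_name}]"
    return res


# ---------------------------------------------------------------------------
# Phylogenetically corrected correlation
# ---------------------------------------------------------------------------

def independent_contrasts(tree: Phylogeny, trait: dict[str, float],
                          eps: float = 1e-8) -> np.ndarray:
    """Felsenstein independent contrasts of a tip trait.

    Zero-length internal branches are floored at ``eps`` (with a
    warning). Returns n_tips - 1 standardized contrasts in a
    deterministic node order. Multifurcations are resolved by sequential
    pairing of the first two children.
    """
    work = tree.copy()
    floored = False
    for b in work.branch_ids:
        if work.nodes[b].length <= 0:
            work.nodes[b].length = eps
            floored = True
    if floored:
        logger.warning("zero-length branches floored at %g for contrasts", eps)

    value: dict[int, float] = {}
    # adjusted branch length above each processed node
    adj: dict[int, float] = {}
    contrasts: list[float] = []
    for nid in work.postorder():
        node = work.nodes[nid]
        own = node.length if node.parent >= 0 else 0.0
        if node.is_tip:
            value[nid] = trait[node.name]
            adj[nid] = own
            continue
        # fold children pairwise (handles multifurcations sequentially)
        v1, l1 = value[node.children[0]], adj[node.children[0]]
        for other in node.children[1:]:
            v2, l2 = value[other], adj[other]
            contrasts.append((v1 - v2) / np.sqrt(l1 + l2))
            v1 = (v1 * l2 + v2 * l1) / (l1 + l2)
            l1 = l1 * l2 / (l1 + l2)
        value[nid] = v1
        adj[nid] = own + l1
    return np.array(contrasts)


def pic_correlation(tree: Phylogeny, x: NormalizedRates,
                    y: NormalizedRates) -> ErcResult:
    """Pearson correlation (through the origin) of independent contrasts.

    Stands in for an unspecified phylogenetic correlation test; the
    contrasts are computed on the supplied tree's branch lengths.
    """
    shared = [t for t in x.taxa if t in y.values]
    if len(shared) < 3:
        raise InvalidInputError("need >= 3 shared taxa")
    sub = _prune_to(tree, shared)
    cx = independent_contrasts(sub, {t: x[t] for t in shared})
    cy = independent_contrasts(sub, {t: y[t] for t in shared})
    den = np.sqrt((cx ** 2).sum() * (cy ** 2).sum())
    if den == 0:
        raise InvalidInputError("degenerate contrasts")
    r = float((cx * cy).sum() / den)
    return ErcResult(x.gene_set, y.gene_set, r, len(shared), method="pic")


def _prune_to(tree: Phylogeny, taxa: list[str]) -> Phylogeny:
    keep = set(taxa)
    dt = tree.to_dendropy()
    dt.retain_taxa_with_labels(list(keep))
    return Phylogeny.from_dendropy(dt)
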