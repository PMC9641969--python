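"""Synthetic data with known ground truth.

Generates the three kinds of input the analysis consumes, with the
statistical structure the method assumes baked in and fully logged:

* **Correlated lineage rates** — per-branch rate scalars for the
  mitochondrial (mt) and nuclear mt-targeted (N-mt) gene sets drawn from a
  bivariate log-normal with tunable correlation ``rho``, plus independent
  scalars for background/control sets. This is the signal evolutionary
  rate covariation (ERC) is meant to detect.
* **Sequence evolution** — amino-acid sequences under a 20-state
  equal-exchangeability (Poisson) process, or codons under a GY-style
  omega/kappa process with uniform codon frequencies, with every
  substitution event logged to the branch it occurred on.
* **Compensatory contact pairs** — pairs of sites where one partner (the
  trigger) substitutes at the baseline rate and, once it has substituted
  on a lineage, the other partner's rate is multiplied by ``beta`` on
  descendant branches until it too substitutes. The true
  mt-first / N-mt-first ordering of every pair is recorded.

All randomness flows from one integer seed; each stage derives its own
sub-stream from (seed, stage-name) so stages can be re-run independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .core import (AMINO_ACIDS, Alignment, InvalidInputError, Phylogeny,
                   RateVector)

_N_AA = len(AMINO_ACIDS)

DNA = "TCAG"
_PURINES = frozenset("AG")


def _is_transition(a: str, b: str) -> bool:
    return a != b and ((a in _PURINES) == (b in _PURINES))


def substream(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage random stream derived from one master seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF,
                                  zlib.crc32(stage.encode())])


# ---------------------------------------------------------------------------
# Configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Knobs of the generative model.

    Defaults describe a mammal-like study design: 60 taxa, strong
    mt/N-mt rate coupling (rho = 0.9), per-branch log-rate scatter of
    sd = 0.5 (giving several-fold rate differences between the fastest
    and slowest lineages), purifying selection on both genomes
    (omega < 1, lower for mt), a transition/transversion ratio of 2,
    and mt-triggered compensation with a 20x rate boost.
    """

    n_taxa: int = 60
    tree_source: str = "yule"          # "yule" or a fixed Newick string
    seq_length: int = 500              # amino-acid sites, or codons
    rate_coupling_rho: float = 0.9
    scalar_sd: float = 0.5
    base_rate: float = 0.02            # expected subs/site per unit length
    omega_by_geneset: dict[str, float] = field(
        default_factory=lambda: {"mt": 0.1, "nmt": 0.2, "control": 0.2})
    kappa: float = 2.0
    compensation_boost_beta: float = 20.0
    compensation_direction: str = "mt_triggers_n"
    n_background_genes: int = 15       # genes averaged into a background set
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rate_coupling_rho <= 1.0:
            raise InvalidInputError("rate_coupling_rho must be in [-1, 1]")
        if self.scalar_sd < 0:
            raise InvalidInputError("scalar_sd must be >= 0")
        if self.base_rate < 0:
            raise InvalidInputError("base_rate must be >= 0")
        if self.kappa <= 0:
            raise InvalidInputError("kappa must be > 0")
        if self.compensation_boost_beta < 1:
            raise InvalidInputError("compensation_boost_beta must be >= 1")
        if self.compensation_direction not in (
                "mt_triggers_n", "n_triggers_mt", "none"):
            raise InvalidInputError(
                f"unknown compensation_direction {self.compensation_direction!r}")
        for name, omega in self.omega_by_geneset.items():
            if omega < 0:
                raise InvalidInputError(f"omega for {name!r} must be >= 0")


@dataclass
class TrueEvent:
    """One logged substitution: which branch, site, and state change."""

    gene_set: str
    site: int                 # 0-based column (amino) or codon index
    branch: int               # branch id = child-node id
    depth: int                # edges from root
    from_state: str
    to_state: str
    pair_id: int | None = None
    time: float = 0.0         # position within the branch, for ordering


@dataclass
class SyntheticTruth:
    """Ground truth for a simulation run, reproducible from the seed."""

    events: list[TrueEvent] = field(default_factory=list)
    root_sequences: dict[str, str] = field(default_factory=dict)
    branch_scalars: dict[int, tuple[float, float]] = field(default_factory=dict)
    pair_labels: dict[int, str] = field(default_factory=dict)

    def events_for(self, gene_set: str) -> list[TrueEvent]:
        return [e for e in self.events if e.gene_set == gene_set]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pair_id\tgene\tsite\tbranch_id\tdepth\tfrom\tto\n")
            for e in self.events:
                pid = "" if e.pair_id is None else str(e.pair_id)
                fh.write(f"{pid}\t{e.gene_set}\t{e.site}\t{e.branch}\t"
                         f"{e.depth}\t{e.from_state}\t{e.to_state}\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def generate_yule_tree(n_taxa: int, seed: int) -> Phylogeny:
    """Pure-birth tree with uniquely named tips ``t001``, ``t002``, ...

    Branch lengths are in units of the birth rate (1.0); the same seed
    always yields the same Newick string.
    """
    if n_taxa < 2:
        raise InvalidInputError("n_taxa must be >= 2")
    import random as _random

    from dendropy.simulate import treesim

    dtree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        rng=_random.Random(int(seed)))
    dtree.seed_node.edge.length = 0.0
    tree = Phylogeny.from_dendropy(dtree)
    # canonical deterministic tip labels, in preorder
    counter = 0
    width = max(3, len(str(n_taxa)))
    for node in tree.nodes:
        if node.is_tip:
            counter += 1
            node.name = f"t{counter:0{width}d}"
        else:
            node.name = None
    # The birth-death simulator stops at the n-th split, which can leave
    # zero-length pendant edges (always for n = 2). Extend every pendant
    # edge by the waiting time to the next (unrealized) birth event.
    ext_rng = substream(seed, "yule_pendant")
    extension = float(ext_rng.exponential(1.0 / n_taxa))
    for node in tree.nodes:
        if node.is_tip:
            node.length += extension
    return tree


def tree_from_config(config: SimulationConfig) -> Phylogeny:
    if config.tree_source == "yule":
        return generate_yule_tree(config.n_taxa, config.seed)
    return Phylogeny.from_newick(config.tree_source)


# ---------------------------------------------------------------------------
# Lineage rate scalars
# ---------------------------------------------------------------------------

def draw_branch_scalars(tree: Phylogeny, rho: float, sd: float,
                        seed: int) -> dict[int, tuple[float, float]]:
    """Per-branch (mt, N-mt) rate-scalar pairs.

    Log scalars are bivariate normal with mean 0, standard deviation
    ``sd`` per margin and correlation ``rho``; the returned scalars are
    their exponentials, so all are positive and a branch with scalar 1
    evolves at the baseline rate.
    """
    if not -1.0 <= rho <= 1.0:
        raise InvalidInputError("rho must be in [-1, 1]")
    if sd < 0:
        raise InvalidInputError("sd must be >= 0")
    rng = substream(seed, "branch_scalars")
    branches = tree.branch_ids
    z1 = rng.standard_normal(len(branches))
    z2 = rng.standard_normal(len(branches))
    log_mt = sd * z1
    log_nmt = sd * (rho * z1 + np.sqrt(max(1.0 - rho * rho, 0.0)) * z2)
    return {b: (float(np.exp(a)), float(np.exp(c)))
            for b, a, c in zip(branches, log_mt, log_nmt)}


def draw_background_scalars(tree: Phylogeny, sd: float, n_genes: int,
                            seed: int, stage: str = "background") -> dict[int, float]:
    """Per-branch scalar of a background gene set.

    A background set (e.g. one half of the random nuclear orthologs) is a
    concatenation of ``n_genes`` genes whose lineage effects are
    independent; its effective scalar is their average, so its branch-level
    noise shrinks by roughly ``sqrt(n_genes)`` relative to a single set.
    """
    if n_genes < 1:
        raise InvalidInputError("n_genes must be >= 1")
    rng = substream(seed, stage)
    branches = tree.branch_ids
    draws = np.exp(rng.normal(0.0, sd, size=(len(branches), n_genes)))
    means = draws.mean(axis=1)
    return {b: float(m) for b, m in zip(branches, means)}


def tip_rates(tree: Phylogeny, scalars: dict[int, float], gene_set: str,
              base_rate: float = 1.0) -> RateVector:
    """True per-tip root-to-tip expected substitutions per site.

    The rate on branch *b* is ``base_rate * scalars[b] * length(b)``; the
    tip value is the sum over its root path.
    """
    values = {}
    for t in tree.tip_ids:
        total = 0.0
        for b in tree.path_to_tip(t):
            total += base_rate * scalars[b] * tree.nodes[b].length
        values[tree.nodes[t].name] = total
    return RateVector(gene_set, values)


# ---------------------------------------------------------------------------
# Codon model machinery (shared with the dN/dS recovery tests)
# ---------------------------------------------------------------------------

def sense_codons(stop_codons: tuple[str, ...] = ("TAA", "TAG", "TGA")) -> list[str]:
    return [a + b + c for a in DNA for b in DNA for c in DNA
            if a + b + c not in stop_codons]


_CODON_TABLE: dict[str, str] = {}


def _standard_translation() -> dict[str, str]:
    global _CODON_TABLE
    if not _CODON_TABLE:
        from Bio.Data import CodonTable
        fwd = CodonTable.unambiguous_dna_by_id[1].forward_table
        _CODON_TABLE = dict(fwd)
    return _CODON_TABLE


class _CodonProcess:
    """GY-style codon CTMC: uniform frequencies, kappa, omega.

    Rates are normalized so one unit of branch length equals one expected
    codon substitution per site at omega = 1... more precisely the matrix
    is rescaled to unit mean substitution rate at stationarity for the
    given (omega, kappa), so branch lengths stay interpretable as expected
    substitutions per codon site.
    """

    def __init__(self, omega: float, kappa: float):
        codons = sense_codons()
        trans = _standard_translation()
        n = len(codons)
        rates = np.zeros((n, n))
        for i, ci in enumerate(codons):
            for j, cj in enumerate(codons):
                if i == j:
                    continue
                diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
                if len(diffs) != 1:
                    continue
                r = kappa if _is_transition(*diffs[0]) else 1.0
                if trans[ci] != trans[cj]:
                    r *= omega
                rates[i, j] = r
        leave = rates.sum(axis=1)
        mean_rate = leave.mean()  # uniform stationary frequencies
        if mean_rate > 0:
            rates /= mean_rate
            leave = leave / mean_rate
        self.codons = codons
        self.index = {c: k for k, c in enumerate(codons)}
        self.rates = rates
        self.leave = leave
        # conditional jump distributions
        with np.errstate(invalid="ignore", divide="ignore"):
            self.jump_cdf = np.cumsum(
                np.where(leave[:, None] > 0, rates / leave[:, None], 0.0),
                axis=1)
        self.translation = trans

    def gillespie(self, state: int, duration: float,
                  rng: np.random.Generator) -> list[tuple[float, int, int]]:
        """Jump chain over one branch: (time, from, to) triples."""
        out = []
        t = 0.0
        while True:
            rate = self.leave[state]
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= duration:
                break
            nxt = int(np.searchsorted(self.jump_cdf[state], rng.random()))
            out.append((t, state, nxt))
            state = nxt
        return out


_PROCESS_CACHE: dict[tuple[float, float], _CodonProcess] = {}


def codon_process(omega: float, kappa: float) -> _CodonProcess:
    key = (round(float(omega), 12), round(float(kappa), 12))
    if key not in _PROCESS_CACHE:
        _PROCESS_CACHE[key] = _CodonProcess(*key)
    return _PROCESS_CACHE[key]


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

def simulate_alignment(tree: Phylogeny, scalars: dict[int, float],
                       length: int, mode: str, config: SimulationConfig,
                       gene_set: str = "mt",
                       stage: str = "alignment") -> tuple[Alignment, SyntheticTruth]:
    """Evolve sequences down the tree, logging every substitution.

    ``mode="amino"`` uses the 20-state equal-exchangeability process at
    rate ``base_rate * scalars[b]`` per site; ``mode="codon"`` uses the
    omega/kappa codon process for ``config.omega_by_geneset[gene_set]``.
    """
    if length < 1:
        raise InvalidInputError("length must be >= 1")
    if mode not in ("amino", "codon"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    for b in tree.branch_ids:
        if b not in scalars:
            raise InvalidInputError(f"missing scalar for branch {b}")

    rng = substream(config.seed, f"{stage}:{gene_set}")
    truth = SyntheticTruth()

    if mode == "amino":
        aln = _simulate_amino(tree, scalars, length, config, gene_set, rng, truth)
    else:
        aln = _simulate_codon(tree, scalars, length, config, gene_set, rng, truth)
    return aln, truth


def _simulate_amino(tree, scalars, length, config, gene_set, rng, truth):
    root_seq = rng.integers(0, _N_AA, size=length)
    truth.root_sequences[gene_set] = "".join(AMINO_ACIDS[i] for i in root_seq)
    states = {0: root_seq}
    for node in tree.nodes[1:]:  # preorder, skipping root
        seq = states[node.parent].copy()
        t = node.length * scalars[node.id] * config.base_rate
        if t > 0:
            counts = rng.poisson(t, size=length)
            for site in np.nonzero(counts)[0]:
                for _ in range(int(counts[site])):
                    old = int(seq[site])
                    new = int(rng.integers(0, _N_AA - 1))
                    if new >= old:
                        new += 1
                    seq[site] = new
                    truth.events.append(TrueEvent(
                        gene_set=gene_set, site=int(site), branch=node.id,
                        depth=node.depth, from_state=AMINO_ACIDS[old],
                        to_state=AMINO_ACIDS[new]))
        states[node.id] = seq
    taxa, seqs = [], []
    for t_id in tree.tip_ids:
        taxa.append(tree.nodes[t_id].name)
        seqs.append("".join(AMINO_ACIDS[i] for i in states[t_id]))
    return Alignment(taxa, seqs, molecule="amino", gene_set=gene_set)


def _simulate_codon(tree, scalars, length, config, gene_set, rng, truth):
    omega = config.omega_by_geneset.get(gene_set, 0.2)
    proc = codon_process(omega, config.kappa)
    n_codons = len(proc.codons)
    root = rng.integers(0, n_codons, size=length)
    truth.root_sequences[gene_set] = "".join(proc.codons[i] for i in root)
    states = {0: root}
    for node in tree.nodes[1:]:
        seq = states[node.parent].copy()
        t = node.length * scalars[node.id] * config.base_rate
        if t > 0:
            for site in range(length):
                jumps = proc.gillespie(int(seq[site]), t, rng)
                for _, frm, to in jumps:
                    truth.events.append(TrueEvent(
                        gene_set=gene_set, site=site, branch=node.id,
                        depth=node.depth, from_state=proc.codons[frm],
                        to_state=proc.codons[to]))
                if jumps:
                    seq[site] = jumps[-1][2]
        states[node.id] = seq
    taxa, seqs = [], []
    for t_id in tree.tip_ids:
        taxa.append(tree.nodes[t_id].name)
        seqs.append("".join(proc.codons[i] for i in states[t_id]))
    return Alignment(taxa, seqs, molecule="codon", gene_set=gene_set)


def replay_events(tree: Phylogeny, root_sequence: str,
                  events: list[TrueEvent], tip: int | str,
                  amino: bool = True) -> str:
    """Reconstruct a tip sequence by applying logged events root->tip.

    Independent check that the event log fully accounts for the
    simulated sequences.
    """
    step = 1 if amino else 3
    seq = [root_sequence[i:i + step]
           for i in range(0, len(root_sequence), step)]
    path = tree.path_to_tip(tip)
    by_branch: dict[int, list[TrueEvent]] = {}
    for e in events:
        by_branch.setdefault(e.branch, []).append(e)
    for b in path:
        for e in sorted(by_branch.get(b, []), key=lambda e: (e.site, e.time)):
            seq[e.site] = e.to_state
    return "".join(seq)


# ---------------------------------------------------------------------------
# Compensatory contact pairs
# ---------------------------------------------------------------------------

def simulate_compensatory_pairs(
        tree: Phylogeny, n_pairs: int,
        config: SimulationConfig) -> tuple[Alignment, Alignment, SyntheticTruth]:
    """Simulate contact pairs with a known substitution-ordering truth.

    Each pair occupies one column of the mt alignment and one column of
    the N-mt alignment (column = pair index). The trigger site evolves at
    the baseline rate; once it has substituted on a lineage the partner's
    rate is multiplied by ``compensation_boost_beta`` on all descendant
    time until the partner itself substitutes. With ``beta = 1`` or
    direction ``"none"`` the two sites are independent.
    """
    if n_pairs < 1:
        raise InvalidInputError("n_pairs must be >= 1")
    direction = config.compensation_direction
    beta = config.compensation_boost_beta if direction != "none" else 1.0
    trigger_is_mt = direction != "n_triggers_mt"

    rng = substream(config.seed, "compensatory_pairs")
    truth = SyntheticTruth()
    rate = config.base_rate

    mt_root = rng.integers(0, _N_AA, size=n_pairs)
    nmt_root = rng.integers(0, _N_AA, size=n_pairs)
    truth.root_sequences["mt"] = "".join(AMINO_ACIDS[i] for i in mt_root)
    truth.root_sequences["nmt"] = "".join(AMINO_ACIDS[i] for i in nmt_root)

    mt_states = {0: mt_root.copy()}
    nmt_states = {0: nmt_root.copy()}
    # per pair, per lineage: (trigger has substituted, partner has
    # substituted after the trigger). The boost applies on branches that
    # start with the first flag set and the second unset.
    flags = {0: np.zeros((n_pairs, 2), dtype=bool)}

    for node in tree.nodes[1:]:
        mt_seq = mt_states[node.parent].copy()
        nmt_seq = nmt_states[node.parent].copy()
        flg = flags[node.parent].copy()
        duration = node.length * rate
        for p in range(n_pairs):
            trig_done, part_done = flg[p]
            boost_now = trig_done and not part_done and beta > 1
            t = 0.0
            while duration > 0:
                r_part = beta if boost_now else 1.0
                r_mt = 1.0 if trigger_is_mt else r_part
                r_nmt = r_part if trigger_is_mt else 1.0
                total = r_mt + r_nmt
                t += rng.exponential(1.0 / total)
                if t >= duration:
                    break
                hit_mt = rng.random() < r_mt / total
                seq = mt_seq if hit_mt else nmt_seq
                old = int(seq[p])
                new = int(rng.integers(0, _N_AA - 1))
                if new >= old:
                    new += 1
                seq[p] = new
                truth.events.append(TrueEvent(
                    gene_set="mt" if hit_mt else "nmt", site=p,
                    branch=node.id, depth=node.depth,
                    from_state=AMINO_ACIDS[old], to_state=AMINO_ACIDS[new],
                    pair_id=p, time=t))
                hit_trigger = hit_mt == trigger_is_mt
                if hit_trigger:
                    trig_done = True  # boost reaches descendants only
                elif trig_done:
                    part_done = True
                    boost_now = False
            flg[p] = (trig_done, part_done)
        mt_states[node.id] = mt_seq
        nmt_states[node.id] = nmt_seq
        flags[node.id] = flg

    taxa = [tree.nodes[t].name for t in tree.tip_ids]
    mt_aln = Alignment(
        taxa, ["".join(AMINO_ACIDS[i] for i in mt_states[t]) for t in tree.tip_ids],
        molecule="amino", gene_set="mt")
    nmt_aln = Alignment(
        taxa, ["".join(AMINO_ACIDS[i] for i in nmt_states[t]) for t in tree.tip_ids],
        molecule="amino", gene_set="nmt")

    truth.pair_labels = {
        p: _true_pair_label(tree, truth, p) for p in range(n_pairs)}
    return mt_aln, nmt_aln, truth


def _true_pair_label(tree: Phylogeny, truth: SyntheticTruth, pair: int) -> str:
    """Ordering label from the true event log.

    For every root-to-tip path containing at least one event at each
    partner site, compare the shallowest event per partner (ties within a
    branch broken by event time); aggregate over paths by majority vote.
    """
    mt_ev = [e for e in truth.events if e.pair_id == pair and e.gene_set == "mt"]
    nmt_ev = [e for e in truth.events if e.pair_id == pair and e.gene_set == "nmt"]
    votes = {"mt_first": 0, "nmt_first": 0, "same_branch": 0}
    for t in tree.tip_ids:
        path = set(tree.path_to_tip(t))
        mt_on = [e for e in mt_ev if e.branch in path]
        nmt_on = [e for e in nmt_ev if e.branch in path]
        if not mt_on or not nmt_on:
            continue
        m = min(mt_on, key=lambda e: (e.depth, e.time))
        n = min(nmt_on, key=lambda e: (e.depth, e.time))
        if m.depth < n.depth:
            votes["mt_first"] += 1
        elif n.depth < m.depth:
            votes["nmt_first"] += 1
        else:
            # equal depth on a shared path means the same branch
            votes["same_branch"] += 1
    if not any(votes.values()):
        return "unresolved"
    best = max(votes.values())
    winners = [k for k, v in votes.items() if v == best]
    return winners[0] if len(winners) == 1 else "unresolved"
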