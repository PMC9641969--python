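"""Substitution ordering at mitonuclear contact pairs.

Ancestral states are reconstructed on the fixed species tree (Fitch
parsimony with a deterministic tie-break by default, marginal ML under
the Poisson model as a sensitivity option), substitutions are assigned
to the branches where parent and child states differ, and each contact
pair is classified by which partner substituted on a shallower branch
along a shared root-to-tip path:

* ``mt_first`` / ``nmt_first`` — the shallowest events at the two
  partner sites on a shared path differ in depth; majority vote over all
  qualifying paths.
* ``same_branch`` — both shallowest events on one branch (tabulated
  separately, excluded from the ordering chi-square).
* ``unresolved`` — no path carries events at both sites, or the vote ties.

A classified pair is ``close`` when the two event branches are one or
two edges apart on the shared path (the deeper branch then necessarily
lies in the clade subtended by the shallower one), otherwise ``far``.
The nuclear-compensation prediction — mt substitutions precede N-mt —
is tested with a one-degree-of-freedom chi-square against equal counts,
and enrichment of mt-first ordering in restricted data (close pairs,
positively selected sites, functional nodal mutations) with Fisher's
exact test (conditional-MLE odds ratio, exact CI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

from .core import Alignment, InvalidInputError, Phylogeny, is_gap
from .contacts import ContactPair

logger = logging.getLogger("mitonuc.ordering")


@dataclass
class SubstitutionEvent:
    gene: str
    genome: str               # "mt" | "nuclear"
    column: int               # 0-based alignment column
    branch: int
    depth: int
    from_state: str
    to_state: str

    def __post_init__(self) -> None:
        if self.from_state == self.to_state:
            raise InvalidInputError("event with from == to")


@dataclass
class OrderingRecord:
    pair_id: int
    classification: str       # mt_first | nmt_first | same_branch | unresolved
    separation: int | None = None
    proximity: str | None = None      # close | far
    lineage_scope: str = "all"
    selection_flag: bool | None = None
    fnm_flag: bool | None = None
    n_paths: int = 0
    mt_branch: int | None = None
    nmt_branch: int | None = None


@dataclass
class OrderingTestResult:
    test: str
    n_mt_first: int
    n_nmt_first: int
    statistic: float | None
    df: int | None
    p_value: float
    odds_ratio: float | None = None
    or_ci: tuple[float, float] | None = None


# ---------------------------------------------------------------------------
# Ancestral reconstruction
# ---------------------------------------------------------------------------

def reconstruct_ancestral(alignment: Alignment, tree: Phylogeny,
                          method: str = "fitch"
                          ) -> dict[int, list[str | None]]:
    """Per-node, per-column ancestral states.

    Returns ``{node_id: [state_or_None, ...]}`` over alignment columns
    (codon alignments are reconstructed per codon). Gaps are missing
    data: a gapped tip gets no state and contributes no events.
    """
    if method not in ("fitch", "marginal_ml"):
        raise InvalidInputError(f"unknown method {method!r}")
    columns = _columns(alignment)
    tip_of = {}
    for t in tree.tip_ids:
        name = tree.nodes[t].name
        try:
            tip_of[t] = alignment.taxa.index(name)
        except ValueError:
            raise InvalidInputError(f"tree tip {name!r} absent from alignment")

    states: dict[int, list[str | None]] = {n.id: [] for n in tree.nodes}
    for col in columns:
        if method == "fitch":
            assign = _fitch_column(tree, tip_of, col)
        else:
            assign = _marginal_ml_column(tree, tip_of, col)
        for nid, s in assign.items():
            states[nid].append(s)
    return states


def _columns(alignment: Alignment) -> list[list[str]]:
    step = 3 if alignment.molecule == "codon" else 1
    n_cols = alignment.length // step
    return [[seq[i * step:(i + 1) * step] for seq in alignment.sequences]
            for i in range(n_cols)]


def _fitch_column(tree: Phylogeny, tip_of: dict[int, int],
                  col: list[str]) -> dict[int, str | None]:
    """Two-pass Fitch with a deterministic tie-break.

    Downward resolution keeps the parent's chosen state when it is in
    the node's optimal set, otherwise takes the lexicographically
    smallest member.
    """
    sets: dict[int, frozenset | None] = {}
    for nid in tree.postorder():
        node = tree.nodes[nid]
        if node.is_tip:
            s = col[tip_of[nid]]
            sets[nid] = None if is_gap(s) else frozenset([s])
            continue
        child_sets = [sets[c] for c in node.children if sets[c] is not None]
        if not child_sets:
            sets[nid] = None
        else:
            inter = frozenset.intersection(*child_sets)
            sets[nid] = inter if inter else frozenset.union(*child_sets)

    assign: dict[int, str | None] = {}
    for nid in tree.preorder():
        node = tree.nodes[nid]
        s = sets[nid]
        if s is None:
            assign[nid] = None
            continue
        parent_state = assign.get(node.parent) if node.parent >= 0 else None
        if parent_state is not None and parent_state in s:
            assign[nid] = parent_state
        else:
            assign[nid] = min(s)
    return assign


def fitch_parsimony_score(tree: Phylogeny, tip_states: dict[str, str]) -> int:
    """Minimum number of state changes for one column (union count)."""
    sets: dict[int, frozenset | None] = {}
    score = 0
    for nid in tree.postorder():
        node = tree.nodes[nid]
        if node.is_tip:
            s = tip_states.get(node.name)
            sets[nid] = None if s is None or is_gap(s) else frozenset([s])
            continue
        child_sets = [sets[c] for c in node.children if sets[c] is not None]
        if not child_sets:
            sets[nid] = None
        else:
            inter = frozenset.intersection(*child_sets)
            if inter:
                sets[nid] = inter
            else:
                sets[nid] = frozenset.union(*child_sets)
                score += 1
    return score


def _marginal_ml_column(tree: Phylogeny, tip_of: dict[int, int],
                        col: list[str]) -> dict[int, str | None]:
    """Marginal MAP states under the 20-state Poisson model."""
    alphabet = sorted({s for s in col if not is_gap(s)})
    if not alphabet:
        return {n.id: None for n in tree.nodes}
    n_states = max(len(alphabet), 2)
    # equal-rates transition probability over the observed alphabet size
    # (states never observed cannot be MAP, so restricting is safe)
    index = {s: i for i, s in enumerate(alphabet)}
    k = n_states

    def P(t: float) -> np.ndarray:
        mu = k / (k - 1)
        e = np.exp(-mu * max(t, 0.0))
        return e * np.eye(k) + (1 - e) / k * np.ones((k, k))

    up: dict[int, np.ndarray] = {}
    for nid in tree.postorder():
        node = tree.nodes[nid]
        if node.is_tip:
            s = col[tip_of[nid]]
            if is_gap(s):
                up[nid] = np.ones(k)
            else:
                v = np.zeros(k)
                v[index[s]] = 1.0
                up[nid] = v
            continue
        v = np.ones(k)
        for c in tree.nodes[nid].children:
            v = v * (P(tree.nodes[c].length) @ up[c])
        mx = v.max()
        up[nid] = v / mx if mx > 0 else v

    down: dict[int, np.ndarray] = {0: np.ones(k) / k}
    assign: dict[int, str | None] = {}
    for nid in tree.preorder():
        node = tree.nodes[nid]
        post = down[nid] * up[nid]
        total = post.sum()
        if total <= 0:
            assign[nid] = None
        else:
            # deterministic argmax: smallest index (alphabet is sorted)
            assign[nid] = alphabet[int(np.argmax(post))]
        for c in node.children:
            sib = np.ones(k)
            for c2 in node.children:
                if c2 != c:
                    sib = sib * (P(tree.nodes[c2].length) @ up[c2])
            msg = P(tree.nodes[c].length).T @ (down[nid] * sib)
            mx = msg.max()
            down[c] = msg / mx if mx > 0 else msg
    # tips with gaps stay missing
    for t in tree.tip_ids:
        if is_gap(col[tip_of[t]]):
            assign[t] = None
    return assign


# ---------------------------------------------------------------------------
# Substitution mapping
# ---------------------------------------------------------------------------

def map_substitutions(states: dict[int, list[str | None]], tree: Phylogeny,
                      gene: str, genome: str) -> list[SubstitutionEvent]:
    """One event per branch and column where parent and child states differ.

    Both states must be non-missing; branch depth is recorded for the
    ordering comparison.
    """
    events = []
    n_cols = len(states[0])
    for node in tree.nodes[1:]:
        parent_states = states[node.parent]
        child_states = states[node.id]
        for col in range(n_cols):
            a, b = parent_states[col], child_states[col]
            if a is not None and b is not None and a != b:
                events.append(SubstitutionEvent(
                    gene=gene, genome=genome, column=col, branch=node.id,
                    depth=node.depth, from_state=a, to_state=b))
    return events


# ---------------------------------------------------------------------------
# Pair classification
# ---------------------------------------------------------------------------

def classify_pair_order(mt_events: list[SubstitutionEvent],
                        nmt_events: list[SubstitutionEvent],
                        pair_id: int, tree: Phylogeny,
                        tip_subset: set[str] | None = None,
                        lineage_scope: str = "all") -> OrderingRecord:
    """Classify one contact pair from the events at its two sites.

    ``mt_events``/``nmt_events`` are the events at the pair's mt and
    N-mt columns. For every root-to-tip path carrying at least one event
    at each site, the shallowest event per side is compared by branch
    depth; paths vote and the majority wins (tie or no qualifying path:
    unresolved). ``tip_subset`` restricts to paths ending in the named
    tips (lineage-restricted analyses).
    """
    votes = {"mt_first": 0, "nmt_first": 0, "same_branch": 0}
    detail: dict[str, list[tuple[int, int, int]]] = {
        "mt_first": [], "nmt_first": [], "same_branch": []}
    for t in tree.tip_ids:
        if tip_subset is not None and tree.nodes[t].name not in tip_subset:
            continue
        path = tree.path_to_tip(t)
        on_path = set(path)
        mt_on = [e for e in mt_events if e.branch in on_path]
        nmt_on = [e for e in nmt_events if e.branch in on_path]
        if not mt_on or not nmt_on:
            continue
        m = min(mt_on, key=lambda e: e.depth)
        n = min(nmt_on, key=lambda e: e.depth)
        if m.depth == n.depth:
            cls = "same_branch"
            sep = 0
        else:
            cls = "mt_first" if m.depth < n.depth else "nmt_first"
            sep = abs(m.depth - n.depth)
        votes[cls] += 1
        detail[cls].append((sep, m.branch, n.branch))

    n_paths = sum(votes.values())
    if n_paths == 0:
        return OrderingRecord(pair_id, "unresolved",
                              lineage_scope=lineage_scope)
    best = max(votes.values())
    winners = [c for c, v in votes.items() if v == best]
    if len(winners) > 1:
        return OrderingRecord(pair_id, "unresolved",
                              lineage_scope=lineage_scope, n_paths=n_paths)
    cls = winners[0]
    sep, mt_b, nmt_b = min(detail[cls])
    record = OrderingRecord(pair_id, cls, separation=sep,
                            lineage_scope=lineage_scope, n_paths=n_paths,
                            mt_branch=mt_b, nmt_branch=nmt_b)
    if cls in ("mt_first", "nmt_first"):
        record.proximity = proximity(record)
    return record


def proximity(record: OrderingRecord) -> str:
    """``close`` iff the event branches are 1 or 2 edges apart.

    On a shared root-to-tip path the deeper branch always lies within
    the clade subtended by the shallower branch, so the monophyly
    condition is implied.
    """
    if record.classification not in ("mt_first", "nmt_first"):
        raise InvalidInputError(
            "proximity applies only to mt_first/nmt_first records")
    return "close" if record.separation in (1, 2) else "far"


def events_at_column(events: list[SubstitutionEvent],
                     column: int) -> list[SubstitutionEvent]:
    return [e for e in events if e.column == column]


def classify_contact_pairs(pairs: list[ContactPair],
                           mt_events: list[SubstitutionEvent],
                           nmt_events: list[SubstitutionEvent],
                           tree: Phylogeny,
                           tip_subset: set[str] | None = None,
                           lineage_scope: str = "all"
                           ) -> list[OrderingRecord]:
    """Classify every contact pair with mapped alignment columns.

    Contact-pair columns are 1-based; events carry 0-based columns.
    """
    mt_by_col: dict[tuple[str, int], list[SubstitutionEvent]] = {}
    for e in mt_events:
        mt_by_col.setdefault((e.gene, e.column), []).append(e)
    nmt_by_col: dict[tuple[str, int], list[SubstitutionEvent]] = {}
    for e in nmt_events:
        nmt_by_col.setdefault((e.gene, e.column), []).append(e)
    records = []
    for k, pair in enumerate(pairs):
        if pair.mt_column is None or pair.n_column is None:
            records.append(OrderingRecord(k, "unresolved",
                                          lineage_scope=lineage_scope))
            continue
        records.append(classify_pair_order(
            mt_by_col.get((pair.mt_gene, pair.mt_column - 1), []),
            nmt_by_col.get((pair.n_gene, pair.n_column - 1), []),
            k, tree, tip_subset, lineage_scope))
    return records


# ---------------------------------------------------------------------------
# Ordering statistics
# ---------------------------------------------------------------------------

def chisq_equal_order(n_mt_first: int, n_nmt_first: int) -> OrderingTestResult:
    """One-df goodness-of-fit of (mt-first, N-mt-first) counts vs 50:50."""
    if n_mt_first < 0 or n_nmt_first < 0:
        raise InvalidInputError("negative counts")
    if n_mt_first + n_nmt_first == 0:
        raise InvalidInputError("no classified pairs")
    stat, p = stats.chisquare([n_mt_first, n_nmt_first])
    return OrderingTestResult("chisq_equal_order", n_mt_first, n_nmt_first,
                              float(stat), 1, float(p))


def fisher_mtfirst_enrichment(table) -> OrderingTestResult:
    """Fisher's exact test on a 2x2 table of ordering counts.

    Rows: restricted vs broader dataset; columns: (mt_first, nmt_first).
    Reports the conditional-MLE odds ratio with its exact CI; with a
    zero margin the odds ratio is undefined and only the one-sided bound
    from the CI is meaningful.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise InvalidInputError("need a nonnegative 2x2 table")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    zero_margin = (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any()
    if zero_margin:
        return OrderingTestResult("fisher_exact", int(t[0, 0]), int(t[0, 1]),
                                  None, None, float(p), None, None)
    res = _odds_ratio(t, kind="conditional")
    ci = res.confidence_interval(0.95)
    return OrderingTestResult("fisher_exact", int(t[0, 0]), int(t[0, 1]),
                              None, None, float(p),
                              float(res.statistic),
                              (float(ci.low), float(ci.high)))


def branch_substitution_summary(events: list[SubstitutionEvent],
                                tree: Phylogeny) -> dict[int, dict]:
    """Per-branch mt and nuclear substitution counts.

    The ``majority`` flag says which genome substituted more on the
    branch (the orange/gray dichotomy of a per-branch substitution map).
    """
    out = {b: {"mt": 0, "nmt": 0} for b in tree.branch_ids}
    for e in events:
        key = "mt" if e.genome == "mt" else "nmt"
        out[e.branch][key] += 1
    for b, c in out.items():
        c["majority"] = ("mt" if c["mt"] > c["nmt"]
                         else "nmt" if c["nmt"] > c["mt"] else "tie")
    return out


def ordering_summary(records: list[OrderingRecord]) -> dict[str, int]:
    """Counts by classification over a set of records."""
    out = {"mt_first": 0, "nmt_first": 0, "same_branch": 0, "unresolved": 0}
    for r in records:
        out[r.classification] += 1
    return out


def records_to_tsv(records: list[OrderingRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("pair_id\tclassification\tseparation\tproximity\t"
                 "lineage_scope\tselection\tfnm\tn_paths\n")
        for r in records:
            fh.write(f"{r.pair_id}\t{r.classification}\t"
                     f"{'' if r.separation is None else r.separation}\t"
                     f"{r.proximity or ''}\t{r.lineage_scope}\t"
                     f"{'' if r.selection_flag is None else int(r.selection_flag)}\t"
                     f"{'' if r.fnm_flag is None else int(r.fnm_flag)}\t"
                     f"{r.n_paths}\n")
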