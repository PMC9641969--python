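from itertools import product

import numpy as np
import pytest
from scipy.stats import hypergeom

from mitonuc.core import Alignment, InvalidInputError, Phylogeny
from mitonuc.contacts import ContactPair
from mitonuc.ordering import (OrderingRecord, SubstitutionEvent,
                              branch_substitution_summary,
                              chisq_equal_order, classify_contact_pairs,
                              classify_pair_order,
                              fisher_mtfirst_enrichment,
                              fitch_parsimony_score, map_substitutions,
                              proximity, reconstruct_ancestral)
from mitonuc.simulate import (SimulationConfig, generate_yule_tree,
                              simulate_alignment)


# --- reconstruction ---------------------------------------------------------

class TestFitch:
    def test_invariant_column_no_events(self, quartet_tree):
        aln = Alignment(["A", "B", "C", "D"], ["K"] * 4)
        states = reconstruct_ancestral(aln, quartet_tree)
        assert all(v == ["K"] for v in states.values())

    def test_quartet_ambiguity_resolved_lexicographically(self, quartet_tree):
        # (K,K,R,R): root set {K,R} resolves to K; exactly one event
        aln = Alignment(["A", "B", "C", "D"], ["K", "K", "R", "R"])
        states = reconstruct_ancestral(aln, quartet_tree)
        assert states[0] == ["K"]
        events = map_substitutions(states, quartet_tree, "g", "mt")
        assert len(events) == 1
        assert (events[0].from_state, events[0].to_state) == ("K", "R")

    def test_gap_tip_gets_no_event(self, quartet_tree):
        aln = Alignment(["A", "B", "C", "D"], ["K", "K", "K", "-"])
        states = reconstruct_ancestral(aln, quartet_tree)
        events = map_substitutions(states, quartet_tree, "g", "mt")
        assert events == []
        assert states[quartet_tree.tip_id("D")] == [None]

    def test_all_gap_column_all_missing(self, quartet_tree):
        aln = Alignment(["A", "B", "C", "D"], ["-"] * 4)
        states = reconstruct_ancestral(aln, quartet_tree)
        assert all(v == [None] for v in states.values())

    @pytest.mark.parametrize("seed", range(4))
    def test_score_matches_exhaustive_search(self, seed):
        # Fitch attains the minimum over all internal labelings
        rng = np.random.default_rng(seed)
        tree = generate_yule_tree(6, seed)
        alphabet = ["A", "C", "D", "E"]
        tips = {n.name: alphabet[i] for n, i in
                zip((tree.nodes[t] for t in tree.tip_ids),
                    rng.integers(0, len(alphabet), 6))}
        score = fitch_parsimony_score(tree, tips)

        internal = [n.id for n in tree.nodes if not n.is_tip]
        best = None
        for labels in product(alphabet, repeat=len(internal)):
            assign = dict(zip(internal, labels))
            for t in tree.tip_ids:
                assign[t] = tips[tree.nodes[t].name]
            changes = sum(assign[n.id] != assign[n.parent]
                          for n in tree.nodes if n.parent >= 0)
            best = changes if best is None else min(best, changes)
        assert score == best

    def test_fitch_reconstruction_attains_its_score(self, quartet_tree):
        aln = Alignment(["A", "B", "C", "D"], ["K", "R", "K", "R"])
        states = reconstruct_ancestral(aln, quartet_tree)
        events = map_substitutions(states, quartet_tree, "g", "mt")
        tips = {t: aln.sequence_of(t) for t in aln.taxa}
        assert len(events) == fitch_parsimony_score(quartet_tree, tips)

    def test_marginal_ml_agrees_on_clear_signal(self, quartet_tree):
        aln = Alignment(["A", "B", "C", "D"], ["K", "K", "R", "R"])
        f = reconstruct_ancestral(aln, quartet_tree, "fitch")
        m = reconstruct_ancestral(aln, quartet_tree, "marginal_ml")
        for tid in quartet_tree.tip_ids:
            assert f[tid] == m[tid]
        # internal nodes adjacent to the (K,K) and (R,R) cherries agree
        for node in quartet_tree.nodes:
            if node.is_tip or node.id == 0:
                continue
            assert f[node.id] == m[node.id]


class TestMapSubstitutions:
    def test_recovery_against_truth(self):
        # sparse simulation: >= 90% of true events recovered on the
        # correct branch
        tree = generate_yule_tree(20, 3)
        cfg = SimulationConfig(n_taxa=20, base_rate=0.02, seed=3)
        aln, truth = simulate_alignment(
            tree, {b: 1.0 for b in tree.branch_ids}, 1000, "amino", cfg)
        states = reconstruct_ancestral(aln, tree)
        events = map_substitutions(states, tree, "g", "mt")
        true_keys = {(e.site, e.branch) for e in truth.events}
        reco_keys = {(e.column, e.branch) for e in events}
        assert len(true_keys & reco_keys) / len(true_keys) >= 0.9

    def test_totals_conserved_in_branch_summary(self, quartet_tree):
        aln = Alignment(["A", "B", "C", "D"], ["KR", "KK", "RK", "RK"])
        states = reconstruct_ancestral(aln, quartet_tree)
        events = map_substitutions(states, quartet_tree, "g", "mt")
        summary = branch_substitution_summary(events, quartet_tree)
        assert sum(c["mt"] for c in summary.values()) == len(events)


# --- pair classification ----------------------------------------------------

def _event(column, branch, depth, genome="mt", gene="g"):
    return SubstitutionEvent(gene=gene, genome=genome, column=column,
                             branch=branch, depth=depth, from_state="K",
                             to_state="R")


class TestClassifyPairOrder:
    def test_shallow_mt_deep_nmt_is_mt_first(self):
        # chain tree: depths 1..5 along one path
        tree = Phylogeny.from_newick(
            "(((((A:1,B:1):1,C:1):1,D:1):1,E:1):1,F:1);")
        path = tree.path_to_tip("A")
        mt = [_event(0, path[1], 2)]
        nmt = [_event(0, path[4], 5, genome="nuclear")]
        rec = classify_pair_order(mt, nmt, 0, tree)
        assert rec.classification == "mt_first"
        assert rec.separation == 3
        assert rec.proximity == "far"

    def test_same_branch(self, quartet_tree):
        b = quartet_tree.path_to_tip("A")[0]
        rec = classify_pair_order([_event(0, b, 1)],
                                  [_event(0, b, 1, genome="nuclear")],
                                  0, quartet_tree)
        assert rec.classification == "same_branch"

    def test_mutually_exclusive_clades_unresolved(self, quartet_tree):
        a = quartet_tree.tip_id("A")
        c = quartet_tree.tip_id("C")
        rec = classify_pair_order(
            [_event(0, a, quartet_tree.nodes[a].depth)],
            [_event(0, c, quartet_tree.nodes[c].depth, genome="nuclear")],
            0, quartet_tree)
        assert rec.classification == "unresolved"

    def test_majority_vote_across_paths(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        anc_ab = tree.path_to_tip("A")[0]     # depth-1 branch over (A,B)
        a = tree.tip_id("A")
        b = tree.tip_id("B")
        # mt event above the (A,B) cherry; nmt events on both tips:
        # both paths vote mt_first
        mt = [_event(0, anc_ab, 1)]
        nmt = [_event(0, a, 2, genome="nuclear"),
               _event(0, b, 2, genome="nuclear")]
        rec = classify_pair_order(mt, nmt, 0, tree)
        assert rec.classification == "mt_first"
        assert rec.n_paths == 2
        assert rec.separation == 1 and rec.proximity == "close"

    def test_tip_subset_restricts_paths(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        anc_ab = tree.path_to_tip("A")[0]
        a = tree.tip_id("A")
        mt = [_event(0, anc_ab, 1)]
        nmt = [_event(0, a, 2, genome="nuclear")]
        rec = classify_pair_order(mt, nmt, 0, tree, tip_subset={"C", "D"},
                                  lineage_scope="cd_only")
        assert rec.classification == "unresolved"
        assert rec.lineage_scope == "cd_only"


class TestProximity:
    @pytest.mark.parametrize("sep,expected", [(1, "close"), (2, "close"),
                                              (3, "far"), (5, "far")])
    def test_two_branches_or_fewer_is_close(self, sep, expected):
        rec = OrderingRecord(0, "mt_first", separation=sep)
        assert proximity(rec) == expected

    def test_same_branch_not_applicable(self):
        with pytest.raises(InvalidInputError):
            proximity(OrderingRecord(0, "same_branch", separation=0))


# --- statistics -------------------------------------------------------------

class TestChisq:
    def test_published_counts(self):
        res = chisq_equal_order(74, 323)
        assert res.statistic == pytest.approx(156.17, abs=0.005)
        assert res.p_value < 0.0001

    def test_balanced_counts(self):
        res = chisq_equal_order(50, 50)
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_goodness_of_fit_formula(self):
        # (10, 30): 2 * 10^2 / 20 = 10
        assert chisq_equal_order(10, 30).statistic == pytest.approx(10.0)

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            chisq_equal_order(0, 0)


def fisher_p_oracle(table):
    """Two-sided Fisher P by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    n1, n2, m = a + b, c + d, a + c
    rv = hypergeom(n1 + n2, n1, m)
    support = range(max(0, m - n2), min(m, n1) + 1)
    p_obs = rv.pmf(a)
    return sum(rv.pmf(k) for k in support if rv.pmf(k) <= p_obs * (1 + 1e-9))


class TestFisher:
    def test_no_association(self):
        res = fisher_mtfirst_enrichment([[5, 5], [5, 5]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_perfect_association_exact_p(self):
        # 2 / C(20, 10) = 2 / 184756
        res = fisher_mtfirst_enrichment([[10, 0], [0, 10]])
        assert res.p_value == pytest.approx(2 / 184756)

    @pytest.mark.parametrize("seed", range(20))
    def test_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        while True:
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum() <= 20 and t.sum(axis=0).all() and t.sum(axis=1).all():
                break
        res = fisher_mtfirst_enrichment(t.tolist())
        assert res.p_value == pytest.approx(fisher_p_oracle(t), rel=1e-8)

    def test_zero_margin_reports_no_odds_ratio(self):
        res = fisher_mtfirst_enrichment([[0, 5], [0, 7]])
        assert res.odds_ratio is None
        assert res.p_value == pytest.approx(1.0)


class TestBranchSummary:
    def test_no_events_all_zero(self, quartet_tree):
        summary = branch_substitution_summary([], quartet_tree)
        assert all(c["mt"] == 0 and c["nmt"] == 0 for c in summary.values())

    def test_majority_flag(self, quartet_tree):
        b = quartet_tree.branch_ids[0]
        events = [_event(i, b, 1) for i in range(3)] + \
                 [_event(9, b, 1, genome="nuclear")]
        summary = branch_substitution_summary(events, quartet_tree)
        assert summary[b]["majority"] == "mt"

    def test_faster_mt_dominates_branches(self):
        # mt at 5x the nuclear rate: mt majority on most branches
        tree = generate_yule_tree(15, 2)
        cfg = SimulationConfig(n_taxa=15, base_rate=0.1, seed=2)
        mt_aln, mt_truth = simulate_alignment(
            tree, {b: 1.0 for b in tree.branch_ids}, 300, "amino", cfg,
            gene_set="mt", stage="br_mt")
        cfg2 = SimulationConfig(n_taxa=15, base_rate=0.02, seed=2)
        n_aln, n_truth = simulate_alignment(
            tree, {b: 1.0 for b in tree.branch_ids}, 300, "amino", cfg2,
            gene_set="nmt", stage="br_n")
        events = ([SubstitutionEvent("mt", "mt", e.site, e.branch, e.depth,
                                     e.from_state, e.to_state)
                   for e in mt_truth.events]
                  + [SubstitutionEvent("nmt", "nuclear", e.site, e.branch,
                                       e.depth, e.from_state, e.to_state)
                     for e in n_truth.events])
        summary = branch_substitution_summary(events, tree)
        majorities = [c["majority"] for c in summary.values()]
        assert majorities.count("mt") > len(majorities) / 2


class TestClassifyContactPairs:
    def test_unmapped_columns_unresolved(self, quartet_tree):
        pairs = [ContactPair("m", "", 1, "n", "", 1, 4.0)]
        recs = classify_contact_pairs(pairs, [], [], quartet_tree)
        assert recs[0].classification == "unresolved"
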