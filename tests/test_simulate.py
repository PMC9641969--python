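import numpy as np
import pytest

from mitonuc.core import InvalidInputError
from mitonuc.simulate import (SimulationConfig, draw_background_scalars,
                              draw_branch_scalars, generate_yule_tree,
                              replay_events, simulate_alignment,
                              simulate_compensatory_pairs, tip_rates)

from conftest import star_tree


class TestYuleTree:
    def test_two_taxa_forced_topology(self):
        tree = generate_yule_tree(2, seed=1)
        assert len(tree.tip_ids) == 2
        assert sum(1 for n in tree.nodes if not n.is_tip) == 1

    def test_binary_tree_counting(self):
        tree = generate_yule_tree(60, seed=7)
        assert len(tree.tip_ids) == 60
        assert sum(1 for n in tree.nodes if not n.is_tip) == 59
        assert len(tree.branch_ids) == 118

    def test_deterministic_newick(self):
        assert (generate_yule_tree(25, seed=3).to_newick()
                == generate_yule_tree(25, seed=3).to_newick())

    def test_positive_branch_lengths(self):
        tree = generate_yule_tree(10, seed=5)
        assert all(tree.nodes[b].length > 0 for b in tree.branch_ids)

    def test_rejects_single_taxon(self):
        with pytest.raises(InvalidInputError):
            generate_yule_tree(1, seed=0)


class TestBranchScalars:
    def test_sd_zero_gives_unit_scalars(self):
        tree = generate_yule_tree(10, seed=0)
        scalars = draw_branch_scalars(tree, 0.5, 0.0, seed=1)
        assert all(v == (1.0, 1.0) for v in scalars.values())

    def test_perfect_correlation_equal_scalars(self):
        tree = generate_yule_tree(10, seed=0)
        scalars = draw_branch_scalars(tree, 1.0, 0.7, seed=2)
        for mt, nmt in scalars.values():
            assert mt == pytest.approx(nmt)

    def test_independent_scalars_near_zero_correlation(self):
        # 10,000 branches: empirical log-scalar correlation within +-0.05
        tree = star_tree(10000)
        scalars = draw_branch_scalars(tree, 0.0, 0.5, seed=5)
        logs = np.log(np.array(list(scalars.values())))
        r = np.corrcoef(logs[:, 0], logs[:, 1])[0, 1]
        assert abs(r) < 0.05

    def test_rejects_invalid_rho(self):
        tree = generate_yule_tree(4, seed=0)
        with pytest.raises(InvalidInputError):
            draw_branch_scalars(tree, 1.5, 0.5, seed=0)

    def test_background_averaging_shrinks_spread(self):
        tree = star_tree(2000)
        single = draw_background_scalars(tree, 0.5, 1, seed=1)
        avg = draw_background_scalars(tree, 0.5, 15, seed=1)
        assert (np.std(np.log(list(avg.values())))
                < 0.5 * np.std(np.log(list(single.values()))))


class TestSimulateAlignment:
    def test_zero_length_branches_no_change(self):
        tree = star_tree(5, length=0.0)
        cfg = SimulationConfig(n_taxa=5, seed=3)
        scalars = {b: 1.0 for b in tree.branch_ids}
        aln, truth = simulate_alignment(tree, scalars, 50, "amino", cfg)
        assert not truth.events
        assert all(s == truth.root_sequences["mt"] for s in aln.sequences)

    def test_poisson_event_count(self):
        # expected events = mu * L * S; observed within 3 sigma
        tree = star_tree(20, length=1.0)
        cfg = SimulationConfig(n_taxa=20, base_rate=0.1, seed=4)
        scalars = {b: 1.0 for b in tree.branch_ids}
        aln, truth = simulate_alignment(tree, scalars, 500, "amino", cfg)
        expected = 0.1 * 20 * 500
        assert abs(len(truth.events) - expected) <= 3 * np.sqrt(expected)

    def test_omega_zero_forbids_nonsynonymous(self):
        from mitonuc.dnds import _code
        tree = generate_yule_tree(8, seed=2)
        cfg = SimulationConfig(n_taxa=8, base_rate=0.2, kappa=2.0,
                               omega_by_geneset={"g": 0.0}, seed=2)
        scalars = {b: 1.0 for b in tree.branch_ids}
        _, truth = simulate_alignment(tree, scalars, 100, "codon", cfg,
                                      gene_set="g")
        fwd, _ = _code(1)
        assert truth.events  # synonymous changes still occur
        for e in truth.events:
            assert fwd[e.from_state] == fwd[e.to_state]

    def test_event_log_replays_to_tip_sequences(self):
        tree = generate_yule_tree(10, seed=6)
        cfg = SimulationConfig(n_taxa=10, base_rate=0.2, seed=6)
        scalars = {b: 1.0 for b in tree.branch_ids}
        aln, truth = simulate_alignment(tree, scalars, 80, "amino", cfg)
        for tid in tree.tip_ids:
            name = tree.nodes[tid].name
            assert replay_events(tree, truth.root_sequences["mt"],
                                 truth.events, tid) == aln.sequence_of(name)

    def test_pairwise_distance_calibration(self):
        # two tips separated by t: P(diff) = (19/20)(1 - e^{-20t/19})
        tree = star_tree(2, length=0.25)
        cfg = SimulationConfig(n_taxa=2, base_rate=1.0, seed=8)
        scalars = {b: 1.0 for b in tree.branch_ids}
        aln, _ = simulate_alignment(tree, scalars, 20000, "amino", cfg)
        diff = np.mean([a != b for a, b in zip(*aln.sequences)])
        t = 0.5
        expected = (19 / 20) * (1 - np.exp(-20 * t / 19))
        assert diff == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / 20000))

    def test_missing_scalar_is_configuration_error(self):
        tree = generate_yule_tree(4, seed=0)
        cfg = SimulationConfig(n_taxa=4, seed=0)
        with pytest.raises(InvalidInputError):
            simulate_alignment(tree, {}, 10, "amino", cfg)

    def test_determinism(self):
        tree = generate_yule_tree(6, seed=9)
        cfg = SimulationConfig(n_taxa=6, base_rate=0.1, seed=9)
        scalars = {b: 1.0 for b in tree.branch_ids}
        a1, t1 = simulate_alignment(tree, scalars, 60, "amino", cfg)
        a2, t2 = simulate_alignment(tree, scalars, 60, "amino", cfg)
        assert a1.sequences == a2.sequences
        assert len(t1.events) == len(t2.events)


class TestCompensatoryPairs:
    def test_rejects_zero_pairs(self):
        tree = generate_yule_tree(4, seed=0)
        with pytest.raises(InvalidInputError):
            simulate_compensatory_pairs(tree, 0, SimulationConfig(seed=0))

    def test_beta_one_is_symmetric(self):
        # independent processes: mt-first fraction ~ 0.5 among resolved
        # labels; pooled over 3 seeds x 1000 pairs at a divergence giving
        # many resolved pairs
        counts = {"mt_first": 0, "nmt_first": 0}
        for seed in range(3):
            tree = generate_yule_tree(30, seed)
            cfg = SimulationConfig(n_taxa=30, base_rate=0.1,
                                   compensation_boost_beta=1.0, seed=seed)
            _, _, truth = simulate_compensatory_pairs(tree, 1000, cfg)
            for lab in truth.pair_labels.values():
                if lab in counts:
                    counts[lab] += 1
        total = counts["mt_first"] + counts["nmt_first"]
        assert total > 500
        assert abs(counts["mt_first"] / total - 0.5) <= 0.05

    def test_strong_boost_gives_mt_first_truth(self):
        # deep tree, mt-triggered beta=50: >80% of resolved labels mt_first
        counts = {"mt_first": 0, "nmt_first": 0}
        for seed in range(3):
            tree = generate_yule_tree(30, seed)
            cfg = SimulationConfig(n_taxa=30, compensation_boost_beta=50.0,
                                   compensation_direction="mt_triggers_n",
                                   seed=seed)
            _, _, truth = simulate_compensatory_pairs(tree, 300, cfg)
            for lab in truth.pair_labels.values():
                if lab in counts:
                    counts[lab] += 1
        total = counts["mt_first"] + counts["nmt_first"]
        assert counts["mt_first"] / total > 0.8

    def test_truth_labels_consistent_with_event_depths(self):
        tree = generate_yule_tree(12, seed=4)
        cfg = SimulationConfig(n_taxa=12, base_rate=0.1,
                               compensation_boost_beta=20.0, seed=4)
        _, _, truth = simulate_compensatory_pairs(tree, 50, cfg)
        for pid, label in truth.pair_labels.items():
            if label != "mt_first":
                continue
            # some shared root-to-tip path must carry the mt event on a
            # strictly shallower branch than the N-mt event
            mt_ev = [e for e in truth.events
                     if e.pair_id == pid and e.gene_set == "mt"]
            nmt_ev = [e for e in truth.events
                      if e.pair_id == pid and e.gene_set == "nmt"]
            witnessed = False
            for t in tree.tip_ids:
                on_path = set(tree.path_to_tip(t))
                md = [e.depth for e in mt_ev if e.branch in on_path]
                nd = [e.depth for e in nmt_ev if e.branch in on_path]
                if md and nd and min(md) < min(nd):
                    witnessed = True
                    break
            assert witnessed

    def test_truth_tsv_roundtrip(self, tmp_path):
        tree = generate_yule_tree(6, seed=1)
        cfg = SimulationConfig(n_taxa=6, base_rate=0.1, seed=1)
        _, _, truth = simulate_compensatory_pairs(tree, 20, cfg)
        path = tmp_path / "truth.tsv"
        truth.to_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("pair_id\t")
        assert len(lines) == len(truth.events) + 1


class TestTipRates:
    def test_rates_are_weighted_path_sums(self):
        from mitonuc.core import Phylogeny
        tree = Phylogeny.from_newick("((A:1,B:1):1,C:2);")
        scalars = {b: 2.0 for b in tree.branch_ids}
        vec = tip_rates(tree, scalars, "g", base_rate=0.5)
        assert vec["A"] == pytest.approx(0.5 * 2.0 * 2.0)
        assert vec["C"] == pytest.approx(0.5 * 2.0 * 2.0)
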