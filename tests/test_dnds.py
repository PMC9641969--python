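import math
from itertools import permutations, product

import numpy as np
import pytest

from mitonuc.core import Alignment, InvalidInputError
from mitonuc.dnds import (STANDARD_CODE, VERTEBRATE_MITO_CODE, _code,
                          compare_groups, contact_fraction_trend,
                          count_diffs_ng86, count_sites_ng86, geneset_dnds,
                          pairwise_dnds_ng86)
from mitonuc.simulate import (SimulationConfig, generate_yule_tree,
                              simulate_alignment)

DNA = "TCAG"


# --- independent oracles ----------------------------------------------------

def oracle_sites(codon, table_id=STANDARD_CODE):
    """Direct enumeration of the 9 single-nucleotide neighbors."""
    fwd, stops = _code(table_id)
    syn = 0.0
    for pos in range(3):
        neighbors = [codon[:pos] + nt + codon[pos + 1:]
                     for nt in DNA if nt != codon[pos]]
        ok = [n for n in neighbors if n not in stops]
        if ok:
            syn += sum(fwd[n] == fwd[codon] for n in ok) / len(ok)
    return syn, 3.0 - syn


def oracle_diffs(ca, cb, table_id=STANDARD_CODE):
    """Exhaustive pathway enumeration between two codons."""
    fwd, stops = _code(table_id)
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in permutations(positions):
        cur, sd, nd, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in stops:
                ok = False
                break
            if fwd[nxt] == fwd[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            paths.append((sd, nd))
    if not paths:
        return None
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def all_sense_codons(table_id=STANDARD_CODE):
    fwd, _ = _code(table_id)
    return sorted(fwd)


class TestSiteCounts:
    def test_phenylalanine_one_third_synonymous(self):
        syn, nonsyn = count_sites_ng86("TTT")
        assert syn == pytest.approx(1 / 3)
        assert nonsyn == pytest.approx(8 / 3)

    def test_glycine_third_position_fully_synonymous(self):
        syn, nonsyn = count_sites_ng86("GGG")
        assert syn == pytest.approx(1.0) and nonsyn == pytest.approx(2.0)

    def test_stop_codon_rejected(self):
        with pytest.raises(InvalidInputError):
            count_sites_ng86("TGA")

    @pytest.mark.parametrize("table_id", [STANDARD_CODE,
                                          VERTEBRATE_MITO_CODE])
    def test_every_codon_matches_enumeration_oracle(self, table_id):
        for codon in all_sense_codons(table_id):
            assert count_sites_ng86(codon, table_id) == pytest.approx(
                oracle_sites(codon, table_id))

    def test_sites_sum_to_three(self):
        for codon in all_sense_codons():
            syn, nonsyn = count_sites_ng86(codon)
            assert syn + nonsyn == pytest.approx(3.0)


class TestPairwiseDiffs:
    def test_every_codon_pair_matches_pathway_oracle(self):
        codons = all_sense_codons()
        rng = np.random.default_rng(0)
        sample = rng.choice(len(codons), size=(400, 2))
        for i, j in sample:
            ca, cb = codons[i], codons[j]
            assert count_diffs_ng86(ca, cb) == oracle_diffs(ca, cb)

    def test_identical_sequences(self):
        res = pairwise_dnds_ng86("AAATTT", "AAATTT")
        assert res.syn_diffs == 0 and res.nonsyn_diffs == 0
        assert res.d_n == 0 and res.d_s == 0 and res.omega is None

    def test_hand_computed_example(self):
        # ten AAA codons, one synonymous change to AAG
        res = pairwise_dnds_ng86("AAA" * 10, "AAA" * 9 + "AAG")
        assert res.syn_diffs == pytest.approx(1.0)
        assert res.syn_sites == pytest.approx(10 / 3)
        assert res.d_s == pytest.approx(-0.75 * math.log(0.6))
        assert res.d_n == 0 and res.omega == 0

    def test_brute_force_on_short_random_sequences(self):
        # <= 5-codon inputs vs an oracle that recomputes everything
        codons = all_sense_codons()
        rng = np.random.default_rng(7)
        fwd, stops = _code(STANDARD_CODE)
        for _ in range(50):
            n = rng.integers(1, 6)
            sa = "".join(codons[i] for i in rng.integers(0, len(codons), n))
            sb = "".join(codons[i] for i in rng.integers(0, len(codons), n))
            res = pairwise_dnds_ng86(sa, sb)
            S = N = Sd = Nd = 0.0
            for k in range(n):
                ca, cb = sa[3 * k:3 * k + 3], sb[3 * k:3 * k + 3]
                d = oracle_diffs(ca, cb)
                if d is None:
                    continue
                Sd += d[0]
                Nd += d[1]
                oa, ob = oracle_sites(ca), oracle_sites(cb)
                S += (oa[0] + ob[0]) / 2
                N += (oa[1] + ob[1]) / 2
            assert res.syn_sites == pytest.approx(S)
            assert res.nonsyn_sites == pytest.approx(N)
            assert res.syn_diffs == pytest.approx(Sd)
            assert res.nonsyn_diffs == pytest.approx(Nd)

    def test_gapped_codons_skipped(self):
        res = pairwise_dnds_ng86("AAA---TTT", "AAAGGGTTT")
        # middle codon skipped; AAA and TTT each contribute 1/3 syn sites
        assert res.syn_sites == pytest.approx(2 / 3)

    def test_saturated_pair_flagged(self):
        # maximally different codons at every position saturate p_n
        res = pairwise_dnds_ng86("AAA" * 4, "GGC" * 4)
        assert res.saturated and res.omega is None


class TestGenesetDnds:
    def test_two_taxa_equals_pairwise(self):
        aln = Alignment(["A", "B"], ["AAA" * 10, "AAA" * 9 + "AAG"],
                        molecule="codon", gene_set="g")
        gene = geneset_dnds(aln)
        pair = pairwise_dnds_ng86(aln.sequences[0], aln.sequences[1])
        assert gene.d_s == pytest.approx(pair.d_s)
        assert gene.d_n == pytest.approx(pair.d_n)

    def test_invariant_to_taxon_order(self):
        rng = np.random.default_rng(1)
        codons = all_sense_codons()
        seqs = ["".join(codons[i] for i in rng.integers(0, 61, 20))
                for _ in range(4)]
        a1 = Alignment(list("ABCD"), seqs, molecule="codon")
        a2 = Alignment(list("DCBA"), seqs[::-1], molecule="codon")
        r1, r2 = geneset_dnds(a1), geneset_dnds(a2)
        assert r1.d_n == pytest.approx(r2.d_n)
        assert r1.d_s == pytest.approx(r2.d_s)

    def test_recovers_simulated_omega(self):
        # omega = 0.2, kappa = 1 (the no-ts/tv-bias regime NG86 assumes):
        # recovered within +-0.1 at 1,000 codons, 20 taxa
        cfg = SimulationConfig(n_taxa=20, base_rate=0.05, kappa=1.0,
                               omega_by_geneset={"g": 0.2}, seed=1)
        tree = generate_yule_tree(20, 1)
        aln, _ = simulate_alignment(tree, {b: 1.0 for b in tree.branch_ids},
                                    1000, "codon", cfg, gene_set="g")
        assert geneset_dnds(aln).omega == pytest.approx(0.2, abs=0.1)

    def test_neutral_omega_calibration(self):
        cfg = SimulationConfig(n_taxa=20, base_rate=0.05, kappa=1.0,
                               omega_by_geneset={"g": 1.0}, seed=5)
        tree = generate_yule_tree(20, 5)
        aln, _ = simulate_alignment(tree, {b: 1.0 for b in tree.branch_ids},
                                    1000, "codon", cfg, gene_set="g")
        assert geneset_dnds(aln).omega == pytest.approx(1.0, abs=0.15)


class TestBranchwiseMode:
    def test_invariant_alignment_zero_differences(self):
        from mitonuc.core import Phylogeny
        from mitonuc.dnds import branchwise_dnds
        from mitonuc.ordering import reconstruct_ancestral
        tree = Phylogeny.from_newick("((A:0.1,B:0.1):0.1,C:0.1);")
        aln = Alignment(["A", "B", "C"], ["AAATTT"] * 3, molecule="codon")
        states = reconstruct_ancestral(aln, tree)
        res = branchwise_dnds(states, tree)
        assert res.syn_diffs == 0 and res.nonsyn_diffs == 0

    def test_recovers_purifying_regime(self):
        from mitonuc.dnds import branchwise_dnds
        from mitonuc.ordering import reconstruct_ancestral
        tree = generate_yule_tree(12, 3)
        cfg = SimulationConfig(n_taxa=12, base_rate=0.05, kappa=1.0,
                               omega_by_geneset={"g": 0.3}, seed=3)
        aln, _ = simulate_alignment(
            tree, {b: 1.0 for b in tree.branch_ids}, 500, "codon", cfg,
            gene_set="g")
        states = reconstruct_ancestral(aln, tree)
        omega = branchwise_dnds(states, tree).omega
        # approximate mode (parsimony undercounts multiple hits): the
        # purifying regime is recovered, not the exact value
        assert 0.1 < omega < 0.5


class TestGroupComparisons:
    def test_identical_groups_all_p_one(self):
        omegas = {f"g{i}": 0.2 for i in range(9)}
        groups = {f"g{i}": f"set{i % 3}" for i in range(9)}
        comps = compare_groups(omegas, groups)
        assert len(comps) == 3
        assert all(c.mean_difference == 0 and c.p_adjusted == 1
                   for c in comps)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        omegas = {}
        groups = {}
        for i in range(6):
            omegas[f"a{i}"] = 0.1 + rng.normal(0, 1e-4)
            omegas[f"b{i}"] = 0.5 + rng.normal(0, 1e-4)
            groups[f"a{i}"] = "low"
            groups[f"b{i}"] = "high"
        comps = compare_groups(omegas, groups)
        assert len(comps) == 1
        assert abs(comps[0].mean_difference) == pytest.approx(0.4, abs=1e-3)
        assert comps[0].p_adjusted < 1e-6

    def test_three_groups_three_comparisons(self):
        rng = np.random.default_rng(2)
        omegas = {f"g{i}": float(rng.random()) for i in range(12)}
        groups = {f"g{i}": f"s{i % 3}" for i in range(12)}
        assert len(compare_groups(omegas, groups)) == 3

    def test_small_group_excluded(self):
        omegas = {"a1": 0.1, "a2": 0.2, "b1": 0.3, "b2": 0.4, "c1": 0.9}
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"}
        comps = compare_groups(omegas, groups)
        assert {c.group_a for c in comps} | {c.group_b for c in comps} \
            == {"A", "B"}


class TestContactFractionTrend:
    def test_perfectly_linear(self):
        omegas = {f"g{i}": 0.05 + 0.1 * (i / 10) for i in range(10)}
        fracs = {f"g{i}": i / 10 for i in range(10)}
        slope, r, p = contact_fraction_trend(omegas, fracs)
        assert slope == pytest.approx(0.1)
        assert r == pytest.approx(1.0)

    def test_constant_predictor_rejected(self):
        with pytest.raises(InvalidInputError):
            contact_fraction_trend({"a": 0.1, "b": 0.2, "c": 0.3},
                                   {"a": 0.5, "b": 0.5, "c": 0.5})

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.random(40)
        y = 0.1 * x + rng.normal(0, 0.02, 40)
        omegas = {f"g{i}": float(y[i]) for i in range(40)}
        fracs = {f"g{i}": float(x[i]) for i in range(40)}
        slope, r, _ = contact_fraction_trend(omegas, fracs)
        xc, yc = x - x.mean(), y - y.mean()
        assert slope == pytest.approx(float(xc @ yc / (xc @ xc)))
        assert r == pytest.approx(
            float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc))))
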