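"""Branch-model likelihoods, LRTs, and the meta-analytic statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from duplicability import branchlik as bl
from duplicability import codonrates as cr
from duplicability import genetics, syntree
from duplicability.branchlik import CodonModelParams
from duplicability.treeclass import GeneFamilyTree

from conftest import simulate_pair


class TestCodonLoglik:
    def test_matches_pairwise_likelihood_on_two_leaves(self, codonish_pi):
        """Cross-module oracle: pruning on a 2-leaf tree equals the
        independent pairwise formula at the same (t, kappa, omega)."""
        aln = simulate_pair("(macaque|m:0.07,gibbon|g:0.07);", 400, 3.0, 0.4,
                            codonish_pi, seed=21)
        tree = GeneFamilyTree.from_newick("(macaque|m:0.1,gibbon|g:0.04);")
        params = CodonModelParams(kappa=2.5, omega_by_class={"bg": 0.35},
                                  branch_lengths={}, codon_freqs=codonish_pi)
        l_tree = bl.codon_loglik(tree, aln, params)
        l_pair = cr.pairwise_loglik(aln, 0.14, 2.5, 0.35, pi=codonish_pi)
        assert abs(l_tree - l_pair) < 1e-8

    def test_reroot_invariance(self, small_dataset):
        fam = small_dataset.families[0]
        aln = small_dataset.alignments[fam.family_id]
        pi = genetics.f3x4_frequencies(list(aln.sequences.values()))
        params = CodonModelParams(kappa=3.0, omega_by_class={"bg": 0.5},
                                  branch_lengths={}, codon_freqs=pi)
        base = bl.codon_loglik(fam, aln, params)
        clone = fam.clone()
        node = clone.tree.find_node_with_taxon_label(clone.genes_of("gorilla")[0])
        L = node.edge.length
        clone.tree.reroot_at_edge(node.edge, length1=L / 2, length2=L / 2,
                                  update_bipartitions=False)
        assert abs(bl.codon_loglik(clone, aln, params) - base) < 1e-8

    def test_zero_branch_lengths_identical_sequences(self, codonish_pi):
        """Analytic limit: all t = 0 with identical leaves gives
        logL = sum over sites of log pi(codon)."""
        seq = "".join(genetics.SENSE_CODONS[i] for i in
                      np.random.default_rng(0).integers(0, 61, 50))
        aln = cr.CodonAlignment({("macaque", "m"): seq, ("gibbon", "g"): seq,
                                 ("human", "h"): seq})
        tree = GeneFamilyTree.from_newick(
            "((macaque|m:0.0,gibbon|g:0.0):0.0,human|h:0.0);")
        params = CodonModelParams(kappa=2.0, omega_by_class={"bg": 0.3},
                                  branch_lengths={}, codon_freqs=codonish_pi)
        expected = sum(math.log(codonish_pi[genetics.CODON_INDEX[c]])
                       for c in genetics.codons_of(seq))
        assert abs(bl.codon_loglik(tree, aln, params) - expected) < 1e-8


class TestFitModel:
    def test_single_omega_recovery(self, cal_tree, codonish_pi):
        rng = np.random.default_rng(77)
        aln = syntree.evolve_alignment(cal_tree, 2000, 3.0, 0.25,
                                       codonish_pi, rng)
        params, lnl = bl.fit_model(cal_tree, aln)
        assert abs(params.omega_by_class["bg"] - 0.25) < 0.07
        assert abs(params.kappa - 3.0) < 1.0

    def test_foreground_background_ordering_recovered(self, cal_tree, codonish_pi):
        """omega 0.8 on the paralog clade vs 0.2 background."""
        clade = frozenset({"chimp|c1", "chimp|c2"})
        fg = {clade: 0.8, frozenset({"chimp|c1"}): 0.8, frozenset({"chimp|c2"}): 0.8}
        hits = 0
        for rep in range(6):
            rng = np.random.default_rng(800 + rep)
            aln = syntree.evolve_alignment(cal_tree, 2000, 3.0, 0.2,
                                           codonish_pi, rng, omega_overrides=fg)
            classes = {k: "dup" for k in fg}
            params, _ = bl.fit_model(cal_tree, aln, branch_classes=classes)
            if params.omega_by_class["dup"] > params.omega_by_class["bg"]:
                hits += 1
        assert hits >= 5

    def test_nesting_contract(self, cal_tree, codonish_pi):
        rng = np.random.default_rng(5)
        aln = syntree.evolve_alignment(cal_tree, 500, 3.0, 0.3, codonish_pi, rng)
        _, lnl_null = bl.fit_model(cal_tree, aln)
        res = bl.acceleration_test(cal_tree, aln, "chimp")
        assert res.lnL_alt >= res.lnL_null - 1e-6
        assert res.lnL_null >= lnl_null - 1e-6


class TestDuplicationLRTs:
    def test_two_paralogs_df(self, cal_tree, codonish_pi):
        rng = np.random.default_rng(31)
        aln = syntree.evolve_alignment(cal_tree, 400, 3.0, 0.3, codonish_pi, rng)
        res = bl.asymmetry_test(cal_tree, aln, "chimp")
        assert res.df == 1
        assert res.statistic >= 0
        res2 = bl.acceleration_test(cal_tree, aln, "chimp")
        assert res2.df == 1

    def test_asymmetry_detected_when_strong(self, cal_tree, codonish_pi):
        """One paralog at omega 1.0, the other at 0.1."""
        overrides = {frozenset({"chimp|c1"}): 1.0,
                     frozenset({"chimp|c2"}): 0.1}
        hits = 0
        for rep in range(6):
            rng = np.random.default_rng(1200 + rep)
            aln = syntree.evolve_alignment(cal_tree, 1500, 3.0, 0.3,
                                           codonish_pi, rng,
                                           omega_overrides=overrides)
            res = bl.asymmetry_test(cal_tree, aln, "chimp")
            hits += res.p_raw < 0.05
        assert hits >= 5

    def test_acceleration_direction_recovered(self, cal_tree, codonish_pi):
        """Post-duplication omega doubled: median fitted ratio above 1."""
        overrides = {frozenset({"chimp|c1", "chimp|c2"}): 0.6,
                     frozenset({"chimp|c1"}): 0.6,
                     frozenset({"chimp|c2"}): 0.6}
        ratios = []
        for rep in range(6):
            rng = np.random.default_rng(2400 + rep)
            aln = syntree.evolve_alignment(cal_tree, 1500, 3.0, 0.3,
                                           codonish_pi, rng,
                                           omega_overrides=overrides)
            res = bl.acceleration_test(cal_tree, aln, "chimp")
            ratios.append(res.omega_alt["dup"] / res.omega_alt["bg"])
        assert np.median(ratios) > 1

    def test_requires_two_paralogs(self, singleton_tree, small_dataset):
        fam = small_dataset.families[0]
        aln = small_dataset.alignments[fam.family_id]
        with pytest.raises(ValueError):
            bl.asymmetry_test(singleton_tree, aln, "chimp")


class TestMetaStatistics:
    def test_bh_fdr_hand_example(self):
        """[0.01, 0.02, 0.03, 0.04] -> all 0.04 by the step-up definition:
        adjusted_i = min over j>=i of p_j * n / j, and 0.04*4/4 = 0.04
        dominates every earlier term."""
        out = bl.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, 0.04)

    def test_bh_fdr_trivial_cases(self):
        assert bl.bh_fdr([0.2]) == pytest.approx([0.2])
        assert np.allclose(bl.bh_fdr([0.3, 0.3, 0.3]), 0.3)
        with pytest.raises(ValueError):
            bl.bh_fdr([1.2])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_bh_fdr_dominates_raw_and_is_capped(self, pvals):
        adj = bl.bh_fdr(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0)

    def test_fisher_combine(self):
        stat, df, p = bl.fisher_combine([1.0, 1.0, 1.0])
        assert stat == 0.0 and df == 6 and p == 1.0
        stat, df, p = bl.fisher_combine([0.05])
        assert df == 2 and np.isclose(p, 0.05) and np.isclose(stat, 5.99, atol=0.01)
        stat, df, p = bl.fisher_combine([0.1, 0.2])
        assert np.isclose(stat, 7.824, atol=5e-4) and df == 4
        assert np.isclose(p, 0.098, atol=5e-4)
        with pytest.raises(ValueError):
            bl.fisher_combine([0.0, 0.5])

    def test_fisher_df_always_even(self):
        for k in (1, 5, 26, 52):
            _, df, _ = bl.fisher_combine(np.full(k, 0.5))
            assert df == 2 * k

    def test_chi2_upper_tail_printed_values(self):
        # the two reference meta-analytic tail probabilities
        assert round(bl.chi2_upper_tail(82.9, 104), 2) == 0.94
        assert round(bl.chi2_upper_tail(63.37, 50), 3) == 0.097
        assert bl.chi2_upper_tail(0.0, 2) == 1.0

    def test_chi2_upper_tail_monotone(self):
        stats = np.linspace(0, 30, 40)
        p = [bl.chi2_upper_tail(s, 4) for s in stats]
        assert np.all(np.diff(p) < 0)

    def test_binomial_two_sided(self):
        assert round(bl.binomial_two_sided(25, 39), 2) == 0.11
        assert bl.binomial_two_sided(10, 20) == 1.0
        assert np.isclose(bl.binomial_two_sided(39, 39), 2 * 0.5 ** 39)
        with pytest.raises(ValueError):
            bl.binomial_two_sided(5, 0)
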