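"""Pruning likelihoods, ancestral posteriors and ML fits against
independent brute-force oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from _oracles import (
    enum_branch_joint,
    enum_marginal_posterior,
    enum_site_likelihood,
    expm_pmats,
)
from conftest import AAS, random_protein_records, simulate_protein_on_tree
from convsel.io import SequenceRecord
from convsel.likelihood import (
    branch_joint_posterior,
    branch_pmats,
    encode_codon_alignment,
    encode_protein_alignment,
    fit_branch_lengths,
    fit_m0,
    log_likelihood,
    marginal_ancestral_posteriors,
    pattern_logliks,
)
from convsel.substmodels import CodonModel, f3x4_frequencies
from convsel.trees import parse_newick


def _tips(align, taxa):
    return {t: align.partials[align.taxon_row(t)] for t in taxa}


class TestPruningLikelihood:
    def test_two_taxon_closed_form(self, dayhoff):
        tree = parse_newick("(A:0.2,B:0.4);")
        al = encode_protein_alignment(
            [SequenceRecord("A", "L"), SequenceRecord("B", "V")]
        )
        lnl, per_site = log_likelihood(al, tree, dayhoff)
        i, j = AAS.index("L"), AAS.index("V")
        p1 = dayhoff.transition_matrix(0.2)
        p2 = dayhoff.transition_matrix(0.4)
        expected = np.log(np.sum(dayhoff.freqs * p1[:, i] * p2[:, j]))
        assert lnl == pytest.approx(expected, abs=1e-12)

    def test_all_gap_column_contributes_zero(self, dayhoff, five_taxon_tree):
        al = encode_protein_alignment(
            [SequenceRecord(t, "L-") for t in "ABCDE"]
        )
        _, per_site = log_likelihood(al, five_taxon_tree, dayhoff)
        assert per_site[1] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_taxon_named_in_error(self, dayhoff, five_taxon_tree):
        al = encode_protein_alignment([SequenceRecord("ZZ", "LLL")])
        with pytest.raises(KeyError, match="ZZ"):
            log_likelihood(al, five_taxon_tree, dayhoff)

    @pytest.mark.parametrize("seed", range(4))
    def test_aa_pruning_matches_enumeration(self, dayhoff, rng, seed, five_taxon_tree):
        rng = np.random.default_rng(seed)
        recs, _ = simulate_protein_on_tree(five_taxon_tree, dayhoff, 12, rng)
        al = encode_protein_alignment(recs)
        pm = branch_pmats(five_taxon_tree, dayhoff.eig)
        lnl = pattern_logliks(al, five_taxon_tree, pm, dayhoff.freqs)
        lnl = lnl[al.pattern_of_site]
        pm_o = expm_pmats(five_taxon_tree, dayhoff.q)
        tips = _tips(al, "ABCDE")
        for s in range(al.n_sites):
            tp = {t: tips[t][al.pattern_of_site[s]] for t in "ABCDE"}
            oracle = np.log(
                enum_site_likelihood(five_taxon_tree, tp, pm_o, dayhoff.freqs)
            )
            assert lnl[s] == pytest.approx(oracle, rel=1e-10)

    def test_codon_pruning_matches_enumeration(self, rng):
        tree = parse_newick("((A:0.2,B:0.1):0.15,(C:0.3,D:0.12):0.08);")
        freqs = np.full(61, 1 / 61)
        model = CodonModel(kappa=2.5, omega=0.4, codon_freqs=freqs)
        codons = ["ATG", "CTG", "CTA", "ATA"]
        recs = [
            SequenceRecord(t, "".join(rng.choice(codons, 5)))
            for t in "ABCD"
        ]
        al = encode_codon_alignment(recs)
        pm = branch_pmats(tree, model.eig)
        lnl = pattern_logliks(al, tree, pm, freqs)[al.pattern_of_site]
        pm_o = expm_pmats(tree, model.q)
        tips = _tips(al, "ABCD")
        for s in range(al.n_sites):
            tp = {t: tips[t][al.pattern_of_site[s]] for t in "ABCD"}
            oracle = np.log(enum_site_likelihood(tree, tp, pm_o, freqs))
            assert lnl[s] == pytest.approx(oracle, rel=1e-10)

    def test_rerooting_invariance(self, dayhoff, rng):
        """A reversible model gives the same likelihood however rooted."""
        t1 = parse_newick("(((A:0.1,B:0.2):0.1,C:0.3):0.15,D:0.25);")
        # same unrooted tree, rooted along the C branch instead
        t2 = parse_newick("(C:0.15,((A:0.1,B:0.2):0.1,D:0.4):0.15);")
        recs = random_protein_records("ABCD", 10, rng)
        al = encode_protein_alignment(recs)
        l1, _ = log_likelihood(al, t1, dayhoff)
        l2, _ = log_likelihood(al, t2, dayhoff)
        assert l1 == pytest.approx(l2, abs=1e-8)


class TestAncestralPosteriors:
    def test_invariant_site_root_confident(self, dayhoff):
        tree = parse_newick("((A:0.05,B:0.08):0.05,(C:0.06,D:0.04):0.07);")
        al = encode_protein_alignment([SequenceRecord(t, "L") for t in "ABCD"])
        pm = branch_pmats(tree, dayhoff.eig)
        post = marginal_ancestral_posteriors(al, tree, pm, dayhoff.freqs)
        assert post[tree.root][0, AAS.index("L")] > 0.99

    def test_short_branches_collapse_to_tip_state(self, dayhoff):
        tree = parse_newick("((A:1e-7,B:1e-7):1e-7,(C:1e-7,D:1e-7):1e-7);")
        al = encode_protein_alignment([SequenceRecord(t, "H") for t in "ABCD"])
        pm = branch_pmats(tree, dayhoff.eig)
        post = marginal_ancestral_posteriors(al, tree, pm, dayhoff.freqs)
        for node in range(len(tree.nodes)):
            assert post[node][0, AAS.index("H")] > 0.999

    @pytest.mark.parametrize("seed", range(3))
    def test_marginals_match_enumeration(self, dayhoff, seed, five_taxon_tree):
        rng = np.random.default_rng(100 + seed)
        recs, _ = simulate_protein_on_tree(five_taxon_tree, dayhoff, 8, rng)
        al = encode_protein_alignment(recs)
        pm = branch_pmats(five_taxon_tree, dayhoff.eig)
        post = marginal_ancestral_posteriors(al, five_taxon_tree, pm, dayhoff.freqs)
        pm_o = expm_pmats(five_taxon_tree, dayhoff.q)
        tips = _tips(al, "ABCDE")
        internals = [i for i in range(len(five_taxon_tree.nodes))
                     if five_taxon_tree.nodes[i].children]
        for node in internals:
            for s in range(al.n_sites):
                tp = {t: tips[t][al.pattern_of_site[s]] for t in "ABCDE"}
                oracle = enum_marginal_posterior(
                    five_taxon_tree, tp, pm_o, dayhoff.freqs, node
                )
                assert np.allclose(post[node][s], oracle, atol=1e-10)
        # normalisation
        for node, arr in post.items():
            assert np.allclose(arr.sum(axis=1), 1.0, atol=1e-9)


class TestBranchJointPosteriors:
    def test_tip_branch_constrained_to_observed_state(self, dayhoff, five_taxon_tree, rng):
        recs, _ = simulate_protein_on_tree(five_taxon_tree, dayhoff, 6, rng)
        recs[0] = SequenceRecord("A", "V" * 6)
        al = encode_protein_alignment(recs)
        pm = branch_pmats(five_taxon_tree, dayhoff.eig)
        tip_a = five_taxon_tree.tip_index()["A"]
        j = branch_joint_posterior(al, five_taxon_tree, pm, dayhoff.freqs, tip_a)
        v = AAS.index("V")
        mask = np.ones(20, dtype=bool)
        mask[v] = False
        assert np.all(j[:, :, mask] == 0)
        assert np.allclose(j.sum(axis=(1, 2)), 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_joint_matches_enumeration(self, dayhoff, seed, five_taxon_tree):
        rng = np.random.default_rng(300 + seed)
        recs, _ = simulate_protein_on_tree(five_taxon_tree, dayhoff, 6, rng)
        al = encode_protein_alignment(recs)
        pm = branch_pmats(five_taxon_tree, dayhoff.eig)
        pm_o = expm_pmats(five_taxon_tree, dayhoff.q)
        tips = _tips(al, "ABCDE")
        branches = [five_taxon_tree.mrca(["A", "B"]),
                    five_taxon_tree.mrca(["D", "E"]),
                    five_taxon_tree.tip_index()["C"]]
        for br in branches:
            j = branch_joint_posterior(al, five_taxon_tree, pm, dayhoff.freqs, br)
            for s in range(al.n_sites):
                tp = {t: tips[t][al.pattern_of_site[s]] for t in "ABCDE"}
                oracle = enum_branch_joint(
                    five_taxon_tree, tp, pm_o, dayhoff.freqs, br
                )
                assert np.allclose(j[s], oracle, atol=1e-10)

    def test_joint_marginalizes_to_child_marginal(self, dayhoff, five_taxon_tree, rng):
        recs, _ = simulate_protein_on_tree(five_taxon_tree, dayhoff, 10, rng)
        al = encode_protein_alignment(recs)
        pm = branch_pmats(five_taxon_tree, dayhoff.eig)
        post = marginal_ancestral_posteriors(al, five_taxon_tree, pm, dayhoff.freqs)
        br = five_taxon_tree.mrca(["A", "B"])
        j = branch_joint_posterior(al, five_taxon_tree, pm, dayhoff.freqs, br)
        assert np.allclose(j.sum(axis=1), post[br], atol=1e-9)
        parent = five_taxon_tree.nodes[br].parent
        assert np.allclose(j.sum(axis=2), post[parent], atol=1e-9)

    def test_unknown_branch_rejected(self, dayhoff, five_taxon_tree, rng):
        recs, _ = simulate_protein_on_tree(five_taxon_tree, dayhoff, 3, rng)
        al = encode_protein_alignment(recs)
        pm = branch_pmats(five_taxon_tree, dayhoff.eig)
        with pytest.raises(KeyError):
            branch_joint_posterior(
                al, five_taxon_tree, pm, dayhoff.freqs, five_taxon_tree.root
            )


class TestFitting:
    def test_pairwise_distance_matches_scalar_oracle(self, dayhoff, rng):
        """ML distance on a two-taxon tree equals a golden-section search."""
        tree = parse_newick("(A:0.1,B:0.1);")
        recs, _ = simulate_protein_on_tree(
            parse_newick("(A:0.15,B:0.15);"), dayhoff, 400, rng
        )
        al = encode_protein_alignment(recs)
        fit = fit_branch_lengths(al, tree, dayhoff)
        t_hat = sum(fit.params["lengths"].values())

        def neg_lnl(t):
            two = parse_newick(f"(A:{t / 2:.12f},B:{t / 2:.12f});")
            return -log_likelihood(al, two, dayhoff)[0]

        res = minimize_scalar(neg_lnl, bounds=(1e-6, 5.0), method="bounded",
                              options={"xatol": 1e-10})
        assert t_hat == pytest.approx(res.x, abs=1e-4)
        assert fit.lnl == pytest.approx(-res.fun, abs=1e-6)

    def test_refit_from_optimum_is_fixed_point(self, dayhoff, five_taxon_tree, rng):
        recs, _ = simulate_protein_on_tree(five_taxon_tree, dayhoff, 60, rng)
        al = encode_protein_alignment(recs)
        fit1 = fit_branch_lengths(al, five_taxon_tree, dayhoff)
        fit2 = fit_branch_lengths(al, fit1.tree, dayhoff)
        assert fit2.lnl == pytest.approx(fit1.lnl, abs=1e-8)

    def test_m0_recovers_omega(self):
        from convsel.simulate import balanced_tree, simulate_gene

        tree = balanced_tree(8, 0.2, foreground=None)
        rng = np.random.default_rng(9)
        sim = simulate_gene(tree, 500, rng, params=0.5)
        recs = sim.records()
        al = encode_codon_alignment(recs)
        fit = fit_m0(al, tree, codon_freqs=f3x4_frequencies([r.seq for r in recs]))
        assert 0.35 < fit.params["omega"] < 0.65
        assert fit.converged
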