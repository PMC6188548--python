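"""Pairwise convergence PPs, ancestral-branch selection, trend statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import enum_pair_pps, expm_pmats
from conftest import simulate_protein_on_tree
from convsel.convergence import (
    ConvergencePairModel,
    convergence_vs_branchlength,
    gene_convergence_summary,
    select_ancestral_branch,
    site_convergence_pp,
)
from convsel.likelihood import (
    branch_joint_posterior,
    branch_pmats,
    encode_protein_alignment,
)
from convsel.trees import parse_newick


def _point_joint(a, x, s=20):
    j = np.zeros((1, s, s))
    j[0, a, x] = 1.0
    return j


class TestSitePp:
    def test_same_ancestral_same_derived_is_parallel(self):
        par, conv, tot = site_convergence_pp(_point_joint(3, 5), _point_joint(3, 5))
        assert (par[0], conv[0], tot[0]) == (1.0, 0.0, 1.0)

    def test_different_ancestral_same_derived_is_convergent(self):
        par, conv, tot = site_convergence_pp(_point_joint(3, 5), _point_joint(7, 5))
        assert (par[0], conv[0], tot[0]) == (0.0, 1.0, 1.0)

    def test_no_substitution_contributes_nothing(self):
        par, conv, tot = site_convergence_pp(_point_joint(5, 5), _point_joint(3, 5))
        assert tot[0] == 0.0

    def test_different_derived_states_do_not_count(self):
        par, conv, tot = site_convergence_pp(_point_joint(3, 5), _point_joint(3, 8))
        assert tot[0] == 0.0

    def test_unnormalized_joint_rejected(self):
        j = _point_joint(3, 5) * 0.8
        with pytest.raises(ValueError, match="normalised"):
            site_convergence_pp(j, _point_joint(3, 5))

    def test_total_is_parallel_plus_convergent_exactly(self, rng):
        for _ in range(20):
            j1 = rng.random((4, 20, 20))
            j2 = rng.random((4, 20, 20))
            j1 /= j1.sum(axis=(1, 2), keepdims=True)
            j2 /= j2.sum(axis=(1, 2), keepdims=True)
            par, conv, tot = site_convergence_pp(j1, j2)
            assert np.allclose(tot, par + conv, atol=0)
            assert np.all((tot >= 0) & (tot <= 1))

    def test_short_branches_give_vanishing_pp(self, dayhoff):
        tree = parse_newick(
            "(((A:1e-6,B:1e-6):1e-6,C:1e-6):1e-6,(D:1e-6,E:1e-6):1e-6);"
        )
        from convsel.io import SequenceRecord

        al = encode_protein_alignment([SequenceRecord(t, "LIV") for t in "ABCDE"])
        pm = branch_pmats(tree, dayhoff.eig)
        b1 = tree.mrca(["A", "B"])
        b2 = tree.mrca(["D", "E"])
        j1 = branch_joint_posterior(al, tree, pm, dayhoff.freqs, b1)
        j2 = branch_joint_posterior(al, tree, pm, dayhoff.freqs, b2)
        _, _, tot = site_convergence_pp(j1, j2)
        assert np.all(tot < 1e-8)


class TestExactAgainstEnumeration:
    @pytest.mark.parametrize("seed", range(3))
    def test_exact_mode_matches_four_endpoint_oracle(self, dayhoff, seed):
        from convsel.convergence import _exact_pair_pps

        tree = parse_newick("(((A,B),C),(D,E));")
        rng = np.random.default_rng(800 + seed)
        for i in tree.branch_nodes():
            tree.nodes[i].length = float(rng.uniform(0.05, 0.3))
        recs, _ = simulate_protein_on_tree(tree, dayhoff, 10, rng)
        al = encode_protein_alignment(recs)
        pm = branch_pmats(tree, dayhoff.eig)
        b1, b2 = tree.mrca(["A", "B"]), tree.tip_index()["D"]
        par, conv = _exact_pair_pps(al, tree, pm, dayhoff.freqs, b1, b2)
        pm_o = expm_pmats(tree, dayhoff.q)
        tips = {t: al.partials[al.taxon_row(t)] for t in "ABCDE"}
        for s in range(al.n_sites):
            tp = {t: tips[t][al.pattern_of_site[s]] for t in "ABCDE"}
            po, co = enum_pair_pps(tree, tp, pm_o, dayhoff.freqs, b1, b2)
            assert par[s] == pytest.approx(po, abs=1e-10)
            assert conv[s] == pytest.approx(co, abs=1e-10)

    def test_product_form_close_to_exact_when_separated(self, dayhoff):
        """On a study-shaped tree with focal branches in different
        superorders the independence approximation is tight."""
        from convsel.convergence import _exact_pair_pps
        from convsel.simulate import study_tree

        tree = study_tree(seed=3)
        rng = np.random.default_rng(42)
        recs, _ = simulate_protein_on_tree(tree, dayhoff, 40, rng)
        al = encode_protein_alignment(recs)
        pm = branch_pmats(tree, dayhoff.eig)
        b1, b2 = tree.node_by_tag("A"), tree.node_by_tag("D")
        j1 = branch_joint_posterior(al, tree, pm, dayhoff.freqs, b1)
        j2 = branch_joint_posterior(al, tree, pm, dayhoff.freqs, b2)
        par, conv, _ = site_convergence_pp(j1, j2)
        par_x, conv_x = _exact_pair_pps(al, tree, pm, dayhoff.freqs, b1, b2)
        assert np.abs(par - par_x).max() < 1e-3
        assert np.abs(conv - conv_x).max() < 1e-3


class TestAncestralBranchSelection:
    def setup_method(self):
        self.tree = parse_newick(
            "(((A:0.1,B:0.2):0.1,(C:0.1,D:0.1):0.2):0.1,(E:0.3,F:0.1):0.2);"
        )

    def test_full_clade_gives_stem_branch(self):
        b = select_ancestral_branch(self.tree, ["A", "B"])
        assert b == self.tree.mrca(["A", "B"])

    def test_single_member_gives_terminal_branch(self):
        b = select_ancestral_branch(self.tree, ["C"])
        assert b == self.tree.tip_index()["C"]

    def test_partial_clade_gives_mrca_of_present(self):
        pruned = self.tree.prune_to(["A", "C", "D", "E"])
        b = select_ancestral_branch(pruned, ["C", "D", "X_missing"])
        assert sorted(pruned.subtree_tips(b)) == ["C", "D"]

    def test_absent_clade_raises(self):
        with pytest.raises(KeyError):
            select_ancestral_branch(self.tree, ["Z1", "Z2"])

    def test_clade_spanning_root_raises(self):
        with pytest.raises(ValueError, match="root"):
            select_ancestral_branch(self.tree, ["A", "E"])


class TestGeneSummary:
    def test_two_tier_thresholds(self):
        prof = gene_convergence_summary([0.6, 0.0], [0.0, 0.6], gene="g")
        assert prof.summed_pp_total == pytest.approx(1.2)
        assert prof.flag_1_0 and not prof.flag_2_0
        assert prof.n_sites_pp_gt_half == 2
        assert prof.retained

    def test_diffuse_signal_not_retained(self):
        prof = gene_convergence_summary([0.3] * 4, [0.0] * 4)
        assert prof.flag_1_0
        assert prof.n_sites_pp_gt_half == 0
        assert not prof.retained

    def test_empty_gene(self):
        prof = gene_convergence_summary([], [])
        assert prof.summed_pp_total == 0.0
        assert not prof.flag_1_0 and not prof.flag_2_0


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31), st.integers(2, 30))
def test_summed_pp_additive_over_blocks(seed, n_sites):
    rng = np.random.default_rng(seed)
    par = rng.random(n_sites) * 0.5
    conv = rng.random(n_sites) * 0.5
    k = n_sites // 2
    whole = gene_convergence_summary(par, conv)
    left = gene_convergence_summary(par[:k], conv[:k])
    right = gene_convergence_summary(par[k:], conv[k:])
    assert whole.summed_pp_total == pytest.approx(
        left.summed_pp_total + right.summed_pp_total, rel=1e-12
    )


class TestTrend:
    def test_monotone_simulation_gives_perfect_rank_correlation(self, dayhoff):
        lengths = [0.05, 0.2, 0.8]
        totals = []
        for i, t in enumerate(lengths):
            tree = parse_newick(
                f"(((A:{t},B:{t}):0.1,C:0.1):0.05,(D:{t},E:{t}):0.1);"
            )
            rng = np.random.default_rng(1000 + i)
            recs, _ = simulate_protein_on_tree(tree, dayhoff, 200, rng)
            al = encode_protein_alignment(recs)
            pm = branch_pmats(tree, dayhoff.eig)
            b1, b2 = tree.mrca(["A", "B"]), tree.mrca(["D", "E"])
            j1 = branch_joint_posterior(al, tree, pm, dayhoff.freqs, b1)
            j2 = branch_joint_posterior(al, tree, pm, dayhoff.freqs, b2)
            totals.append(site_convergence_pp(j1, j2)[2].sum())
        res = convergence_vs_branchlength(totals, lengths)
        assert res["spearman_rho"] == pytest.approx(1.0)
        assert res["pearson_r"] > 0 and res["slope"] > 0

    def test_identical_totals_give_zero(self):
        res = convergence_vs_branchlength([2.0, 2.0, 2.0], [0.1, 0.2, 0.3])
        assert res["spearman_rho"] == 0.0 and res["slope"] == 0.0

    def test_degenerate_x_flagged(self):
        res = convergence_vs_branchlength([1.0, 2.0, 3.0], [0.1, 0.1, 0.1])
        assert res["degenerate_x"]

    def test_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            convergence_vs_branchlength([1.0, 2.0], [0.1, 0.2])


def test_pair_model_front_end(dayhoff):
    """ConvergencePairModel wires pruning, fitting and scoring together."""
    from convsel.simulate import FOCAL_CLADES, simulate_gene, study_tree
    from convsel.likelihood import translate_records

    tree = study_tree(seed=4)
    rng = np.random.default_rng(9)
    sim = simulate_gene(tree, 60, rng, params=0.2)
    prot = translate_records(sim.records())
    res = ConvergencePairModel(
        prot, tree, FOCAL_CLADES["A"], FOCAL_CLADES["B"]
    ).fit(gene="g0")
    assert res.profile.summed_pp_total >= 0
    table = res.site_table("g0")
    assert list(table.columns) == [
        "gene", "site", "pp_parallel", "pp_convergent", "pp_total",
    ]
    assert len(table) == 60
    assert "summed PP total" in res.summary()


def test_nested_branch_pair_rejected(dayhoff, rng):
    from convsel.io import SequenceRecord

    tree = parse_newick("(((A:0.1,B:0.1):0.1,C:0.1):0.1,D:0.1);")
    recs = [SequenceRecord(t, "LIVLIV") for t in "ABCD"]
    model = ConvergencePairModel(recs, tree, ["A", "B", "C"], ["A", "B"])
    with pytest.raises(ValueError, match="nested|same"):
        model.fit()
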