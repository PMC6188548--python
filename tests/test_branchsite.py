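"""Branch-site Model A machinery: LRT, EB posteriors, PSS rules, FDR."""

import numpy as np
import pytest
from scipy.stats import chi2

from _oracles import enum_site_likelihood, expm_pmats
from convsel.branchsite import (
    AggregationFilter,
    BranchSiteModel,
    LrtResult,
    PssCall,
    bh_fdr,
    branch_site_lrt,
    call_pss,
    eb_site_posteriors,
    fit_model_a,
    fit_model_a_null,
    pss_aggregation_filter,
)
from convsel.likelihood import encode_codon_alignment, fit_m0, match_tree
from convsel.simulate import ModelAParams, balanced_tree, simulate_gene
from convsel.substmodels import (
    codon_rate_matrix,
    expected_rate,
    f3x4_frequencies,
)


@pytest.fixture(scope="module")
def small_gene():
    """A 6-taxon gene with mild foreground selection, fitted once."""
    tree = balanced_tree(8, 0.25, foreground="pair0")
    rng = np.random.default_rng(77)
    sim = simulate_gene(
        tree, 80, rng, params=ModelAParams(omega2=6.0), foreground_tags=("1",)
    )
    recs = sim.records()
    align = encode_codon_alignment(recs)
    freqs = f3x4_frequencies([r.seq for r in recs])
    m0 = fit_m0(align, match_tree(align, tree), codon_freqs=freqs)
    null = fit_model_a_null(align, tree, "1", freqs, m0=m0)
    alt = fit_model_a(
        align, tree, "1", freqs, m0=m0,
        extra_starts=[(null.p0, null.p1, null.omega0, 1.0)],
    )
    return sim, align, freqs, m0, null, alt


class TestLrt:
    def test_equal_likelihoods_give_p_one(self):
        res = branch_site_lrt(-100.0, -100.0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_critical_value(self):
        # 2*delta = 3.841459 is the chi2(1) 5% critical value
        res = branch_site_lrt(-100.0, -100.0 + 3.841459 / 2)
        assert res.p_value == pytest.approx(0.05, abs=1e-6)

    def test_against_chi2_oracle(self):
        res = branch_site_lrt(-50.0, -47.0)  # 2*delta = 6
        assert res.p_value == pytest.approx(chi2.sf(6.0, 1), rel=1e-12)
        assert res.p_value == pytest.approx(0.01431, abs=5e-6)

    def test_negative_delta_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            res = branch_site_lrt(-100.0, -100.001)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            branch_site_lrt(float("nan"), -1.0)


class TestModelAFits:
    def test_null_omega2_fixed_at_one(self, small_gene):
        _, _, _, _, null, _ = small_gene
        assert null.omega2 == 1.0
        assert null.is_null

    def test_nesting_alt_at_least_null(self, small_gene):
        _, _, _, _, null, alt = small_gene
        assert alt.lnl >= null.lnl - 1e-6

    def test_class_proportions_valid(self, small_gene):
        _, _, _, _, null, alt = small_gene
        for fit in (null, alt):
            props = fit.proportions
            assert np.all(props >= 0)
            assert props.sum() == pytest.approx(1.0, abs=1e-9)
            assert 0 < fit.omega0 < 1

    def test_site_class_posteriors_normalized(self, small_gene):
        _, _, _, _, _, alt = small_gene
        assert np.allclose(
            alt.site_class_posteriors.sum(axis=1), 1.0, atol=1e-9
        )

    def test_missing_foreground_tag_rejected(self, small_gene):
        sim, align, freqs, m0, _, _ = small_gene
        tree = balanced_tree(8, 0.25, foreground=None)
        with pytest.raises(ValueError, match="foreground"):
            fit_model_a(align, tree, "1", freqs)


class TestEmpiricalBayes:
    def test_neb_matches_hand_computed_class_mixture(self):
        """NEB PP = q_k L_k / sum_j q_j L_j with class likelihoods from an
        independent expm-based enumeration (4-taxon toy)."""
        toy_tree = balanced_tree(4, 0.2, foreground="pair0")
        rng = np.random.default_rng(21)
        sim = simulate_gene(
            toy_tree, 40, rng, params=ModelAParams(omega2=5.0),
            foreground_tags=("1",),
        )
        recs = sim.records()
        align = encode_codon_alignment(recs)
        freqs = f3x4_frequencies([r.seq for r in recs])
        alt = fit_model_a(align, toy_tree, "1", freqs)
        tree = alt.tree
        fg = alt.foreground
        props = alt.proportions
        # joint mixture scale, recomputed independently of the engine
        def rate(w):
            return expected_rate(codon_rate_matrix(alt.kappa, w, freqs), freqs)

        scale = (props[0] + props[2]) * rate(alt.omega0) + (
            props[1] + props[3]
        ) * rate(1.0)
        scaled = tree.copy()
        for i in scaled.branch_nodes():
            scaled.nodes[i].length /= scale
        class_branch_omegas = [
            (alt.omega0, alt.omega0),
            (1.0, 1.0),
            (alt.omega0, alt.omega2),
            (1.0, alt.omega2),
        ]
        taxa = align.taxa
        tips = {t: align.partials[align.taxon_row(t)] for t in taxa}
        n_check = 6
        liks = np.zeros((4, n_check))
        for k, (bg, fgw) in enumerate(class_branch_omegas):
            pm = expm_pmats(scaled, codon_rate_matrix(alt.kappa, bg, freqs))
            q_fg = codon_rate_matrix(alt.kappa, fgw, freqs)
            from scipy.linalg import expm

            pm[fg] = expm(q_fg * scaled.nodes[fg].length)
            for s in range(n_check):
                tp = {t: tips[t][align.pattern_of_site[s]] for t in taxa}
                liks[k, s] = enum_site_likelihood(scaled, tp, pm, freqs)
        hand = (props[:, None] * liks) / (props[:, None] * liks).sum(axis=0)
        assert np.allclose(
            alt.site_class_posteriors[:n_check].T, hand, atol=1e-10
        )

    def test_neb_and_beb_in_range_and_consistent(self, small_gene):
        sim, align, _, _, _, alt = small_gene
        neb = eb_site_posteriors(alt, align, method="NEB")
        beb = eb_site_posteriors(alt, align, method="BEB")
        for pps in (neb, beb):
            assert pps.shape == (align.n_sites,)
            assert np.all((pps >= 0) & (pps <= 1))

    def test_invariant_site_not_selected(self, dayhoff):
        """A site identical in all taxa should not look selected."""
        tree = balanced_tree(4, 0.1, foreground="pair0")
        rng = np.random.default_rng(5)
        sim = simulate_gene(tree, 60, rng, params=ModelAParams(omega2=4.0),
                            foreground_tags=("1",))
        recs = sim.records()
        # overwrite the first codon with an invariant one
        recs = [type(r)(r.id, "ATG" + r.seq[3:]) for r in recs]
        align = encode_codon_alignment(recs)
        freqs = f3x4_frequencies([r.seq for r in recs])
        alt = fit_model_a(align, tree, "1", freqs)
        pps = eb_site_posteriors(alt, align, method="NEB")
        assert pps[0] < 0.5

    def test_unknown_method_rejected(self, small_gene):
        _, align, _, _, _, alt = small_gene
        with pytest.raises(ValueError):
            eb_site_posteriors(alt, align, method="XEB")


class TestPssCalling:
    def _lrt(self, p):
        stat = chi2.isf(p, 1)
        return LrtResult(-100.0, -100.0 + stat / 2, stat, 1, p)

    def test_nonsignificant_gene_yields_no_sites(self, small_gene):
        _, _, _, _, _, alt = small_gene
        pps = np.array([0.99, 0.2, 0.8])
        assert call_pss(self._lrt(0.2), alt, pps) == []

    def test_threshold_and_sorting(self, small_gene):
        _, _, _, _, _, alt = small_gene
        fit = alt
        assert fit.omega2 > 1.0
        pps = np.zeros(10)
        pps[6] = 0.93
        pps[8] = 0.40
        pps[2] = 0.51
        calls = call_pss(self._lrt(0.01), fit, pps)
        assert [c.site for c in calls] == [3, 7]

    def test_omega_gate(self, small_gene):
        _, _, _, _, null, _ = small_gene
        pps = np.array([0.99])
        assert call_pss(self._lrt(0.01), null, pps) == []

    def test_order_invariance(self, small_gene):
        _, _, _, _, _, alt = small_gene
        rng = np.random.default_rng(0)
        pps = rng.random(30)
        calls = call_pss(self._lrt(0.001), alt, pps)
        # site order in the input array is positional; permuting labels via
        # a reordered computation gives the same sorted call list
        assert [c.site for c in calls] == sorted(c.site for c in calls)


class TestAggregationFilter:
    @pytest.mark.parametrize(
        "sites,retain,median",
        [
            ([10, 15, 22], False, 6.0),
            ([5, 40, 100], True, 47.5),
            ([12], True, None),
            ([], True, None),
            ([3, 14], True, 11.0),
            ([3, 13], False, 10.0),
        ],
    )
    def test_rule(self, sites, retain, median):
        res = pss_aggregation_filter(sites)
        assert res == AggregationFilter(retain=retain, median_interval=median)

    def test_input_order_irrelevant(self):
        assert pss_aggregation_filter([22, 10, 15]) == pss_aggregation_filter(
            [10, 15, 22]
        )


class TestBhFdr:
    def test_hand_computed_example(self):
        adj = bh_fdr([0.01, 0.02, 0.04])
        assert np.allclose(adj, [0.03, 0.03, 0.04])

    def test_ties_and_single(self):
        assert np.allclose(bh_fdr([0.05, 0.05, 0.05]), 0.05)
        assert bh_fdr([0.42])[0] == pytest.approx(0.42)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        adj = bh_fdr(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])


def test_results_front_end_summary(small_gene):
    """The Model/Results wrapper reports a coherent gene-level summary."""
    sim, _, _, _, _, _ = small_gene
    tree = balanced_tree(8, 0.25, foreground="pair0")
    res = BranchSiteModel(sim.records(), tree, "1").fit(eb_method="NEB")
    assert res.lrt.statistic >= 0
    row = res.to_row("gene1")
    assert row["gene"] == "gene1"
    assert row["n_taxa"] == 8
    text = res.summary()
    assert "omega2" in text and "lnL" in text
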