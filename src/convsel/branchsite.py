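"""Branch-site test of episodic positive selection (Model A vs. its null).

Model A partitions sites into four classes: class 0 evolves under
purifying selection (0 < w0 < 1) everywhere, class 1 is neutral (w1 = 1)
everywhere, and classes 2a/2b allow w2 >= 1 on a designated *foreground*
branch while keeping the background at w0 and 1 respectively.  The null
model fixes w2 = 1 and is compared with the alternative by a chi-square
likelihood-ratio test with one degree of freedom; sites under selection
are then identified from empirical-Bayes posteriors of membership in the
selected classes (naive plug-in NEB, or BEB averaging over a parameter
grid).  Class proportions follow the standard constrained form

    q0 = p0, q1 = p1, q2a = (1-p0-p1) p0/(p0+p1), q2b = (1-p0-p1) p1/(p0+p1).

Branch lengths and kappa are estimated per gene under the one-ratio M0
model and held fixed during the branch-site fits; within each branch-site
likelihood evaluation the class rate matrices share a joint scale equal to
the mixture-averaged background substitution rate, so branch lengths stay
in expected substitutions per codon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .genetics import CODON_NDIFF, CODON_SYNONYMOUS, CODON_TRANSITION
from .likelihood import (
    Alignment,
    FitResult,
    branch_pmats,
    encode_codon_alignment,
    fit_m0,
    match_tree,
    pattern_logliks,
)
from .substmodels import EigenQ, codon_rate_matrix, f3x4_frequencies
from .trees import RootedTree

__all__ = [
    "ModelAFit",
    "LrtResult",
    "PssCall",
    "AggregationFilter",
    "fit_model_a",
    "fit_model_a_null",
    "branch_site_lrt",
    "eb_site_posteriors",
    "call_pss",
    "pss_aggregation_filter",
    "bh_fdr",
    "BranchSiteModel",
    "BranchSiteResults",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------


@dataclass
class ModelAFit:
    """Fitted branch-site Model A (or its w2=1 null)."""

    p0: float
    p1: float
    omega0: float
    omega2: float
    kappa: float
    lnl: float
    converged: bool
    tree: RootedTree
    foreground: int
    codon_freqs: np.ndarray
    site_class_posteriors: np.ndarray  # (n_sites, 4), NEB at the MLE
    _align: Alignment = field(repr=False)

    @property
    def proportions(self) -> np.ndarray:
        return _class_proportions(self.p0, self.p1)

    @property
    def is_null(self) -> bool:
        return self.omega2 == 1.0


@dataclass
class LrtResult:
    """Likelihood-ratio test of Model A against its null (1 df chi-square)."""

    lnl_null: float
    lnl_alt: float
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class PssCall:
    """A positively selected site: 1-based column, EB posterior, method."""

    site: int
    eb_posterior: float
    method: str


@dataclass(frozen=True)
class AggregationFilter:
    """Outcome of the clustered-PSS alignment-error filter."""

    retain: bool
    median_interval: float | None


# ---------------------------------------------------------------------------
# Model A machinery
# ---------------------------------------------------------------------------


def _class_proportions(p0: float, p1: float) -> np.ndarray:
    tot = p0 + p1
    rest = max(1.0 - tot, 0.0)
    return np.array([p0, p1, rest * p0 / tot, rest * p1 / tot])


def _rate_coefficients(kappa: float, freqs: np.ndarray) -> tuple[float, float]:
    """Expected rate of the unscaled codon Q as a linear function of omega:
    rate = syn + omega * nonsyn (both depend on kappa and the frequencies)."""
    base = np.where(CODON_NDIFF == 1, freqs[None, :], 0.0)
    base = np.where(CODON_TRANSITION, base * kappa, base)
    flow = freqs[:, None] * base
    syn = float(flow[CODON_SYNONYMOUS & (CODON_NDIFF == 1)].sum())
    nonsyn = float(flow[(~CODON_SYNONYMOUS) & (CODON_NDIFF == 1)].sum())
    return syn, nonsyn


class _ModelAEngine:
    """Per-gene cache for branch-site likelihood evaluations."""

    def __init__(
        self,
        align: Alignment,
        tree: RootedTree,
        foreground: int,
        kappa: float,
        codon_freqs: np.ndarray,
    ):
        self.align = align
        self.tree = tree
        self.fg = foreground
        self.kappa = kappa
        self.freqs = codon_freqs
        self.syn_rate, self.nonsyn_rate = _rate_coefficients(kappa, codon_freqs)
        self.nodes = tree.branch_nodes()
        if foreground == tree.root:
            raise ValueError("the root cannot be a foreground branch")
        self._eig_cache: dict[tuple[float, float], EigenQ] = {}

    def _eig(self, omega: float) -> EigenQ:
        """Unscaled Q(omega); the mixture scale is applied to branch lengths."""
        key = round(omega, 14)
        if key not in self._eig_cache:
            q = codon_rate_matrix(self.kappa, omega, self.freqs)
            self._eig_cache[key] = EigenQ(q, self.freqs)
            if len(self._eig_cache) > 64:
                self._eig_cache.pop(next(iter(self._eig_cache)))
        return self._eig_cache[key]

    def _scaled_lengths(self, scale: float) -> dict[int, float]:
        return {i: self.tree.nodes[i].length / scale for i in self.nodes}

    def mixture_scale(self, props: np.ndarray, omega0: float) -> float:
        """Mixture-averaged background rate (class 2b/1 are neutral there)."""
        r0 = self.syn_rate + omega0 * self.nonsyn_rate
        r1 = self.syn_rate + self.nonsyn_rate
        return float((props[0] + props[2]) * r0 + (props[1] + props[3]) * r1)

    def class_logliks(
        self, omega0: float, omega2: float, scale: float
    ) -> np.ndarray:
        """Per-pattern log-likelihoods for the 4 site classes; (4, n_pat)."""
        lengths = self._scaled_lengths(scale)
        e0 = self._eig(omega0)
        e1 = self._eig(1.0)
        pm0 = branch_pmats(self.tree, e0, lengths)
        pm1 = branch_pmats(self.tree, e1, lengths)
        if omega2 == 1.0:
            pm2_fg = pm1[self.fg]
        else:
            e2 = self._eig(omega2)
            pm2_fg = e2.transition_matrix(lengths[self.fg])
        l0 = pattern_logliks(self.align, self.tree, pm0, self.freqs)
        l1 = pattern_logliks(self.align, self.tree, pm1, self.freqs)
        l2a = pattern_logliks(
            self.align, self.tree, {**pm0, self.fg: pm2_fg}, self.freqs
        )
        if omega2 == 1.0:
            l2b = l1
        else:
            l2b = pattern_logliks(
                self.align, self.tree, {**pm1, self.fg: pm2_fg}, self.freqs
            )
        return np.stack([l0, l1, l2a, l2b])

    def mixture_loglik(
        self, p0: float, p1: float, omega0: float, omega2: float
    ) -> tuple[float, np.ndarray]:
        props = _class_proportions(p0, p1)
        scale = self.mixture_scale(props, omega0)
        cls = self.class_logliks(omega0, omega2, scale)
        site = logsumexp(cls, axis=0, b=props[:, None])
        return float(site @ self.align.weights), cls


def _unpack_params(x: np.ndarray, fix_omega2: bool) -> tuple[float, float, float, float]:
    e1, e2 = np.exp(x[0]), np.exp(x[1])
    d = 1.0 + e1 + e2
    p0, p1 = e1 / d, e2 / d
    omega0 = np.exp(x[2])
    omega2 = 1.0 if fix_omega2 else float(np.exp(x[3]))
    return float(p0), float(p1), float(omega0), omega2


def fit_model_a(
    align: Alignment,
    tree: RootedTree,
    foreground: str | int = "1",
    codon_freqs: np.ndarray | None = None,
    fix_omega2: bool = False,
    m0: FitResult | None = None,
    extra_starts: list[tuple[float, float, float, float]] | None = None,
) -> ModelAFit:
    """Fit branch-site Model A by ML.

    Branch lengths and kappa come from an M0 fit (computed here if not
    supplied).  ``foreground`` is a branch tag (e.g. ``"1"``) or a node
    index in the pruned tree; exactly one branch may carry the tag.
    """
    work = match_tree(align, tree)
    if isinstance(foreground, str) and not work.has_tag(foreground):
        raise ValueError(f"no foreground branch tagged {foreground!r} in tree")
    if codon_freqs is None:
        raise ValueError("codon_freqs is required (use f3x4 from the gene)")
    if m0 is None:
        m0 = fit_m0(align, work, codon_freqs=codon_freqs)
    work = m0.tree
    fg = work.node_by_tag(foreground) if isinstance(foreground, str) else foreground
    engine = _ModelAEngine(align, work, fg, m0.params["kappa"], codon_freqs)

    def objective(x):
        p0, p1, omega0, omega2 = _unpack_params(x, fix_omega2)
        lnl, _ = engine.mixture_loglik(p0, p1, omega0, omega2)
        return -lnl

    w0_start = min(max(m0.params["omega"], 0.01), 0.9)
    starts: list[list[float]] = []
    base = [np.log(0.5 / 0.2), np.log(0.3 / 0.2), np.log(w0_start)]
    if fix_omega2:
        starts.append(base)
        starts.append([np.log(0.85 / 0.1), np.log(0.05 / 0.1), np.log(0.05)])
    else:
        starts.append(base + [np.log(2.0)])
        if not extra_starts:  # a near-null start unless one is supplied
            starts.append(base + [np.log(1.0 + 1e-6)])
    if extra_starts:
        for p0, p1, w0, w2 in extra_starts:
            rest = max(1.0 - p0 - p1, 1e-6)
            s = [np.log(p0 / rest), np.log(p1 / rest), np.log(w0)]
            if not fix_omega2:
                s.append(np.log(max(w2, 1.0)))
            starts.append(s)

    nb = 3 if fix_omega2 else 4
    bounds = [(-14.0, 14.0), (-14.0, 14.0), (np.log(1e-4), np.log(0.9999))]
    if not fix_omega2:
        bounds.append((0.0, np.log(50.0)))
    best = None
    for x0 in starts:
        res = minimize(
            objective,
            np.array(x0[:nb]),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    p0, p1, omega0, omega2 = _unpack_params(best.x, fix_omega2)
    lnl, cls = engine.mixture_loglik(p0, p1, omega0, omega2)
    props = _class_proportions(p0, p1)
    # NEB class posteriors at the MLE, expanded to sites
    log_post = np.log(props[:, None]) + cls
    log_post -= logsumexp(log_post, axis=0, keepdims=True)
    site_post = np.exp(log_post).T[align.pattern_of_site]
    return ModelAFit(
        p0=p0,
        p1=p1,
        omega0=omega0,
        omega2=omega2,
        kappa=engine.kappa,
        lnl=lnl,
        converged=bool(best.success),
        tree=work,
        foreground=fg,
        codon_freqs=codon_freqs,
        site_class_posteriors=site_post,
        _align=align,
    )


def fit_model_a_null(
    align: Alignment,
    tree: RootedTree,
    foreground: str | int = "1",
    codon_freqs: np.ndarray | None = None,
    m0: FitResult | None = None,
) -> ModelAFit:
    """The null branch-site model: identical to Model A with w2 fixed at 1."""
    return fit_model_a(
        align,
        tree,
        foreground=foreground,
        codon_freqs=codon_freqs,
        fix_omega2=True,
        m0=m0,
    )


def branch_site_lrt(lnl_null: float, lnl_alt: float) -> LrtResult:
    """2*(lnL_alt - lnL_null) against chi-square with 1 df, clamped at 0."""
    if not (np.isfinite(lnl_null) and np.isfinite(lnl_alt)):
        raise ValueError("log-likelihoods must be finite")
    delta = 2.0 * (lnl_alt - lnl_null)
    if delta < -1e-6:
        warnings.warn(
            f"alternative lnL below null by {-delta / 2:.3g}: optimizer issue; "
            "clamping the statistic at 0",
            stacklevel=2,
        )
    stat = max(delta, 0.0)
    return LrtResult(
        lnl_null=lnl_null,
        lnl_alt=lnl_alt,
        statistic=stat,
        df=1,
        p_value=float(chi2.sf(stat, df=1)) if stat > 0 else 1.0,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes site posteriors
# ---------------------------------------------------------------------------

_BEB_GRID = 10


def _beb_grid_posteriors(fit: ModelAFit, align: Alignment) -> np.ndarray:
    """Bayes empirical Bayes PP(site in class 2a or 2b).

    The prior is uniform over a discrete grid: w0 over the midpoints of 10
    bins on (0,1), w2 over the midpoints of 10 bins on (1,11), and the
    class-proportion pair through (p0+p1, p0/(p0+p1)) each over midpoints
    of 10 bins on (0,1).  Gridpoints are weighted by their marginal data
    likelihood (kappa and branch lengths held at their estimates).
    """
    engine = _ModelAEngine(
        align, fit.tree, fit.foreground, fit.kappa, fit.codon_freqs
    )
    g = _BEB_GRID
    mids = (np.arange(g) + 0.5) / g
    w0s = mids
    w2s = 1.0 + 10.0 * mids
    ptots, fracs = mids, mids
    # class proportions per (ptot, frac) gridpoint: (g, g, 4)
    props = np.empty((g, g, 4))
    for a, pt in enumerate(ptots):
        for b, fr in enumerate(fracs):
            props[a, b] = _class_proportions(pt * fr, pt * (1 - fr))
    # scale fixed at the MLE mixture scale: one consistent time scale
    scale = engine.mixture_scale(fit.proportions, fit.omega0)

    n_pat = align.n_patterns
    lengths = engine._scaled_lengths(scale)
    l0 = np.empty((g, n_pat))
    l2a = np.empty((g, g, n_pat))
    l2b = np.empty((g, n_pat))
    e1 = engine._eig(1.0)
    pm1 = branch_pmats(engine.tree, e1, lengths)
    l1 = pattern_logliks(align, engine.tree, pm1, engine.freqs)
    fg_len = lengths[engine.fg]
    fg_pm2 = [engine._eig(w2).transition_matrix(fg_len) for w2 in w2s]
    for i, w0 in enumerate(w0s):
        e0 = engine._eig(w0)
        pm0 = branch_pmats(engine.tree, e0, lengths)
        l0[i] = pattern_logliks(align, engine.tree, pm0, engine.freqs)
        for j in range(g):
            l2a[i, j] = pattern_logliks(
                align, engine.tree, {**pm0, engine.fg: fg_pm2[j]}, engine.freqs
            )
    for j in range(g):
        l2b[j] = pattern_logliks(
            align, engine.tree, {**pm1, engine.fg: fg_pm2[j]}, engine.freqs
        )

    # shift to likelihood domain per pattern
    shift = np.maximum.reduce(
        [l0.max(axis=0), l1, l2a.max(axis=(0, 1)), l2b.max(axis=0)]
    )
    e0v = np.exp(l0 - shift)  # (g, P)
    e1v = np.exp(l1 - shift)  # (P,)
    e2av = np.exp(l2a - shift)  # (g, g, P)
    e2bv = np.exp(l2b - shift)  # (g, P)

    w = align.weights

    def _mix_sel(i: int) -> tuple[np.ndarray, np.ndarray]:
        # mixture and selected-class likelihood over (j, a, b, P) at fixed w0_i
        mix = (
            props[None, :, :, 0, None] * e0v[i, None, None, None, :]
            + props[None, :, :, 1, None] * e1v[None, None, None, :]
            + props[None, :, :, 2, None] * e2av[i, :, None, None, :]
            + props[None, :, :, 3, None] * e2bv[:, None, None, :]
        )
        sel = (
            props[None, :, :, 2, None] * e2av[i, :, None, None, :]
            + props[None, :, :, 3, None] * e2bv[:, None, None, :]
        )
        return mix, sel

    log_marg = np.empty((g, g, g, g))  # (i, j, a, b)
    pp_num = np.zeros(n_pat)
    for i in range(g):
        mix, _ = _mix_sel(i)
        log_marg[i] = np.log(mix) @ w
    log_marg_flat = log_marg.reshape(-1)
    grid_post = np.exp(log_marg_flat - logsumexp(log_marg_flat))
    grid_post = grid_post.reshape(g, g, g, g)
    # second pass: accumulate posterior-weighted selected-class fraction
    for i in range(g):
        mix, sel = _mix_sel(i)
        frac = np.where(mix > 0, sel / np.where(mix > 0, mix, 1.0), 0.0)
        pp_num += np.einsum("jab,jabp->p", grid_post[i], frac)
    return pp_num[align.pattern_of_site]


def eb_site_posteriors(
    fit: ModelAFit, align: Alignment | None = None, method: str = "BEB"
) -> np.ndarray:
    """Per-site posterior probability of membership in class 2a or 2b.

    ``NEB`` plugs in the MLEs; ``BEB`` averages over the parameter grid.
    """
    align = align if align is not None else fit._align
    if method == "NEB":
        return fit.site_class_posteriors[:, 2] + fit.site_class_posteriors[:, 3]
    if method == "BEB":
        return _beb_grid_posteriors(fit, align)
    raise ValueError(f"unknown empirical-Bayes method {method!r}")


def call_pss(
    lrt: LrtResult,
    fit: ModelAFit,
    site_pps: np.ndarray,
    method: str = "BEB",
    alpha: float = 0.05,
    pp_threshold: float = 0.5,
) -> list[PssCall]:
    """Positively selected sites: gated on LRT p < alpha and w2 > 1, then
    sites with EB posterior > ``pp_threshold`` (1-based, ascending)."""
    if lrt.p_value >= alpha or fit.omega2 <= 1.0:
        return []
    sites = np.nonzero(np.asarray(site_pps) > pp_threshold)[0]
    return [PssCall(int(s) + 1, float(site_pps[s]), method) for s in sorted(sites)]


def pss_aggregation_filter(pss_sites: list[int]) -> AggregationFilter:
    """Alignment-error screen: exclude a gene when its PSSs are clustered.

    Intervals are successive differences of the sorted 1-based positions;
    the gene is excluded iff the median interval is <= 10 amino acids.
    Genes with fewer than two PSSs have no intervals and are retained.
    """
    sites = sorted(pss_sites)
    if len(sites) < 2:
        return AggregationFilter(retain=True, median_interval=None)
    intervals = np.diff(sites)
    med = float(np.median(intervals))
    return AggregationFilter(retain=med > 10.0, median_interval=med)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Model / Results front-end
# ---------------------------------------------------------------------------


class BranchSiteModel:
    """Branch-site positive-selection test for one gene.

    Parameters
    ----------
    records : list of SequenceRecord or Alignment
        In-frame codon alignment of the gene.
    tree : RootedTree
        Species tree; pruned to the gene's taxa internally.  The
        foreground branch carries a ``#``-tag (default tag ``"1"``).
    foreground : str
        Branch tag naming the foreground branch.
    """

    def __init__(self, records, tree: RootedTree, foreground: str = "1"):
        if isinstance(records, Alignment):
            self.align = records
            self._seqs = None
        else:
            self.align = encode_codon_alignment(records)
            self._seqs = [r.seq for r in records]
        self.tree = tree
        self.foreground = foreground
        if self._seqs is not None:
            self.codon_freqs = f3x4_frequencies(self._seqs)
        else:
            raise ValueError(
                "pass sequence records (codon frequencies are estimated F3x4)"
            )

    def fit(self, eb_method: str = "BEB", alpha: float = 0.05) -> "BranchSiteResults":
        m0 = fit_m0(self.align, match_tree(self.align, self.tree), self.codon_freqs)
        null = fit_model_a_null(
            self.align, self.tree, self.foreground, self.codon_freqs, m0=m0
        )
        alt = fit_model_a(
            self.align,
            self.tree,
            self.foreground,
            self.codon_freqs,
            m0=m0,
            extra_starts=[(null.p0, null.p1, null.omega0, 1.0)],
        )
        if alt.lnl < null.lnl:  # nested models: keep the null optimum
            alt = fit_model_a(
                self.align,
                self.tree,
                self.foreground,
                self.codon_freqs,
                m0=m0,
                extra_starts=[
                    (null.p0, null.p1, null.omega0, 1.0),
                    (null.p0, null.p1, null.omega0, 1.5),
                ],
            )
        lrt = branch_site_lrt(null.lnl, alt.lnl)
        if lrt.p_value < alpha and alt.omega2 > 1.0:
            pps = eb_site_posteriors(alt, self.align, method=eb_method)
        else:
            pps = eb_site_posteriors(alt, self.align, method="NEB")
        pss = call_pss(lrt, alt, pps, method=eb_method, alpha=alpha)
        agg = pss_aggregation_filter([c.site for c in pss])
        return BranchSiteResults(
            model=self, m0=m0, null=null, alt=alt, lrt=lrt,
            site_pps=pps, pss=pss, aggregation=agg,
        )


@dataclass
class BranchSiteResults:
    """Results of the branch-site screen on one gene."""

    model: BranchSiteModel
    m0: FitResult
    null: ModelAFit
    alt: ModelAFit
    lrt: LrtResult
    site_pps: np.ndarray
    pss: list[PssCall]
    aggregation: AggregationFilter

    @property
    def significant(self) -> bool:
        return self.lrt.p_value < 0.05 and self.alt.omega2 > 1.0

    def to_row(self, gene: str = "") -> dict:
        return {
            "gene": gene,
            "n_taxa": len(self.model.align.taxa),
            "n_codons": self.model.align.n_sites,
            "lnL0": self.null.lnl,
            "lnL1": self.alt.lnl,
            "stat": self.lrt.statistic,
            "p": self.lrt.p_value,
            "omega2": self.alt.omega2,
            "n_pss": len(self.pss),
            "pss_sites": ";".join(str(c.site) for c in self.pss),
            "filter_flag": "retain" if self.aggregation.retain else "exclude",
        }

    def summary(self) -> str:
        rows = [
            ("lnL (null, w2=1)", f"{self.null.lnl:.4f}"),
            ("lnL (Model A)", f"{self.alt.lnl:.4f}"),
            ("2*deltaLnL", f"{self.lrt.statistic:.4f}"),
            ("P (chi2, 1 df)", f"{self.lrt.p_value:.4g}"),
            ("kappa", f"{self.alt.kappa:.3f}"),
            ("omega0", f"{self.alt.omega0:.3f}"),
            ("omega2 (foreground)", f"{self.alt.omega2:.3f}"),
            ("p0, p1", f"{self.alt.p0:.3f}, {self.alt.p1:.3f}"),
            ("PSS (EB > 0.5)", ", ".join(str(c.site) for c in self.pss) or "none"),
            (
                "clustered-PSS filter",
                "retain" if self.aggregation.retain else "exclude",
            ),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Branch-site positive selection test", "=" * 38]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)
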