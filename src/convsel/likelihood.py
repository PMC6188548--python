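"""Pruning-algorithm likelihoods, ML fitting, and ancestral posteriors.

Alignments are encoded as tip partial-likelihood tensors over either the
61 sense codons or the 20 amino acids.  Gaps and 'N'/'X' are fully
missing; other IUPAC ambiguity codes expand to their compatible state
sets; a determined stop codon inside a codon alignment is treated as
missing (stop codons are outside the model's state space).  Site patterns
are compressed before any likelihood work, and per-pattern scaling keeps
partial likelihoods in range on deep trees.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .genetics import (
    CODON_INDEX,
    IUPAC_DNA,
    IUPAC_PROTEIN,
    N_AA,
    N_CODONS,
    AMINO_ACIDS,
)
from .io import SequenceRecord
from .substmodels import AminoAcidModel, CodonModel, EigenQ
from .trees import RootedTree

# ---------------------------------------------------------------------------
# Alignment encoding
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """Pattern-compressed alignment with tip partial likelihoods.

    ``partials`` has shape (n_taxa, n_patterns, n_states); ``weights`` the
    pattern multiplicities; ``pattern_of_site`` maps alignment columns
    (codon or residue sites) to pattern indices.
    """

    taxa: list[str]
    kind: str  # "codon" | "aa"
    partials: np.ndarray
    weights: np.ndarray
    pattern_of_site: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.pattern_of_site)

    @property
    def n_patterns(self) -> int:
        return self.partials.shape[1]

    @property
    def n_states(self) -> int:
        return self.partials.shape[2]

    def taxon_row(self, name: str) -> int:
        try:
            return self.taxa.index(name)
        except ValueError:
            raise KeyError(f"taxon {name!r} not in alignment") from None

    def subset(self, taxa: list[str]) -> "Alignment":
        rows = [self.taxon_row(t) for t in taxa]
        return _compress(list(taxa), self.kind, self._site_partials()[rows])

    def _site_partials(self) -> np.ndarray:
        return self.partials[:, self.pattern_of_site, :]


def _compress(taxa: list[str], kind: str, site_partials: np.ndarray) -> Alignment:
    """site_partials: (n_taxa, n_sites, S) -> pattern-compressed Alignment."""
    n_taxa, n_sites, s = site_partials.shape
    flat = np.ascontiguousarray(
        site_partials.transpose(1, 0, 2).reshape(n_sites, n_taxa * s)
    ).astype(np.uint8)
    patterns, inverse, counts = np.unique(
        flat, axis=0, return_inverse=True, return_counts=True
    )
    partials = (
        patterns.reshape(-1, n_taxa, s).transpose(1, 0, 2).astype(np.float64)
    )
    return Alignment(
        taxa=list(taxa),
        kind=kind,
        partials=np.ascontiguousarray(partials),
        weights=counts.astype(np.float64),
        pattern_of_site=inverse.astype(np.intp),
    )


def _codon_site_partial(codon: str) -> np.ndarray:
    sets = []
    for ch in codon:
        comp = IUPAC_DNA.get(ch)
        if comp is None:
            raise ValueError(f"unexpected nucleotide {ch!r}")
        sets.append(comp)
    vec = np.zeros(N_CODONS)
    for c in itertools.product(*sets):
        idx = CODON_INDEX.get("".join(c))
        if idx is not None:
            vec[idx] = 1.0
    if vec.sum() == 0:  # determined stop codon: outside state space
        vec[:] = 1.0
    return vec


def encode_codon_alignment(records: list[SequenceRecord]) -> Alignment:
    """Encode an in-frame codon alignment (all sequences equal length, %3==0)."""
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must all have equal length")
    (length,) = lengths
    if length % 3 != 0:
        raise ValueError("codon alignment length must be a multiple of 3")
    n_sites = length // 3
    cache: dict[str, np.ndarray] = {}
    site_partials = np.empty((len(records), n_sites, N_CODONS))
    for ti, rec in enumerate(records):
        seq = rec.seq.upper().replace("U", "T")
        for si in range(n_sites):
            codon = seq[3 * si : 3 * si + 3]
            if codon not in cache:
                cache[codon] = _codon_site_partial(codon)
            site_partials[ti, si] = cache[codon]
    return _compress([r.id for r in records], "codon", site_partials)


def encode_protein_alignment(records: list[SequenceRecord]) -> Alignment:
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError("alignment sequences must all have equal length")
    site_partials = np.empty((len(records), lengths.pop(), N_AA))
    for ti, rec in enumerate(records):
        for si, ch in enumerate(rec.seq.upper()):
            comp = IUPAC_PROTEIN.get(ch)
            if comp is None:
                raise ValueError(f"unexpected residue {ch!r} in {rec.id}")
            vec = np.zeros(N_AA)
            for a in comp:
                vec[AMINO_ACIDS.index(a)] = 1.0
            site_partials[ti, si] = vec
    return _compress([r.id for r in records], "aa", site_partials)


def translate_records(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Codon-wise translation of an aligned CDS set to protein records."""
    from .genetics import translate_codon

    out = []
    for rec in records:
        seq = rec.seq.upper().replace("U", "T")
        aas = [translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - len(seq) % 3, 3)]
        out.append(SequenceRecord(rec.id, "".join("X" if a == "*" else a for a in aas)))
    return out


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------


def _check_taxa(align: Alignment, tree: RootedTree) -> None:
    tree_tips = set(tree.tip_names())
    for t in align.taxa:
        if t not in tree_tips:
            raise KeyError(f"alignment taxon {t!r} is absent from the tree")


def match_tree(align: Alignment, tree: RootedTree) -> RootedTree:
    """Prune the tree to the alignment's taxa (error for unknown taxa)."""
    _check_taxa(align, tree)
    return tree.prune_to(align.taxa)


def branch_pmats(
    tree: RootedTree, eig_of_branch, lengths: dict[int, float] | None = None
) -> dict[int, np.ndarray]:
    """Transition matrix for every branch.

    ``eig_of_branch`` is an :class:`EigenQ` shared by all branches, or a
    callable ``node_index -> EigenQ``.  Branches sharing an EigenQ are
    batched through a single vectorized exponential.
    """
    nodes = tree.branch_nodes()
    if isinstance(eig_of_branch, EigenQ):
        groups: dict[int, tuple[EigenQ, list[int]]] = {
            id(eig_of_branch): (eig_of_branch, nodes)
        }
    else:
        groups = {}
        for i in nodes:
            eig = eig_of_branch(i)
            groups.setdefault(id(eig), (eig, []))[1].append(i)
    pmats: dict[int, np.ndarray] = {}
    for eig, members in groups.values():
        ts = np.array(
            [
                tree.nodes[i].length if lengths is None else lengths[i]
                for i in members
            ]
        )
        mats = eig.transition_matrices(ts)
        for i, m in zip(members, mats):
            pmats[i] = m
    return pmats


def pattern_logliks(
    align: Alignment,
    tree: RootedTree,
    pmats: dict[int, np.ndarray],
    root_freqs: np.ndarray,
) -> np.ndarray:
    """Per-pattern log-likelihoods by Felsenstein pruning with scaling."""
    tip_row = {name: align.taxon_row(name) for name in tree.tip_names()}
    up: dict[int, np.ndarray] = {}
    scale = np.zeros(align.n_patterns)
    for i in tree.postorder():
        node = tree.nodes[i]
        if node.is_tip:
            up[i] = align.partials[tip_row[node.name]]
            continue
        partial = None
        for c in node.children:
            contrib = up[c] @ pmats[c].T
            partial = contrib if partial is None else partial * contrib
            del up[c]
        mx = partial.max(axis=1)
        mx[mx == 0] = 1.0
        partial /= mx[:, None]
        scale += np.log(mx)
        up[i] = partial
    lik = up[tree.root] @ root_freqs
    return np.log(lik) + scale


def log_likelihood(
    align: Alignment, tree: RootedTree, model: AminoAcidModel | CodonModel
) -> tuple[float, np.ndarray]:
    """Total and per-site log-likelihood under a single reversible model.

    The tree is pruned to the alignment's taxa first; branch lengths are
    taken from the tree.
    """
    t = match_tree(align, tree)
    freqs = model.freqs if isinstance(model, AminoAcidModel) else model.codon_freqs
    pat = pattern_logliks(align, t, branch_pmats(t, model.eig), freqs)
    per_site = pat[align.pattern_of_site]
    return float(pat @ align.weights), per_site


# ---------------------------------------------------------------------------
# Ancestral posteriors
# ---------------------------------------------------------------------------


def _up_partials(
    align: Alignment, tree: RootedTree, pmats: dict[int, np.ndarray]
) -> dict[int, np.ndarray]:
    """Per-node upward partials, renormalized per pattern (constants cancel
    in posterior ratios)."""
    tip_row = {name: align.taxon_row(name) for name in tree.tip_names()}
    up: dict[int, np.ndarray] = {}
    for i in tree.postorder():
        node = tree.nodes[i]
        if node.is_tip:
            up[i] = align.partials[tip_row[node.name]].copy()
            continue
        partial = None
        for c in node.children:
            contrib = up[c] @ pmats[c].T
            partial = contrib if partial is None else partial * contrib
        mx = partial.max(axis=1)
        mx[mx == 0] = 1.0
        up[i] = partial / mx[:, None]
    return up


def _outside_arrays(
    tree: RootedTree,
    up: dict[int, np.ndarray],
    pmats: dict[int, np.ndarray],
    root_freqs: np.ndarray,
    n_patterns: int,
) -> dict[int, np.ndarray]:
    """R[v](a) proportional to P(data outside subtree(v) AND state a at v),
    including the root prior; renormalized per pattern."""
    r: dict[int, np.ndarray] = {
        tree.root: np.broadcast_to(root_freqs, (n_patterns, len(root_freqs))).copy()
    }
    edge_down = {v: up[v] @ pmats[v].T for v in tree.branch_nodes()}
    for u in tree.preorder():
        node = tree.nodes[u]
        for v in node.children:
            out = r[u].copy()
            for s in node.children:
                if s != v:
                    out *= edge_down[s]
            rv = out @ pmats[v]
            mx = rv.max(axis=1)
            mx[mx == 0] = 1.0
            r[v] = rv / mx[:, None]
    return r


def marginal_ancestral_posteriors(
    align: Alignment,
    tree: RootedTree,
    pmats: dict[int, np.ndarray],
    root_freqs: np.ndarray,
) -> dict[int, np.ndarray]:
    """Per-site state posteriors for every node: dict node -> (n_sites, S).

    Tips with an observed unambiguous state get a point mass; internal
    nodes get the marginal posterior from the inside-outside pass.  Warns
    when the transition matrices are all (near-)identity while the data
    vary — usually a sign the tree's branch lengths were never fitted.
    """
    s = align.n_states
    if align.n_patterns > 1 and all(
        np.allclose(p, np.eye(s), atol=1e-12) for p in pmats.values()
    ):
        warnings.warn(
            "all branch lengths are ~0 but the alignment is variable; "
            "fit branch lengths before reconstructing ancestral states",
            stacklevel=2,
        )
    up = _up_partials(align, tree, pmats)
    r = _outside_arrays(tree, up, pmats, root_freqs, align.n_patterns)
    out: dict[int, np.ndarray] = {}
    for i in range(len(tree.nodes)):
        post = r[i] * up[i]
        total = post.sum(axis=1, keepdims=True)
        total[total == 0] = 1.0
        post = post / total
        out[i] = post[align.pattern_of_site]
    return out


def branch_joint_posterior(
    align: Alignment,
    tree: RootedTree,
    pmats: dict[int, np.ndarray],
    root_freqs: np.ndarray,
    branch: int,
) -> np.ndarray:
    """Per-site joint posterior of (parent state, child state) on a branch.

    Returns shape (n_sites, S, S) with J[site].sum() == 1.
    """
    if branch == tree.root or branch >= len(tree.nodes):
        raise KeyError(f"unknown branch {branch}")
    up = _up_partials(align, tree, pmats)
    r = _outside_arrays(tree, up, pmats, root_freqs, align.n_patterns)
    u = tree.nodes[branch].parent
    # outside-of-branch contribution at the parent: R[u] times siblings
    out_u = r[u].copy()
    for s in tree.nodes[u].children:
        if s != branch:
            out_u *= up[s] @ pmats[s].T
    j = out_u[:, :, None] * pmats[branch][None, :, :] * up[branch][:, None, :]
    total = j.sum(axis=(1, 2), keepdims=True)
    total[total == 0] = 1.0
    j = j / total
    return j[align.pattern_of_site]


def _lnl_and_length_grad(
    align: Alignment,
    tree: RootedTree,
    eig: "EigenQ",
    lengths: dict[int, float],
    root_freqs: np.ndarray,
) -> tuple[float, dict[int, float]]:
    """Log-likelihood and its exact gradient w.r.t. every branch length.

    Uses the inside-outside identity d lnL/d t_v = sum_sites
    (O_v' (Q P_v) U_v) / (O_v' P_v U_v) with O_v the outside vector at the
    parent of v excluding v's subtree; per-pattern normalisations cancel
    in the ratio.
    """
    pmats = branch_pmats(tree, eig, lengths)
    pat_lnl = pattern_logliks(align, tree, pmats, root_freqs)
    lnl = float(pat_lnl @ align.weights)
    up = _up_partials(align, tree, pmats)
    edge_down = {v: up[v] @ pmats[v].T for v in tree.branch_nodes()}
    q = eig.q
    r: dict[int, np.ndarray] = {
        tree.root: np.broadcast_to(
            root_freqs, (align.n_patterns, len(root_freqs))
        ).copy()
    }
    grads: dict[int, float] = {}
    w = align.weights
    for u in tree.preorder():
        children = tree.nodes[u].children
        for v in children:
            o = r[u].copy()
            for s in children:
                if s != v:
                    o *= edge_down[s]
            den = np.einsum("pa,pa->p", o, edge_down[v])
            num = np.einsum("pa,pa->p", o, up[v] @ (q @ pmats[v]).T)
            grads[v] = float(np.dot(num / den, w))
            rv = o @ pmats[v]
            mx = rv.max(axis=1)
            mx[mx == 0] = 1.0
            r[v] = rv / mx[:, None]
    return lnl, grads


# ---------------------------------------------------------------------------
# ML fitting
# ---------------------------------------------------------------------------

_MIN_T, _MAX_T = 1e-8, 30.0
_LOG_BOUNDS_T = (np.log(_MIN_T), np.log(_MAX_T))


@dataclass
class FitResult:
    """A maximum-likelihood fit: updated tree/model, lnL, diagnostics."""

    tree: RootedTree
    model: object
    lnl: float
    converged: bool
    n_evaluations: int
    params: dict

    def __repr__(self) -> str:  # keep tracebacks readable
        return (
            f"FitResult(lnl={self.lnl:.4f}, converged={self.converged}, "
            f"params={ {k: v for k, v in self.params.items() if k != 'lengths'} })"
        )


def _maximize(objective, x0_list, bounds, maxiter=500, jac=None):
    """Run bounded L-BFGS-B from each start; return the best result.

    Deterministic given the starts list.  Non-convergence of every start is
    reported through the returned flag rather than raised.
    """
    best = None
    n_eval = 0
    for x0 in x0_list:
        res = minimize(
            objective,
            np.asarray(x0, dtype=float),
            method="L-BFGS-B",
            bounds=bounds,
            jac=jac,
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": 1e-7},
        )
        n_eval += res.nfev
        if best is None or res.fun < best.fun:
            best = res
    return best, n_eval


def fit_branch_lengths(
    align: Alignment,
    tree: RootedTree,
    model: AminoAcidModel | CodonModel,
    start_length: float = 0.1,
) -> FitResult:
    """ML branch lengths under a fixed single-class model.

    L-BFGS-B on log-lengths with the exact inside-outside gradient; the
    input tree's lengths (when present) and a flat start are both tried.
    """
    t = match_tree(align, tree)
    nodes = t.branch_nodes()
    freqs = model.freqs if isinstance(model, AminoAcidModel) else model.codon_freqs
    eig = model.eig

    def objective(x):
        ts = np.exp(x)
        lengths = {i: v for i, v in zip(nodes, ts)}
        lnl, grads = _lnl_and_length_grad(align, t, eig, lengths, freqs)
        g = -np.array([grads[i] for i in nodes]) * ts
        return -lnl, g

    flat = np.full(len(nodes), np.log(start_length))
    current = np.array(
        [np.clip(t.nodes[i].length, _MIN_T, _MAX_T) for i in nodes]
    )
    starts = [np.log(current)] if np.any(current > _MIN_T * 2) else [flat]
    bounds = [_LOG_BOUNDS_T] * len(nodes)
    best, n_eval = _maximize(objective, starts, bounds, jac=True)
    if not best.success and not np.array_equal(starts[0], flat):
        alt, n2 = _maximize(objective, [flat], bounds, jac=True)
        n_eval += n2
        if alt.fun < best.fun:
            best = alt
    fitted = t.with_branch_lengths(
        {i: v for i, v in zip(nodes, np.exp(best.x))}
    )
    return FitResult(
        tree=fitted,
        model=model,
        lnl=-best.fun,
        converged=bool(best.success),
        n_evaluations=n_eval,
        params={"lengths": dict(zip(nodes, np.exp(best.x)))},
    )


def fit_m0(
    align: Alignment,
    tree: RootedTree,
    codon_freqs: np.ndarray | None = None,
    starts: list[dict] | None = None,
) -> FitResult:
    """One-ratio (M0) codon model: joint ML of branch lengths, kappa, omega.

    The fitted rate matrix is scaled to one expected substitution per codon
    so branch lengths are in expected codon substitutions.
    """
    t = match_tree(align, tree)
    nodes = t.branch_nodes()
    if codon_freqs is None:
        raise ValueError("codon_freqs required (e.g. f3x4 from the alignment)")
    if starts is None:
        starts = [
            {"kappa": 2.0, "omega": 0.4, "length": 0.1},
            {"kappa": 4.0, "omega": 0.1, "length": 0.3},
        ]

    from .substmodels import codon_rate_matrix, expected_rate

    def make_eig(kappa: float, omega: float) -> EigenQ:
        q = codon_rate_matrix(kappa, omega, codon_freqs)
        return EigenQ(q / expected_rate(q, codon_freqs), codon_freqs)

    def plain_lnl(lmap, kappa, omega):
        pm = branch_pmats(t, make_eig(kappa, omega), lmap)
        return float(pattern_logliks(align, t, pm, codon_freqs) @ align.weights)

    def objective(x):
        # analytic gradient for lengths, forward differences for kappa/omega
        ts = np.exp(x[: len(nodes)])
        kappa, omega = float(np.exp(x[-2])), float(np.exp(x[-1]))
        lmap = {i: v for i, v in zip(nodes, ts)}
        lnl, grads = _lnl_and_length_grad(
            align, t, make_eig(kappa, omega), lmap, codon_freqs
        )
        g = np.empty_like(x)
        g[: len(nodes)] = -np.array([grads[i] for i in nodes]) * ts
        h = 1e-5
        g[-2] = -(plain_lnl(lmap, kappa * (1 + h), omega) - lnl) / (h * kappa) * kappa
        g[-1] = -(plain_lnl(lmap, kappa, omega * (1 + h)) - lnl) / (h * omega) * omega
        return -lnl, g

    x0s = [
        np.concatenate(
            [
                np.full(len(nodes), np.log(s["length"])),
                [np.log(s["kappa"]), np.log(s["omega"])],
            ]
        )
        for s in starts
    ]
    bounds = [_LOG_BOUNDS_T] * len(nodes) + [
        (np.log(0.05), np.log(50.0)),
        (np.log(1e-4), np.log(50.0)),
    ]
    best, n_eval = _maximize(objective, x0s[:1], bounds, jac=True)
    if not best.success and len(x0s) > 1:  # fall back to the other starts
        alt, n2 = _maximize(objective, x0s[1:], bounds, jac=True)
        n_eval += n2
        if alt.fun < best.fun:
            best = alt
    kappa, omega = float(np.exp(best.x[-2])), float(np.exp(best.x[-1]))
    lengths = {i: float(v) for i, v in zip(nodes, np.exp(best.x[: len(nodes)]))}
    fitted_tree = t.with_branch_lengths(lengths)
    from .substmodels import codon_rate_matrix as _crm

    q = _crm(kappa, omega, codon_freqs)
    scale = expected_rate(q, codon_freqs)
    model = CodonModel(kappa=kappa, omega=omega, codon_freqs=codon_freqs, scale=scale)
    return FitResult(
        tree=fitted_tree,
        model=model,
        lnl=-best.fun,
        converged=bool(best.success),
        n_evaluations=n_eval,
        params={"kappa": kappa, "omega": omega, "lengths": lengths},
    )


def fit_parameters(
    align: Alignment,
    tree: RootedTree,
    model: AminoAcidModel | CodonModel,
    free: set[str] = frozenset({"branch_lengths"}),
    starts: list[dict] | None = None,
) -> FitResult:
    """Generic ML fit dispatcher.

    ``free`` may contain ``branch_lengths``, ``kappa`` and ``omega``; amino
    acid models support branch lengths only.  The optimum is deterministic
    given the starts list; lnL at the optimum is >= lnL at every start.
    """
    free = set(free)
    if isinstance(model, AminoAcidModel):
        if free - {"branch_lengths"}:
            raise ValueError("amino-acid models only fit branch lengths")
        return fit_branch_lengths(align, tree, model)
    if free == {"branch_lengths"}:
        return fit_branch_lengths(align, tree, model)
    if free == {"branch_lengths", "kappa", "omega"}:
        sdicts = None
        if starts is not None:
            sdicts = [
                {
                    "kappa": s.get("kappa", 2.0),
                    "omega": s.get("omega", 0.4),
                    "length": s.get("length", 0.1),
                }
                for s in starts
            ]
        return fit_m0(align, tree, codon_freqs=model.codon_freqs, starts=sdicts)
    raise ValueError(f"unsupported free-parameter set {sorted(free)}")
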