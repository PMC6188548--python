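"""Independent brute-force oracles used by the test suite.

Deliberately written without the package's pruning or eigendecomposition
machinery: transition matrices come from ``scipy.linalg.expm`` and all
likelihoods/posteriors from the full joint tensor over state assignments
of the internal nodes (plus any tips whose states are explicitly exposed
as tensor axes).  Feasible only for small trees, which is the point.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from convsel.trees import RootedTree


def expm_pmats(tree: RootedTree, q: np.ndarray) -> dict[int, np.ndarray]:
    return {i: expm(q * tree.nodes[i].length) for i in tree.branch_nodes()}


def joint_tensor(
    tree: RootedTree,
    tip_partials: dict[str, np.ndarray],
    pmats: dict[int, np.ndarray],
    root_freqs: np.ndarray,
    expose_tips: tuple[int, ...] = (),
) -> tuple[np.ndarray, dict[int, int]]:
    """Joint P(data, states of axis nodes) over internal nodes and any
    exposed tips.  Returns (tensor, axis_of_node)."""
    s = len(root_freqs)
    axis_nodes = [i for i in tree.postorder() if tree.nodes[i].children]
    axis_nodes += [i for i in expose_tips if not tree.nodes[i].children]
    axis = {node: k for k, node in enumerate(axis_nodes)}
    n_ax = len(axis_nodes)
    shape = [s] * n_ax
    tensor = np.ones(shape)

    def bcast_vec(vec: np.ndarray, ax: int) -> np.ndarray:
        sh = [1] * n_ax
        sh[ax] = s
        return vec.reshape(sh)

    def bcast_mat(mat: np.ndarray, ax_row: int, ax_col: int) -> np.ndarray:
        sh = [1] * n_ax
        sh[ax_row] = s
        sh[ax_col] = s
        if ax_row < ax_col:
            return mat.reshape(sh)
        return mat.T.reshape(sh)

    tensor = tensor * bcast_vec(root_freqs, axis[tree.root])
    for i in tree.branch_nodes():
        node = tree.nodes[i]
        p = pmats[i]
        if i in axis:
            tensor = tensor * bcast_mat(p, axis[node.parent], axis[i])
            if not node.children:  # exposed tip: its own data
                tensor = tensor * bcast_vec(tip_partials[node.name], axis[i])
        else:  # unexposed tip: sum its state against the partial
            tensor = tensor * bcast_vec(
                p @ tip_partials[node.name], axis[node.parent]
            )
    return tensor, axis


def enum_site_likelihood(tree, tip_partials, pmats, root_freqs) -> float:
    tensor, _ = joint_tensor(tree, tip_partials, pmats, root_freqs)
    return float(tensor.sum())


def enum_marginal_posterior(tree, tip_partials, pmats, root_freqs, node):
    expose = (node,) if not tree.nodes[node].children else ()
    tensor, axis = joint_tensor(tree, tip_partials, pmats, root_freqs, expose)
    axes = tuple(a for n, a in axis.items() if n != node)
    marg = tensor.sum(axis=axes)
    return marg / marg.sum()


def enum_branch_joint(tree, tip_partials, pmats, root_freqs, branch):
    """Joint posterior over (parent state, child state) of one branch."""
    node = tree.nodes[branch]
    expose = (branch,) if not node.children else ()
    tensor, axis = joint_tensor(tree, tip_partials, pmats, root_freqs, expose)
    keep = {node.parent, branch}
    axes = tuple(a for n, a in axis.items() if n not in keep)
    j = tensor.sum(axis=axes)
    if axis[node.parent] > axis[branch]:
        j = j.T
    return j / j.sum()


def enum_pair_joint4(tree, tip_partials, pmats, root_freqs, b1, b2):
    """Exact joint posterior over (parent1, child1, parent2, child2).

    Requires the four nodes to be distinct except possibly parent1 ==
    parent2 (sibling branches), in which case the shared-parent diagonal
    is embedded.
    """
    s = len(root_freqs)
    n1, n2 = tree.nodes[b1], tree.nodes[b2]
    expose = tuple(b for b in (b1, b2) if not tree.nodes[b].children)
    tensor, axis = joint_tensor(tree, tip_partials, pmats, root_freqs, expose)
    p1, p2 = n1.parent, n2.parent
    keep_nodes = [p1, b1, p2, b2]
    distinct = list(dict.fromkeys(keep_nodes))
    axes = tuple(a for n, a in axis.items() if n not in set(distinct))
    marg = tensor.sum(axis=axes, keepdims=False)
    # current axis order of `marg` follows sorted original axis ids
    remaining = sorted(axis[n] for n in distinct)
    pos = {n: remaining.index(axis[n]) for n in distinct}
    if len(distinct) == 4:
        j = np.transpose(marg, (pos[p1], pos[b1], pos[p2], pos[b2]))
    else:  # shared parent
        m3 = np.transpose(marg, (pos[p1], pos[b1], pos[b2]))
        j = np.zeros((s, s, s, s))
        for a in range(s):
            j[a, :, a, :] = m3[a]
    return j / j.sum()


def enum_pair_pps(tree, tip_partials, pmats, root_freqs, b1, b2):
    """Exact parallel / convergent PPs from the four-endpoint joint."""
    j4 = enum_pair_joint4(tree, tip_partials, pmats, root_freqs, b1, b2)
    s = j4.shape[0]
    idx = np.arange(s)
    j4 = j4.copy()
    j4[idx, idx, :, :] = 0.0
    j4[:, :, idx, idx] = 0.0
    both = np.einsum("axbx->abx", j4)
    par = np.einsum("aax->", both)
    total = both.sum()
    return float(par), float(total - par)


def hypergeom_tail(k, n_big, k_big, n_draw) -> float:
    """Upper-tail hypergeometric by direct summation of the pmf."""
    from math import comb

    denom = comb(n_big, n_draw)
    total = 0.0
    for i in range(k, min(k_big, n_draw) + 1):
        if n_draw - i > n_big - k_big:
            continue
        total += comb(k_big, i) * comb(n_big - k_big, n_draw - i) / denom
    return total


def mc_intersection_tail(sizes, n, k_obs, n_draws, rng) -> float:
    """Monte-Carlo tail probability of the m-way intersection size."""
    hits = 0
    base = np.arange(n)
    for _ in range(n_draws):
        inter = set(rng.choice(base, size=sizes[0], replace=False))
        for sz in sizes[1:]:
            inter &= set(rng.choice(base, size=sz, replace=False))
        if len(inter) >= k_obs:
            hits += 1
    return hits / n_draws
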