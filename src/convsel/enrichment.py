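"""Gene-set statistics: GO enrichment and exact multi-set intersections.

Enrichment uses the one-sided (overrepresentation) Fisher exact test on a
gene-to-term annotation graph with the true-path rule applied, under three
algorithms: ``classic`` tests every term independently; ``elim`` walks the
DAG from the deepest terms upward and removes the genes of significant
terms from their ancestors before the ancestors are tested, decorrelating
nested terms; ``weight`` is a ratio-weighting variant of the same idea
that down-weights, rather than removes, genes explained by a more
significant child.

The multi-set intersection test gives the exact null distribution of the
size of an m-way intersection of fixed-size sets drawn uniformly and
independently from a finite background, by iterated hypergeometric
conditioning; the reported p-value is the upper tail at the observed
intersection, and fold enrichment is observed/expected with
expected = N * prod(n_i / N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "AnnotationGraph",
    "IntersectionTest",
    "fisher_exact_enrichment",
    "propagate_annotations",
    "go_enrichment",
    "multiset_intersection_test",
]


def fisher_exact_enrichment(
    k_in_study: int, study_size: int, k_in_background: int, background_size: int
) -> float:
    """One-sided Fisher (hypergeometric upper-tail) overrepresentation p.

    ``k_in_study`` of ``study_size`` study genes hit the term;
    ``k_in_background`` of ``background_size`` background genes do.
    """
    if not (
        0 <= k_in_study <= study_size <= background_size
        and k_in_study <= k_in_background <= background_size
        and (k_in_background - k_in_study)
        <= (background_size - study_size)
    ):
        raise ValueError("inconsistent counts for the 2x2 table")
    return float(
        hypergeom.sf(k_in_study - 1, background_size, k_in_background, study_size)
    )


class AnnotationGraph:
    """GO-style term DAG with gene annotations.

    Edges run child -> parent; terms may carry a domain tag (MF/CC/BP).
    ``annotations`` maps gene -> set of directly annotated terms.
    """

    def __init__(
        self,
        edges: list[tuple[str, str]],
        annotations: dict[str, set[str]],
        domains: dict[str, str] | None = None,
    ):
        g = nx.DiGraph()
        g.add_edges_from(edges)
        for terms in annotations.values():
            g.add_nodes_from(terms)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("term graph contains a cycle")
        self.dag = g
        self.annotations = {gene: set(terms) for gene, terms in annotations.items()}
        self.domains = dict(domains or {})
        unknown = {
            t for terms in annotations.values() for t in terms
        } - set(g.nodes)
        if unknown:
            raise ValueError(f"annotated terms missing from DAG: {sorted(unknown)}")

    @classmethod
    def from_tables(
        cls, annotation_df: pd.DataFrame, dag_df: pd.DataFrame
    ) -> "AnnotationGraph":
        """Build from (gene, term) and (child, parent[, domain]) TSV tables."""
        ann: dict[str, set[str]] = {}
        for gene, term in zip(annotation_df.iloc[:, 0], annotation_df.iloc[:, 1]):
            ann.setdefault(str(gene), set()).add(str(term))
        edges = list(zip(dag_df.iloc[:, 0].astype(str), dag_df.iloc[:, 1].astype(str)))
        domains = None
        if dag_df.shape[1] >= 3:
            domains = dict(zip(dag_df.iloc[:, 0].astype(str), dag_df.iloc[:, 2]))
        return cls(edges, ann, domains)

    def genes(self) -> set[str]:
        return set(self.annotations)

    def ancestors(self, term: str) -> set[str]:
        return set(nx.descendants(self.dag, term))  # edges point rootward

    def term_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {t: set() for t in self.dag.nodes}
        for gene, terms in self.annotations.items():
            for t in terms:
                out[t].add(gene)
        return out

    def depths(self) -> dict[str, int]:
        """Longest path length from each term down to a leaf-most descendant
        measured from the root side: larger depth = more specific term."""
        order = list(nx.topological_sort(self.dag.reverse(copy=False)))
        depth: dict[str, int] = {}
        for t in order:  # roots first (no outgoing parent edges in reverse)
            parents = list(self.dag.successors(t))
            depth[t] = 0 if not parents else 1 + max(depth[p] for p in parents)
        return depth


def propagate_annotations(graph: AnnotationGraph) -> AnnotationGraph:
    """True-path closure: each gene is annotated to all ancestors of its terms.

    Idempotent; set semantics make repeated application a no-op.
    """
    closure: dict[str, set[str]] = {}
    anc_cache: dict[str, set[str]] = {}
    for gene, terms in graph.annotations.items():
        full = set(terms)
        for t in terms:
            if t not in anc_cache:
                anc_cache[t] = graph.ancestors(t)
            full |= anc_cache[t]
        closure[gene] = full
    out = AnnotationGraph.__new__(AnnotationGraph)
    out.dag = graph.dag
    out.annotations = closure
    out.domains = graph.domains
    return out


def _fisher_counts(
    study: set[str], genes: set[str], background: set[str]
) -> tuple[int, int, int, int]:
    return (
        len(study & genes),
        len(study),
        len(genes & background),
        len(background),
    )


def go_enrichment(
    study: set[str],
    graph: AnnotationGraph,
    algorithm: str = "classic",
    cutoff: float = 0.05,
) -> pd.DataFrame:
    """Per-term overrepresentation p-values under classic, elim or weight.

    ``study`` must be a subset of the graph's annotated genes (the
    background universe).  Annotations are propagated (true-path rule)
    before testing.  Returns a DataFrame with one row per term.
    """
    study = set(study)
    prop = propagate_annotations(graph)
    background = prop.genes()
    if not study <= background:
        raise ValueError("study genes must be a subset of the annotated background")
    term_genes = prop.term_genes()
    terms = sorted(term_genes)
    if algorithm == "classic":
        pvals = {
            t: fisher_exact_enrichment(
                *_fisher_counts(study, term_genes[t], background)
            )
            for t in terms
        }
    elif algorithm == "elim":
        pvals = _elim(study, prop, term_genes, background, cutoff)
    elif algorithm == "weight":
        pvals = _weight(study, prop, term_genes, background)
    else:
        raise ValueError(f"unknown enrichment algorithm {algorithm!r}")
    rows = []
    for t in terms:
        genes = term_genes[t]
        rows.append(
            {
                "term": t,
                "domain": prop.domains.get(t, ""),
                "n_study": len(study & genes),
                "n_background": len(genes),
                "expected": len(study) * len(genes) / max(len(background), 1),
                "p": pvals[t],
            }
        )
    return pd.DataFrame(rows)


def _elim(study, prop, term_genes, background, cutoff):
    depth = prop.depths()
    removed: dict[str, set[str]] = {t: set() for t in term_genes}
    pvals: dict[str, float] = {}
    for t in sorted(term_genes, key=lambda t: (-depth[t], t)):
        genes = term_genes[t] - removed[t]
        pvals[t] = fisher_exact_enrichment(
            *_fisher_counts(study, genes, background)
        )
        if pvals[t] < cutoff:
            for anc in prop.ancestors(t):
                removed[anc] |= genes
    return pvals


def _weight(study, prop, term_genes, background):
    """Ratio-weighting enrichment (one bottom-up pass).

    Genes already explained by a more significant child are down-weighted
    in the parent by the ratio of log significances; weighted counts are
    rounded before the hypergeometric tail is evaluated.
    """

    def weighted_p(genes: set[str], weights: dict[str, float]) -> float:
        k = round(sum(weights.get(g, 1.0) for g in genes & study))
        m = round(sum(weights.get(g, 1.0) for g in genes))
        k = int(min(k, len(study)))
        m = int(max(min(m, len(background)), k))
        return fisher_exact_enrichment(k, len(study), m, len(background))

    depth = prop.depths()
    pvals: dict[str, float] = {}
    weights: dict[str, dict[str, float]] = {t: {} for t in term_genes}
    for t in sorted(term_genes, key=lambda t: (-depth[t], t)):
        w = weights[t]
        p = weighted_p(term_genes[t], w)
        for c in prop.dag.predecessors(t):  # children point to parents
            pc = pvals.get(c)
            if pc is None or pc >= p:
                continue
            ratio = np.log(max(pc, 1e-300)) / np.log(max(p, 1e-300)) if p < 1 else np.inf
            if not np.isfinite(ratio) or ratio <= 1:
                factor = max(pc, 1e-300) if p >= 1 else 1.0
            else:
                factor = 1.0 / ratio
            for g in term_genes[c]:
                w[g] = min(w.get(g, 1.0), factor)
        pvals[t] = weighted_p(term_genes[t], w)
        # pass accumulated weights one level up
        for parent in prop.dag.successors(t):
            pw = weights[parent]
            for g, v in w.items():
                pw[g] = min(pw.get(g, 1.0), v)
    return pvals


# ---------------------------------------------------------------------------
# Exact multi-set intersection test
# ---------------------------------------------------------------------------


@dataclass
class IntersectionTest:
    """Exact test of an observed m-way gene-set intersection."""

    set_sizes: tuple[int, ...]
    background_size: int
    observed: int
    expected: float = field(init=False)
    fold_enrichment: float = field(init=False)
    p_value: float = field(init=False)
    pmf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = self.background_size
        if any(s > n for s in self.set_sizes):
            raise ValueError("set size exceeds the background")
        if len(self.set_sizes) < 2:
            raise ValueError("need at least two sets")
        self.expected = n * float(np.prod([s / n for s in self.set_sizes]))
        self.pmf = _intersection_pmf(self.set_sizes, n)
        self.fold_enrichment = (
            self.observed / self.expected if self.expected > 0 else float("nan")
        )
        self.p_value = float(self.pmf[self.observed :].sum())


def _intersection_pmf(sizes: tuple[int, ...], n: int) -> np.ndarray:
    """Distribution of |S_1 ∩ ... ∩ S_m| for independent uniform draws of
    fixed-size subsets from a background of size n."""
    dist = np.zeros(sizes[0] + 1)
    dist[sizes[0]] = 1.0
    for size in sizes[1:]:
        cur_max = len(dist) - 1
        new = np.zeros(min(cur_max, size) + 1)
        for x in range(cur_max + 1):
            if dist[x] == 0:
                continue
            ks = np.arange(0, min(x, size) + 1)
            new[ks] += dist[x] * hypergeom.pmf(ks, n, x, size)
        dist = new
    return dist


def multiset_intersection_test(
    sets: list[set[str]], background: int | set[str]
) -> IntersectionTest:
    """Exact upper-tail test of the m-way intersection of gene sets.

    ``background`` is the universe size or the universe itself (in which
    case membership is validated).
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    if isinstance(background, int):
        n = background
    else:
        universe = set(background)
        for s in sets:
            extra = set(s) - universe
            if extra:
                raise ValueError(f"set members outside background: {sorted(extra)[:5]}")
        n = len(universe)
    observed = len(set.intersection(*[set(s) for s in sets]))
    return IntersectionTest(
        set_sizes=tuple(len(s) for s in sets),
        background_size=n,
        observed=observed,
    )
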