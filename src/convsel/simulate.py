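"""Synthetic data generation for the whole screen.

Everything the pipeline consumes can be simulated here: codon alignments
evolved on a 41-taxon mammal tree shaped like the study system (four
independently subterranean clades — golden moles, African mole-rats,
spalacids, and the star-nosed mole — embedded among their terrestrial
sister taxa and four terrestrial control lineages), with branch-site
selection on designated foreground branches, forced parallel/convergent
amino-acid substitutions on designated branch pairs, per-gene taxon
missingness, and synthetic GO universes with planted enrichment.

All generators are pure functions of their parameters and a seeded
``numpy.random.Generator``; regenerating with the same seed reproduces
the data byte for byte.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import AnnotationGraph, propagate_annotations
from .genetics import CODON_AA_INDEX, AMINO_ACIDS, N_CODONS, SENSE_CODONS
from .io import SequenceRecord, write_fasta
from .substmodels import (
    EigenQ,
    _codon_freqs_from_positions,
    codon_rate_matrix,
    expected_rate,
)
from .trees import RootedTree, parse_newick, write_newick

__all__ = [
    "ModelAParams",
    "SimulationSpec",
    "GeneSimulation",
    "study_tree",
    "balanced_tree",
    "simulate_gene",
    "inject_convergent_sites",
    "apply_missingness",
    "simulate_go_universe",
    "make_study_fixture",
    "FOCAL_CLADES",
    "CONTROL_CLADES",
    "SELECTION_RUNS",
]


# ---------------------------------------------------------------------------
# The study-shaped species tree
# ---------------------------------------------------------------------------

# Topology mirroring the mammal phylogeny used for subterranean screens:
# four focal subterranean clades (A golden moles, B African mole-rats,
# C spalacids, D star-nosed mole) and four terrestrial controls
# (E elephant+hyrax, F guinea pig, G mouse+rat, H common shrew).
STUDY_NEWICK = (
    "((((((Amblysomus,Chrysochloris)#A,Echinops),(Elephantulus,Orycteropus),"
    "(Loxodonta,Procavia)#E),(Dasypus,Choloepus))),"
    "((Homo,((Oryctolagus,Ictidomys),"
    "(((Heterocephalus,(Heliophobius,((Georychus,Bathyergus),"
    "(Cryptomys,(Fukomys_mechowii,(Fukomys_damarensis,Fukomys_micklemi))))))#B,"
    "(Cavia#F,(Chinchilla,Octodon))),"
    "(Jaculus,((Spalax,(Eospalax,(Rhizomys,Tachyoryctes)))#C,"
    "(Mesocricetus,Microtus,(Mus,Rattus)#G)))))),"
    "((Erinaceus,(Sorex#H,Condylura#D)),"
    "((Canis,Felis),(Equus,(Bos,Sus),Myotis)))));"
)

FOCAL_CLADES: dict[str, list[str]] = {
    "A": ["Amblysomus", "Chrysochloris"],
    "B": [
        "Heterocephalus", "Heliophobius", "Georychus", "Bathyergus",
        "Cryptomys", "Fukomys_mechowii", "Fukomys_damarensis",
        "Fukomys_micklemi",
    ],
    "C": ["Spalax", "Eospalax", "Rhizomys", "Tachyoryctes"],
    "D": ["Condylura"],
}

CONTROL_CLADES: dict[str, list[str]] = {
    "E": ["Loxodonta", "Procavia"],
    "F": ["Cavia"],
    "G": ["Mus", "Rattus"],
    "H": ["Sorex"],
}

#: per-lineage pruned data sets for selection runs: the focal clade, the
#: nonsubterranean sister taxa retained, and the designated outgroups
SELECTION_RUNS: dict[str, dict[str, list[str]]] = {
    "A": {
        "focal": FOCAL_CLADES["A"],
        "sisters": ["Echinops", "Elephantulus", "Orycteropus", "Dasypus", "Choloepus"],
        "outgroups": ["Dasypus", "Choloepus"],
    },
    "B": {
        "focal": FOCAL_CLADES["B"],
        "sisters": ["Cavia", "Chinchilla", "Octodon", "Oryctolagus", "Ictidomys"],
        "outgroups": ["Oryctolagus", "Ictidomys"],
    },
    "C": {
        "focal": FOCAL_CLADES["C"],
        "sisters": ["Mesocricetus", "Microtus", "Mus", "Rattus", "Jaculus"],
        "outgroups": ["Jaculus"],
    },
    "D": {
        "focal": FOCAL_CLADES["D"],
        "sisters": ["Sorex", "Erinaceus", "Canis", "Felis", "Equus", "Bos", "Sus", "Myotis"],
        "outgroups": ["Canis", "Felis", "Equus", "Bos", "Sus", "Myotis"],
    },
    "E": {
        "focal": CONTROL_CLADES["E"],
        "sisters": ["Echinops", "Elephantulus", "Orycteropus", "Amblysomus",
                     "Chrysochloris", "Dasypus", "Choloepus"],
        "outgroups": ["Dasypus", "Choloepus"],
    },
    "F": {
        "focal": CONTROL_CLADES["F"],
        "sisters": ["Chinchilla", "Octodon", "Heterocephalus", "Heliophobius",
                     "Oryctolagus", "Ictidomys"],
        "outgroups": ["Oryctolagus", "Ictidomys"],
    },
    "G": {
        "focal": CONTROL_CLADES["G"],
        "sisters": ["Mesocricetus", "Microtus", "Spalax", "Tachyoryctes", "Jaculus"],
        "outgroups": ["Jaculus"],
    },
    "H": {
        "focal": CONTROL_CLADES["H"],
        "sisters": ["Condylura", "Erinaceus", "Canis", "Felis", "Equus", "Bos",
                     "Sus", "Myotis"],
        "outgroups": ["Canis", "Felis", "Equus", "Bos", "Sus", "Myotis"],
    },
}


def study_tree(
    seed: int = 1,
    mean_length: float = 0.08,
    min_length: float = 0.005,
    max_length: float = 0.5,
) -> RootedTree:
    """The 41-taxon study tree with branch lengths drawn Exp(mean_length).

    The topology is fixed; lengths are reproducible per seed and clipped
    to a plausible mammalian range.
    """
    tree = parse_newick(STUDY_NEWICK)
    rng = np.random.default_rng(seed)
    for i in tree.branch_nodes():
        tree.nodes[i].length = float(
            np.clip(rng.exponential(mean_length), min_length, max_length)
        )
    return tree


def balanced_tree(
    n_tips: int = 8,
    branch_length: float = 0.15,
    foreground: str | None = "pair0",
    tag: str = "1",
) -> RootedTree:
    """A balanced binary tree of ``n_tips`` (power of two), equal lengths.

    ``foreground`` may be ``"pair0"`` (the stem branch of the first
    cherry), ``"tip0"`` (the first tip's terminal branch), or None.
    Useful for calibration experiments.
    """
    if n_tips & (n_tips - 1):
        raise ValueError("n_tips must be a power of two")
    names = [f"t{i}" for i in range(n_tips)]

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return names[lo]
        mid = (lo + hi) // 2
        return f"({build(lo, mid)},{build(mid, hi)})"

    newick = build(0, n_tips) + ";"
    tree = parse_newick(newick)
    for i in tree.branch_nodes():
        tree.nodes[i].length = branch_length
    if foreground == "pair0":
        tree.nodes[tree.mrca(["t0", "t1"])].tag = tag
    elif foreground == "tip0":
        tree.nodes[tree.tip_index()["t0"]].tag = tag
    elif foreground is not None:
        raise ValueError(f"unknown foreground spec {foreground!r}")
    return tree


# ---------------------------------------------------------------------------
# Codon simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelAParams:
    """Branch-site Model A parameters used for simulation."""

    p0: float = 0.7225
    p1: float = 0.1275
    omega0: float = 0.1
    omega2: float = 1.0

    @property
    def proportions(self) -> np.ndarray:
        tot = self.p0 + self.p1
        rest = max(1.0 - tot, 0.0)
        return np.array(
            [self.p0, self.p1, rest * self.p0 / tot, rest * self.p1 / tot]
        )

    @property
    def class_omegas(self) -> list[tuple[float, float]]:
        """(background, foreground) omega per class 0, 1, 2a, 2b."""
        return [
            (self.omega0, self.omega0),
            (1.0, 1.0),
            (self.omega0, self.omega2),
            (1.0, self.omega2),
        ]


def default_codon_freqs() -> np.ndarray:
    """Mildly AT/GC-skewed codon frequencies used by the simulator."""
    nt = np.array([0.22, 0.26, 0.29, 0.23])  # T C A G
    return _codon_freqs_from_positions(np.tile(nt, (3, 1)))


@dataclass
class GeneSimulation:
    """A simulated gene: tip sequences plus full ancestral truth."""

    gene: str
    tree: RootedTree
    node_states: dict[int, np.ndarray]  # node index -> per-site codon index
    site_classes: np.ndarray  # per-site class 0..3 (0 for single-class sims)
    params: ModelAParams | float
    foreground_tags: tuple[str, ...]
    injections: list[dict] = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.site_classes)

    def records(self) -> list[SequenceRecord]:
        out = []
        for i, node in enumerate(self.tree.nodes):
            if node.is_tip:
                states = self.node_states[i]
                seq = "".join(SENSE_CODONS[s] for s in states)
                out.append(SequenceRecord(node.name, seq))
        return out

    def true_class2_sites(self) -> list[int]:
        """1-based sites simulated in the selected classes (2a/2b)."""
        return [int(s) + 1 for s in np.nonzero(self.site_classes >= 2)[0]]


def _sample_markov(
    parent_states: np.ndarray, p: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample child states from transition matrix rows of the parents."""
    u = rng.random(len(parent_states))
    cum = np.cumsum(p, axis=1)
    child = (cum[parent_states] < u[:, None]).sum(axis=1)
    return np.minimum(child, p.shape[0] - 1)


class _SimEngine:
    """Caches per-(omega) eigendecompositions for one simulation setting."""

    def __init__(self, codon_freqs: np.ndarray, kappa: float, scale: float):
        self.freqs = codon_freqs
        self.kappa = kappa
        self.scale = scale
        self._cache: dict[float, EigenQ] = {}

    def eig(self, omega: float) -> EigenQ:
        if omega not in self._cache:
            q = codon_rate_matrix(self.kappa, omega, self.freqs) / self.scale
            self._cache[omega] = EigenQ(q, self.freqs)
        return self._cache[omega]


def _mixture_scale(
    params: ModelAParams | float, kappa: float, freqs: np.ndarray
) -> float:
    """Background mixture-averaged rate: the simulator's time unit, matching
    the convention used when fitting."""
    if isinstance(params, (int, float)):
        q = codon_rate_matrix(kappa, float(params), freqs)
        return expected_rate(q, freqs)
    rate = 0.0
    for prop, (bg, _) in zip(params.proportions, params.class_omegas):
        q = codon_rate_matrix(kappa, bg, freqs)
        rate += prop * expected_rate(q, freqs)
    return float(rate)


def simulate_gene(
    tree: RootedTree,
    n_codons: int,
    rng: np.random.Generator,
    params: ModelAParams | float = 0.2,
    foreground_tags: tuple[str, ...] = (),
    kappa: float = 2.5,
    codon_freqs: np.ndarray | None = None,
    gene: str = "gene",
) -> GeneSimulation:
    """Simulate one codon alignment on a tree.

    ``params`` is either a single omega (one-ratio simulation) or
    :class:`ModelAParams`; branches whose tag is in ``foreground_tags``
    use the foreground omega for site classes 2a/2b.  Root states are
    drawn from the stationary codon frequencies and evolved by the exact
    transition probabilities of each class's rate matrix.
    """
    freqs = default_codon_freqs() if codon_freqs is None else codon_freqs
    if isinstance(params, ModelAParams):
        props = params.proportions
        if abs(props.sum() - 1.0) > 1e-9 or np.any(props < 0):
            raise ValueError("invalid site-class mixture")
        site_classes = rng.choice(4, size=n_codons, p=props)
        class_omegas = params.class_omegas
    else:
        if params < 0:
            raise ValueError("omega must be >= 0")
        site_classes = np.zeros(n_codons, dtype=int)
        class_omegas = [(float(params), float(params))]
    engine = _SimEngine(freqs, kappa, _mixture_scale(params, kappa, freqs))

    node_states: dict[int, np.ndarray] = {
        tree.root: rng.choice(N_CODONS, size=n_codons, p=freqs)
    }
    for v in tree.preorder():
        if v == tree.root:
            continue
        node = tree.nodes[v]
        fg = node.tag in foreground_tags
        child = np.empty(n_codons, dtype=int)
        parent = node_states[node.parent]
        for k, (bg_w, fg_w) in enumerate(class_omegas):
            sites = np.nonzero(site_classes == k)[0]
            if sites.size == 0:
                continue
            omega = fg_w if fg else bg_w
            p = engine.eig(omega).transition_matrices(np.array([node.length]))[0]
            child[sites] = _sample_markov(parent[sites], p, rng)
        node_states[v] = child
    return GeneSimulation(
        gene=gene,
        tree=tree,
        node_states=node_states,
        site_classes=site_classes,
        params=params,
        foreground_tags=tuple(foreground_tags),
    )


def inject_convergent_sites(
    sim: GeneSimulation,
    branch_pair: tuple[int, int] | tuple[str, str],
    n_sites: int,
    mode: str = "parallel",
    rng: np.random.Generator | None = None,
) -> GeneSimulation:
    """Force the same derived amino acid onto both branches at chosen sites.

    At each chosen site the child nodes of both branches are set to a
    codon of a shared derived amino acid x (different from both parents'
    amino acids) and the subtrees below are re-simulated conditional on
    the forced state.  ``parallel`` requires the two parent nodes to share
    the same amino acid at the site, ``convergent`` requires them to
    differ; sites violating the constraint are skipped and resampled.
    Modifies ``sim`` in place (and returns it); injections are recorded in
    ``sim.injections``.
    """
    if mode not in {"parallel", "convergent"}:
        raise ValueError(f"unknown injection mode {mode!r}")
    if rng is None:
        raise ValueError("an explicit seeded rng is required")
    if n_sites == 0:
        return sim
    if n_sites > sim.n_sites:
        raise ValueError("cannot inject more sites than the gene has")
    tree = sim.tree
    b1, b2 = (
        tree.node_by_tag(b) if isinstance(b, str) else b for b in branch_pair
    )
    if b1 == b2 or tree.is_ancestor(b1, b2) or tree.is_ancestor(b2, b1):
        raise ValueError("branch pair must be distinct and non-nested")
    params = sim.params
    class_omegas = (
        params.class_omegas
        if isinstance(params, ModelAParams)
        else [(float(params), float(params))]
    )
    freqs = default_codon_freqs()
    engine = _SimEngine(freqs, 2.5, _mixture_scale(params, 2.5, freqs))
    aa_of = CODON_AA_INDEX

    p1, p2 = tree.nodes[b1].parent, tree.nodes[b2].parent
    candidates = rng.permutation(sim.n_sites)
    chosen: list[int] = []
    for site in candidates:
        a1 = aa_of[sim.node_states[p1][site]]
        a2 = aa_of[sim.node_states[p2][site]]
        ok = a1 == a2 if mode == "parallel" else a1 != a2
        if ok:
            chosen.append(int(site))
        if len(chosen) == n_sites:
            break
    if len(chosen) < n_sites:
        warnings.warn(
            f"only {len(chosen)} of {n_sites} sites satisfied the {mode} "
            "ancestral constraint; injecting those",
            stacklevel=2,
        )

    codons_of_aa = {
        a: np.nonzero(aa_of == a)[0] for a in range(len(AMINO_ACIDS))
    }
    for site in chosen:
        a1 = aa_of[sim.node_states[p1][site]]
        a2 = aa_of[sim.node_states[p2][site]]
        choices = [x for x in range(len(AMINO_ACIDS)) if x != a1 and x != a2]
        x = int(rng.choice(choices))
        for b in (b1, b2):
            codon = int(rng.choice(codons_of_aa[x]))
            sim.node_states[b][site] = codon
            _resimulate_subtree(sim, b, site, engine, class_omegas, rng)
        sim.injections.append(
            {
                "site": site + 1,
                "mode": mode,
                "aa": AMINO_ACIDS[x],
                "branch_1": b1,
                "branch_2": b2,
            }
        )
    return sim


def _resimulate_subtree(sim, top, site, engine, class_omegas, rng):
    """Re-draw states below ``top`` at one site, conditional on its state."""
    tree = sim.tree
    k = int(sim.site_classes[site])
    k = min(k, len(class_omegas) - 1)
    stack = list(tree.nodes[top].children)
    while stack:
        v = stack.pop()
        node = tree.nodes[v]
        fg = node.tag in sim.foreground_tags
        bg_w, fg_w = class_omegas[k]
        omega = fg_w if fg else bg_w
        p = engine.eig(omega).transition_matrices(np.array([node.length]))[0]
        parent_state = np.array([sim.node_states[node.parent][site]])
        sim.node_states[v][site] = _sample_markov(parent_state, p, rng)[0]
        stack.extend(node.children)


def apply_missingness(
    gene_records: dict[str, list[SequenceRecord]],
    dropout: float | dict[str, float],
    rng: np.random.Generator,
) -> dict[str, list[SequenceRecord]]:
    """Independently drop taxa from each gene with the given probability."""
    probs = [dropout] if isinstance(dropout, float) else list(dropout.values())
    if any(not 0 <= p < 1 for p in probs):
        raise ValueError("dropout probabilities must lie in [0, 1)")
    out: dict[str, list[SequenceRecord]] = {}
    for gene in sorted(gene_records):
        kept = []
        for rec in gene_records[gene]:
            p = dropout if isinstance(dropout, float) else dropout.get(rec.id, 0.0)
            if not 0 <= p < 1:
                raise ValueError("dropout probabilities must lie in [0, 1)")
            if rng.random() >= p:
                kept.append(rec)
        out[gene] = kept
    return out


# ---------------------------------------------------------------------------
# GO universe simulation
# ---------------------------------------------------------------------------


def simulate_go_universe(
    n_genes: int,
    n_terms: int,
    depth: int,
    rng: np.random.Generator,
    n_enriched: int = 2,
    odds_ratio: float = 5.0,
    study_size: int = 40,
    domain: str = "BP",
) -> tuple[AnnotationGraph, set[str], dict]:
    """A random single-root term DAG with planted study-set enrichment.

    Genes are annotated to leaf terms and propagated; the study set is a
    weighted draw without replacement in which genes of the enriched
    (leaf) terms have the given odds ratio.  Returns (graph, study,
    truth) where truth lists the enriched terms.
    """
    genes = [f"g{i:04d}" for i in range(n_genes)]
    terms = [f"T{i:03d}" for i in range(n_terms)]
    root = terms[0]
    levels: dict[str, int] = {root: 0}
    edges: list[tuple[str, str]] = []
    for t in terms[1:]:
        lvl = int(rng.integers(1, depth))
        levels[t] = lvl
        candidates = [u for u in terms if u in levels and levels[u] == lvl - 1 and u != t]
        if not candidates:
            candidates = [root]
        parents = rng.choice(
            candidates, size=min(len(candidates), int(rng.integers(1, 3))),
            replace=False,
        )
        for p in np.atleast_1d(parents):
            edges.append((t, str(p)))
    dag_children = {c for c, _ in edges}
    dag_parents = {p for _, p in edges}
    leaves = sorted((dag_children | {root}) - dag_parents)
    annotations: dict[str, set[str]] = {}
    for g in genes:
        k = int(rng.integers(1, 4))
        annotations[g] = {str(t) for t in rng.choice(leaves, size=k, replace=False)} \
            if k <= len(leaves) else set(leaves)
    graph = AnnotationGraph(edges, annotations, {t: domain for t in terms})
    prop = propagate_annotations(graph)
    term_genes = prop.term_genes()
    enriched = [
        str(t)
        for t in rng.choice(leaves, size=min(n_enriched, len(leaves)), replace=False)
    ]
    weights = np.ones(n_genes)
    for i, g in enumerate(genes):
        if any(g in term_genes[t] for t in enriched):
            weights[i] = odds_ratio
    # Efraimidis–Spirakis weighted sampling without replacement
    keys = rng.random(n_genes) ** (1.0 / weights)
    study = {genes[i] for i in np.argsort(-keys)[:study_size]}
    truth = {"enriched_terms": enriched, "odds_ratio": odds_ratio}
    return graph, study, truth


# ---------------------------------------------------------------------------
# Full study fixture
# ---------------------------------------------------------------------------


@dataclass
class SimulationSpec:
    """Conditions for the desk-scale analogue of the full study design."""

    n_genes: int = 200
    n_codons: int = 300
    seed: int = 1
    omega0: float = 0.1
    omega2: float = 4.0
    p0: float = 0.7225
    p1: float = 0.1275
    kappa: float = 2.5
    prop_selected: float = 0.10
    prop_injected: float = 0.05
    n_inject_sites: int = 5
    dropout: float = 0.08
    mean_branch_length: float = 0.08

    def null_params(self) -> ModelAParams:
        return ModelAParams(self.p0, self.p1, self.omega0, 1.0)

    def alt_params(self) -> ModelAParams:
        return ModelAParams(self.p0, self.p1, self.omega0, self.omega2)


def make_study_fixture(out_dir: str | Path, spec: SimulationSpec | None = None) -> dict:
    """Write a complete synthetic study to disk.

    Produces per-gene FASTA alignments on the 41-taxon tree, the tagged
    Newick tree, truth tables (selection and injections) and a JSON
    config; returns a manifest dict with the paths and truth frames.
    """
    spec = spec or SimulationSpec()
    out = Path(out_dir)
    (out / "genes").mkdir(parents=True, exist_ok=True)
    tree = study_tree(seed=spec.seed, mean_length=spec.mean_branch_length)
    rng = np.random.default_rng(spec.seed)
    focal_tags = list(FOCAL_CLADES)
    pair_cycle = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]

    n_selected = int(round(spec.n_genes * spec.prop_selected))
    n_injected = int(round(spec.n_genes * spec.prop_injected))
    sel_rows, inj_rows = [], []
    gene_records: dict[str, list[SequenceRecord]] = {}
    for gi in range(spec.n_genes):
        gene = f"gene{gi:04d}"
        if gi < n_selected:
            fg = focal_tags[gi % len(focal_tags)]
            params = spec.alt_params()
            tags = (fg,)
        else:
            fg = ""
            params = spec.null_params()
            tags = ()
        sim = simulate_gene(
            tree,
            spec.n_codons,
            rng,
            params=params,
            foreground_tags=tags,
            kappa=spec.kappa,
            gene=gene,
        )
        if gi < n_injected:
            pair = pair_cycle[gi % len(pair_cycle)]
            inject_convergent_sites(
                sim, pair, spec.n_inject_sites, mode="parallel", rng=rng
            )
            for rec in sim.injections:
                inj_rows.append(
                    {"gene": gene, "pair": "".join(pair), **{
                        k: v for k, v in rec.items() if k in ("site", "mode", "aa")
                    }}
                )
        sel_rows.append(
            {
                "gene": gene,
                "foreground": fg,
                "omega2": params.omega2 if isinstance(params, ModelAParams) else "",
                "class2_sites": ";".join(map(str, sim.true_class2_sites())),
            }
        )
        gene_records[gene] = sim.records()

    gene_records = apply_missingness(gene_records, spec.dropout, rng)
    for gene, records in gene_records.items():
        if records:
            write_fasta(records, out / "genes" / f"{gene}.fasta")
    with open(out / "tree.nwk", "w") as fh:
        fh.write(write_newick(tree) + "\n")
    truth_sel = pd.DataFrame(sel_rows)
    truth_inj = pd.DataFrame(
        inj_rows, columns=["gene", "pair", "site", "mode", "aa"]
    )
    truth_sel.to_csv(out / "truth_selection.tsv", sep="\t", index=False)
    truth_inj.to_csv(out / "truth_injections.tsv", sep="\t", index=False)
    config = {
        "spec": {k: getattr(spec, k) for k in spec.__dataclass_fields__},
        "focal_clades": FOCAL_CLADES,
        "control_clades": CONTROL_CLADES,
        "thresholds": {
            "alpha": 0.05, "summed_pp": [1.0, 2.0],
            "site_pp": 0.5, "median_interval": 10,
        },
    }
    with open(out / "config.json", "w") as fh:
        json.dump(config, fh, indent=1, sort_keys=True)
    return {
        "dir": out,
        "tree": tree,
        "genes": gene_records,
        "truth_selection": truth_sel,
        "truth_injections": truth_inj,
    }
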