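"""End-to-end screen orchestration.

Applies the deterministic alignment QC gates, prunes each gene to a
lineage's taxon set, runs the branch-site selection and pairwise
convergence scans over gene batches, intersects the resulting gene sets,
and maps the co-occurrence of positive selection and convergent
substitutions at gene and site level.  Per-gene numerical failures are
quarantined (logged with a reason) rather than aborting a batch.

QC order mirrors standard practice for transcriptome-derived CDS sets:
(1) sequences with more than 50% missing data are removed, (2) incomplete
final codons are padded with N, (3) sequences with internal stop codons
are removed, (4) sequences shorter than 150 nt are removed; at alignment
level, codon columns that are majority-gap are removed and only
alignments longer than 100 codons are kept.  A gene enters a lineage's
test only when at least one focal taxon and at least one outgroup are
present and the alignment has at least four taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .branchsite import BranchSiteModel, bh_fdr
from .convergence import ConvergencePairModel
from .enrichment import multiset_intersection_test
from .genetics import STOP_CODONS
from .io import SequenceRecord, read_fasta, write_table
from .likelihood import translate_records
from .trees import RootedTree

__all__ = [
    "QcReport",
    "qc_sequences",
    "qc_alignment",
    "taxon_gate",
    "prune_dataset",
    "run_selection_screen",
    "run_convergence_pair",
    "intersect_psgs",
    "cooccurrence_map",
    "run_control_comparison",
    "psg_set",
]


@dataclass
class QcReport:
    """Per-gene record of which QC rules fired."""

    removed_seq_missing: list[str] = field(default_factory=list)
    padded_codons: list[str] = field(default_factory=list)
    removed_internal_stop: list[str] = field(default_factory=list)
    removed_short_seq: list[str] = field(default_factory=list)
    removed_gap_columns: int = 0
    too_short_alignment: bool = False
    n_before: int = 0
    n_after: int = 0


def qc_sequences(
    records: list[SequenceRecord],
) -> tuple[list[SequenceRecord], QcReport]:
    """Sequence-level QC in fixed order: missing-data filter, codon
    padding, internal-stop filter, minimum-length filter."""
    report = QcReport(n_before=len(records))
    kept: list[SequenceRecord] = []
    for rec in records:
        seq = rec.seq.upper()
        ungapped = seq.replace("-", "")
        if ungapped and ungapped.count("N") / len(ungapped) > 0.5:
            report.removed_seq_missing.append(rec.id)
            continue
        if len(seq) % 3 != 0:
            seq = seq + "N" * (3 - len(seq) % 3)
            report.padded_codons.append(rec.id)
        has_internal_stop = any(
            seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq) - 3, 3)
        )
        if has_internal_stop:
            report.removed_internal_stop.append(rec.id)
            continue
        if len(seq.replace("-", "").replace("N", "")) < 150:
            report.removed_short_seq.append(rec.id)
            continue
        kept.append(SequenceRecord(rec.id, seq))
    report.n_after = len(kept)
    return kept, report


def qc_alignment(
    records: list[SequenceRecord],
) -> tuple[list[SequenceRecord], QcReport]:
    """Alignment-level QC: drop majority-gap codon columns, then short
    sequences; keep the alignment only if longer than 100 codons.

    Returns an empty record list when the alignment fails the length
    gate.  Idempotent.
    """
    report = QcReport(n_before=len(records))
    if not records:
        report.too_short_alignment = True
        return [], report
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1 or lengths.pop() % 3 != 0:
        raise ValueError("qc_alignment expects an in-frame codon alignment")
    arr = np.array([list(r.seq) for r in records])
    n_codons = arr.shape[1] // 3
    codon_view = arr.reshape(len(records), n_codons, 3)
    gapped = (codon_view == "-").any(axis=2)  # taxon x codon column
    keep_cols = gapped.mean(axis=0) <= 0.5
    report.removed_gap_columns = int((~keep_cols).sum())
    trimmed = codon_view[:, keep_cols, :].reshape(len(records), -1)
    kept: list[SequenceRecord] = []
    for rec, row in zip(records, trimmed):
        seq = "".join(row)
        if len(seq.replace("-", "").replace("N", "")) < 150:
            report.removed_short_seq.append(rec.id)
            continue
        kept.append(SequenceRecord(rec.id, seq))
    if not kept or len(kept[0].seq) // 3 <= 100:
        report.too_short_alignment = True
        report.n_after = 0
        return [], report
    report.n_after = len(kept)
    return kept, report


def taxon_gate(
    taxa: list[str], focal: list[str], outgroups: list[str]
) -> tuple[bool, str | None]:
    """Inclusion rules: >=1 outgroup, >=1 focal taxon, >=4 taxa in total."""
    present = set(taxa)
    if not present & set(outgroups):
        return False, "no_outgroup"
    if not present & set(focal):
        return False, "no_focal"
    if len(present) < 4:
        return False, "too_few_taxa"
    return True, None


def prune_dataset(
    records: list[SequenceRecord], tree: RootedTree, allowed_taxa: list[str]
) -> tuple[list[SequenceRecord], RootedTree]:
    """Restrict a gene to a lineage's taxon set and prune the tree to match."""
    allowed = set(allowed_taxa)
    kept = [r for r in records if r.id in allowed]
    taxa = [r.id for r in kept]
    pruned = tree.prune_to(taxa) if taxa else tree
    return kept, pruned


def _load_genes(genes) -> dict[str, list[SequenceRecord]]:
    if isinstance(genes, (str, Path)):
        gene_dir = Path(genes)
        return {
            p.stem: read_fasta(p, alphabet="dna")
            for p in sorted(gene_dir.glob("*.fasta"))
        }
    return dict(genes)


def run_selection_screen(
    genes,
    tree: RootedTree,
    lineage: str,
    focal: list[str],
    sisters: list[str],
    outgroups: list[str],
    eb_method: str = "BEB",
    alpha: float = 0.05,
    out_path: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Branch-site screen of one lineage over a gene batch.

    ``genes`` is a directory of FASTA files or a mapping gene -> records.
    Returns (results, exclusions); results carry one row per tested gene
    with BH-FDR-adjusted p-values appended, exclusions one row per gene
    that failed a QC or taxon gate (or was quarantined on error).
    Resumable: when ``out_path`` exists, completed genes are reused.
    """
    gene_records = _load_genes(genes)
    allowed = list(focal) + list(sisters)
    done: dict[str, dict] = {}
    if out_path is not None and Path(out_path).exists():
        prev = pd.read_csv(out_path, sep="\t", dtype={"pss_sites": str})
        prev["pss_sites"] = prev["pss_sites"].fillna("")
        done = {row["gene"]: dict(row) for _, row in prev.iterrows()}
    rows, excluded = [], []
    for gene in sorted(gene_records):
        if gene in done:
            rows.append(done[gene])
            continue
        try:
            recs, _ = qc_sequences(gene_records[gene])
            recs = prune_dataset(recs, tree, allowed)[0]
            recs, qc_rep = qc_alignment(recs)
            if qc_rep.too_short_alignment:
                excluded.append({"gene": gene, "reason": "too_short_alignment"})
                continue
            ok, reason = taxon_gate([r.id for r in recs], focal, outgroups)
            if not ok:
                excluded.append({"gene": gene, "reason": reason})
                continue
            pruned = tree.prune_to([r.id for r in recs])
            if not pruned.has_tag(lineage):
                excluded.append({"gene": gene, "reason": "no_focal"})
                continue
            res = BranchSiteModel(recs, pruned, foreground=lineage).fit(
                eb_method=eb_method, alpha=alpha
            )
            rows.append(res.to_row(gene))
        except Exception as err:  # per-gene quarantine
            excluded.append({"gene": gene, "reason": f"error:{err}"})
    results = pd.DataFrame(rows)
    if len(results):
        results = results.sort_values("gene").reset_index(drop=True)
        results["p_fdr"] = bh_fdr(results["p"].to_numpy())
    exclusions = pd.DataFrame(excluded, columns=["gene", "reason"])
    if out_path is not None and len(results):
        write_table(results, out_path)
    return results, exclusions


def psg_set(results: pd.DataFrame, alpha: float = 0.05) -> set[str]:
    """Positively selected genes: LRT p < alpha, omega2 > 1, and passing
    the clustered-PSS filter (nominal p, as in the screen's design)."""
    if not len(results):
        return set()
    mask = (
        (results["p"] < alpha)
        & (results["omega2"] > 1.0)
        & (results["filter_flag"] == "retain")
    )
    return set(results.loc[mask, "gene"])


def run_convergence_pair(
    genes,
    tree: RootedTree,
    clade_1: list[str],
    clade_2: list[str],
    pair_name: str = "",
    min_taxa: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise convergence scan over a gene batch.

    Returns (gene_table, site_table, exclusions); sites are 1-based
    positions in each gene's trimmed protein alignment.
    """
    gene_records = _load_genes(genes)
    gene_rows, site_rows, excluded = [], [], []
    for gene in sorted(gene_records):
        try:
            recs, _ = qc_sequences(gene_records[gene])
            recs, qc_rep = qc_alignment(recs)
            if qc_rep.too_short_alignment or len(recs) < min_taxa:
                excluded.append({"gene": gene, "reason": "qc"})
                continue
            taxa = {r.id for r in recs}
            if not taxa & set(clade_1) or not taxa & set(clade_2):
                excluded.append({"gene": gene, "reason": "clade_absent"})
                continue
            prot = translate_records(recs)
            res = ConvergencePairModel(
                prot, tree.prune_to([r.id for r in recs]), clade_1, clade_2
            ).fit(gene=gene)
            row = res.to_row(gene)
            row["pair"] = pair_name
            gene_rows.append(row)
            st = res.site_table(gene)
            st["pair"] = pair_name
            site_rows.append(st)
        except Exception as err:
            excluded.append({"gene": gene, "reason": f"error:{err}"})
    gene_table = pd.DataFrame(gene_rows)
    site_table = (
        pd.concat(site_rows, ignore_index=True) if site_rows else pd.DataFrame()
    )
    exclusions = pd.DataFrame(excluded, columns=["gene", "reason"])
    return gene_table, site_table, exclusions


def intersect_psgs(
    psg_sets: dict[str, set[str]], background: set[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed vs expected overlap of per-lineage PSG sets.

    Tests every combination of >= 2 lineages with the exact multi-set
    intersection test against the tested-gene background.  Returns the
    overlap table and a gene x lineage membership matrix.
    """
    from itertools import combinations

    if not background:
        raise ValueError("empty background universe")
    lineages = sorted(psg_sets)
    rows = []
    for m in range(2, len(lineages) + 1):
        for combo in combinations(lineages, m):
            sets = [psg_sets[c] & background for c in combo]
            test = multiset_intersection_test(sets, background)
            rows.append(
                {
                    "lineages": "+".join(combo),
                    "m": m,
                    "observed": test.observed,
                    "expected": test.expected,
                    "fold_enrichment": test.fold_enrichment,
                    "p": test.p_value,
                }
            )
    members = sorted(set().union(*psg_sets.values()) & background)
    matrix = pd.DataFrame(
        {lin: [g in psg_sets[lin] for g in members] for lin in lineages},
        index=pd.Index(members, name="gene"),
    )
    return pd.DataFrame(rows), matrix


def cooccurrence_map(
    selection_1: pd.DataFrame,
    selection_2: pd.DataFrame,
    convergence_genes: pd.DataFrame,
    convergence_sites: pd.DataFrame,
    summed_pp_threshold: float = 1.0,
    site_pp_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Join selection and convergence evidence for one lineage pair.

    Gene level: genes that are PSGs in *both* lineages and have summed
    convergence PP >= threshold.  Site level: sites that are a PSS in at
    least one lineage and convergent (PP > threshold), reported with
    per-lineage PSS presence (absence shown as missing, as in standard
    co-occurrence tables).  Raises on coordinate mismatch between the
    selection and convergence tables.
    """
    sel1 = selection_1.set_index("gene")
    sel2 = selection_2.set_index("gene")
    conv = convergence_genes.set_index("gene")
    common = sorted(set(sel1.index) & set(sel2.index) & set(conv.index))
    site_by_gene = (
        dict(tuple(convergence_sites.groupby("gene")))
        if len(convergence_sites)
        else {}
    )
    psg1, psg2 = psg_set(selection_1), psg_set(selection_2)
    gene_rows, site_rows = [], []
    for gene in common:
        n_codons_1 = int(sel1.loc[gene, "n_codons"])
        n_codons_2 = int(sel2.loc[gene, "n_codons"])
        gene_sites = site_by_gene.get(gene)
        n_aa = int(gene_sites["site"].max()) if gene_sites is not None else 0
        if gene_sites is not None and n_aa not in (n_codons_1, n_codons_2):
            raise ValueError(
                f"coordinate mismatch for {gene}: selection alignments have "
                f"{n_codons_1}/{n_codons_2} codons but convergence sites run "
                f"to {n_aa}"
            )
        in_both = gene in psg1 and gene in psg2
        flag_pp = float(conv.loc[gene, "summed_pp_total"]) >= summed_pp_threshold
        gene_rows.append(
            {
                "gene": gene,
                "psg_in_both": in_both,
                "summed_pp_flag": flag_pp,
                "cooccurrent": in_both and flag_pp,
            }
        )
        if gene_sites is None:
            continue
        pss_1 = _pss_site_set(sel1.loc[gene, "pss_sites"])
        pss_2 = _pss_site_set(sel2.loc[gene, "pss_sites"])
        conv_sites = gene_sites[gene_sites["pp_total"] > site_pp_threshold]
        for _, srow in conv_sites.iterrows():
            site = int(srow["site"])
            if site in pss_1 or site in pss_2:
                site_rows.append(
                    {
                        "gene": gene,
                        "site": site,
                        "pss_lineage1": site if site in pss_1 else pd.NA,
                        "pss_lineage2": site if site in pss_2 else pd.NA,
                        "pp_total": float(srow["pp_total"]),
                    }
                )
    gene_table = pd.DataFrame(
        gene_rows, columns=["gene", "psg_in_both", "summed_pp_flag", "cooccurrent"]
    )
    site_table = pd.DataFrame(
        site_rows,
        columns=["gene", "site", "pss_lineage1", "pss_lineage2", "pp_total"],
    )
    n_tested = len(common)
    proportions = {
        "n_tested": n_tested,
        "n_cooccurrent": int(gene_table["cooccurrent"].sum()) if n_tested else 0,
        "proportion_cooccurrent": (
            float(gene_table["cooccurrent"].mean()) if n_tested else float("nan")
        ),
    }
    return gene_table, site_table, proportions


def _pss_site_set(cell) -> set[int]:
    if isinstance(cell, float) and np.isnan(cell):
        return set()
    text = str(cell).strip()
    if not text or text == "nan":
        return set()
    return {int(s) for s in text.split(";") if s}


def run_control_comparison(
    genes,
    tree: RootedTree,
    runs: dict[str, dict[str, list[str]]],
    labels: dict[str, str] | None = None,
    eb_method: str = "NEB",
    alpha: float = 0.05,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Run the identical selection pipeline over several branch sets.

    ``runs`` maps branch tag -> {focal, sisters, outgroups}; ``labels``
    optionally tags each branch set (e.g. subterranean / nonsubterranean).
    Returns per-branch result tables and a one-row-per-branch summary.
    """
    labels = labels or {}
    tables: dict[str, pd.DataFrame] = {}
    summary_rows = []
    for tag in sorted(runs):
        cfg = runs[tag]
        results, exclusions = run_selection_screen(
            genes,
            tree,
            tag,
            cfg["focal"],
            cfg["sisters"],
            cfg["outgroups"],
            eb_method=eb_method,
            alpha=alpha,
        )
        tables[tag] = results
        psgs = psg_set(results, alpha)
        n_fdr = (
            int(
                (
                    (results["p_fdr"] < alpha)
                    & (results["omega2"] > 1.0)
                    & (results["filter_flag"] == "retain")
                ).sum()
            )
            if len(results)
            else 0
        )
        summary_rows.append(
            {
                "branch": tag,
                "lineage": labels.get(tag, ""),
                "n_excluded": len(exclusions),
                "n_retained": len(results),
                "n_psg": len(psgs),
                "n_psg_fdr": n_fdr,
            }
        )
    return tables, pd.DataFrame(summary_rows)
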