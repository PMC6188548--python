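# Methods

`convsel` implements a genome-scale screen for parallel molecular
adaptation: branch-site tests of positive selection on designated lineages,
posterior probabilities of convergent amino-acid substitutions between
lineage pairs, and the set-level statistics used to relate the two. This
note records the models, the numerical choices, and what the synthetic data
do and do not emulate.

## Branch-site model of episodic selection

Codon evolution follows the standard 61-state Markov model: instantaneous
rates are zero for multi-nucleotide changes and otherwise proportional to
the target codon's equilibrium frequency, multiplied by κ for transitions
and ω = dN/dS for nonsynonymous changes. Equilibrium codon frequencies are
F3×4 by default (position-specific nucleotide counts with a pseudocount;
F1×4 and F61 are available). Branch-site Model A has four site classes with
proportions

    q0 = p0,  q1 = p1,  q2a = (1−p0−p1)·p0/(p0+p1),  q2b = (1−p0−p1)·p1/(p0+p1),

where class 0 evolves with 0 < ω0 < 1 everywhere, class 1 is neutral, and
classes 2a/2b switch to ω2 ≥ 1 on the single foreground branch (tagged
`#label` in the Newick input; a tip foreground is allowed). The null model
fixes ω2 = 1; the likelihood-ratio statistic 2Δℓ (clamped at zero) is
referred to χ²₁. This comparison is conservative because the null value
lies on the boundary of the alternative's parameter space; the calibration
test verifies the rejection rate stays at or below the nominal level.

**Two-stage fitting.** Branch lengths and κ are estimated per gene under
the one-ratio M0 model and then held fixed while (p0, p1, ω0, ω2) are
optimised. This is a deliberate simplification relative to re-optimising
everything under each model: it keeps the null nested in the alternative
exactly (identical fixed lengths) and cuts per-gene cost several-fold. The
alternative fit is always started from the null optimum as well, so
lnL_alt ≥ lnL_null holds by construction.

**Rate scaling.** Within each branch-site likelihood evaluation all class
rate matrices share a single scale — the mixture-averaged background
substitution rate — so branch lengths remain expected substitutions per
codon and are comparable between M0, the null, and the alternative.

**Empirical-Bayes sites.** NEB plugs the MLEs into the class posterior
q_k L_k(site)/Σ_j q_j L_j(site). BEB averages that posterior over a
discrete uniform prior grid: 10 midpoints for ω0 on (0,1), 10 for ω2 on
(1,11), and 10×10 for the proportion pair parameterised as
(p0+p1, p0/(p0+p1)); gridpoints are weighted by their marginal likelihood
with κ and branch lengths at their estimates. This is a faithful variant
of the published branch-site BEB; the grid bounds and parameterisation are
this package's documented choices. A positively selected site (PSS)
requires LRT p < 0.05, ω2 > 1 and EB posterior > 0.5; genes whose PSSs are
clustered (median inter-site interval ≤ 10 residues) are excluded as
likely alignment errors, with 0- and 1-site genes retained since no
interval exists. Downstream gene sets use nominal p < 0.05; BH-FDR-adjusted
values are reported alongside but not used as gates.

## Convergence between branch pairs

For the convergence stage each gene's translated alignment is analysed
under the Dayhoff replacement model (published exchangeabilities and
frequencies, rate-scaled to 1) with branch lengths fitted per gene by
maximum likelihood — independent of the codon-stage fits. For each focal
branch (the stem of a lineage's clade in the gene's pruned tree; a single
present member yields its terminal branch — the "most ancestral comparison
possible"), the exact per-site joint posterior J[a, x] of the parent and
child states is computed by an inside–outside pass. For a branch pair,

    pp_parallel   = Σ_x Σ_{a≠x} J1[a,x]·J2[a,x]
    pp_convergent = Σ_x Σ_{a≠x} Σ_{b≠x,b≠a} J1[a,x]·J2[b,x]

and pp_total is their sum — the probability that both branches
independently substituted to the same derived residue. Treating the two
joints as independent is an approximation; its error runs through the
uncertainty of the states on the path between the branches. On study-shaped
trees (41 taxa, focal branches in different superorders) the measured
deviation from the exact four-endpoint joint is below 1e-5; on toy 5-taxon
trees where both branches abut the root it can reach ~1e-2 at
homoplasy-ambiguous sites. An exact mode (`fit(exact=True)`) computes the
full four-endpoint joint by state-clamped passes and is used for
validation. Gene-level evidence uses the conventional two-tier thresholds:
summed pp_total ≥ 1.0 (≈ one convergent site) and ≥ 2.0, with the count of
individual sites at pp_total > 0.5 reported alongside. Because neutral
convergence accumulates with branch length, the package also reports the
trend of convergent-site counts against summed branch length (Pearson and
Spearman); under neutrality this trend is positive, and pair-level excess
should be judged against it.

## Alignment QC and gene gating

Sequence-level rules, in fixed order: remove sequences with > 50% missing
data (N); pad incomplete final codons with N; remove sequences with
internal stop codons (a terminal stop is not internal; determined stops
inside the 61-state alignment are treated as missing states); remove
sequences shorter than 150 nt. Alignment-level: remove codon columns that
are gapped in more than half the taxa (columns are removed in whole-codon
units to preserve frame; a codon counts as gapped if any of its three
positions is a gap), then re-apply the length rule, and keep only
alignments longer than 100 codons (strict). A gene enters a lineage's test
only with ≥ 1 focal taxon, ≥ 1 outgroup and ≥ 4 taxa in total. All rules
are deterministic and idempotent; each excluded gene is logged with exactly
one reason, and per-gene numerical failures are quarantined rather than
aborting a batch.

## Set statistics and enrichment

The m-way intersection of per-lineage gene sets is tested exactly: for
fixed-size sets drawn uniformly and independently from a background of
size N, the intersection size distribution follows by iterated
hypergeometric conditioning; the reported p is the upper tail at the
observed overlap and fold enrichment is observed/expected with
expected = N·Π(n_i/N). For m = 2 this is exactly the hypergeometric. The
background is the set of genes actually tested for the corresponding
signal, not the genome.

GO enrichment applies the true-path rule (genes propagate to all ancestor
terms) and a one-sided Fisher test per term under three algorithms:
`classic` (independent per term), `elim` (deepest terms first; genes of
terms significant at the cutoff, default 0.05, are removed from their
ancestors before those are tested) and `weight` (a ratio-weighting variant
that down-weights genes explained by a more significant child by the ratio
of log significances, with weighted counts rounded for the hypergeometric
tail — a documented faithful variant, since the reference algorithm family
is specified only by name). Classic p-values are deliberately not
FDR-adjusted; elim/weight already decorrelate the DAG.

## Synthetic data

The generator is the package's study design in miniature. The fixed
41-taxon tree mirrors the four independent subterranean clades — golden
moles (2 taxa), African mole-rats (8), spalacids (4) and the star-nosed
mole (1) — embedded among terrestrial sisters, with tags A–D on the focal
stem branches and E–H on the four terrestrial controls (elephant+hyrax,
guinea pig, mouse+rat, shrew). Branch lengths are drawn once per seed from
an exponential with mean 0.08 substitutions/site (clipped to
[0.005, 0.5]); the published per-branch lengths are not available, so these
are documented synthetic values of realistic magnitude. Codon alignments
evolve by the exact CTMC per site class (root states from the stationary
frequencies; default composition mildly AT/GC-skewed via F1×4). Selection
is planted as Model A with ω2 on a designated foreground branch;
convergence positives are planted by forcing a shared derived amino acid
onto both branch children at chosen sites and re-simulating the subtrees
below conditional on the forced state (parallel mode requires the two
parent nodes to share an amino acid at the site, which the simulator
selects for; an impossible site is skipped and resampled). Taxon
missingness drops each taxon independently per gene. Everything is a pure
function of (spec, seed).

What the generator does **not** emulate: alignment error and indels,
assembly chimeras, GC-biased gene conversion, rate variation beyond the
Model A mixture, and selection regimes outside branch-site episodic
selection. Passing tests therefore demonstrate correctness and calibration
of the inference machinery under the model, not robustness to real-data
artefacts — which is why the clustered-PSS filter and the QC gates are
tested as rules on constructed cases rather than on simulated misalignments.

## Problem sizes and numerical choices

Validation experiments use desk-scale defaults chosen to exercise the
statistics at meaningful power: LRT null calibration on 200 genes × 120
codons × 8 taxa (the binomial bound 0.05 + 3·SE applies at n = 200); power
and site recovery on 50 genes × 250 codons with ω2 = 4 at 15% of sites;
convergent-site detection on 20 genes × 300 codons on the 41-taxon tree
with branch lengths ≈ 0.1; the neutral trend over a 5-point length grid ×
50 genes; end-to-end determinism on a 16-gene × 120-codon fixture. The
full-study default (`SimulationSpec`: 200 genes × 300 codons) is the
fixture the generator writes to disk.

Matrix exponentials use the symmetrised eigendecomposition of reversible
rate matrices, cached per ω and shared across branches; per-pattern scaling
guards against underflow; site patterns are compressed before any
likelihood work. Optimisation is bounded L-BFGS-B on log-transformed
parameters with exact inside-outside gradients for branch lengths and
finite differences for κ/ω; mixture parameters use a softmax
parameterisation of (p0, p1). Fits run from one or two deterministic
starts with a fallback start on non-convergence, and refitting from an
optimum reproduces it to 1e-8. Ambiguity handling: gaps and N/X are fully
missing; other IUPAC codes expand to their compatible state sets. LRT
statistics are clamped at zero (nested models; negative values are
optimizer noise and trigger a warning).

## Known limitations

- The branch-site stage fixes branch lengths and κ at M0 estimates;
  codeml-style joint re-optimisation would change lnL values slightly
  (p-values are conservative in our calibration either way).
- The product-form convergence PP is an approximation whose error grows as
  the compared branches approach one another; use the exact mode for
  closely spaced pairs on small trees.
- The `weight` enrichment algorithm is a variant, not a line-for-line port
  of the reference implementation; `classic` and `elim` follow the
  standard definitions exactly.
- Convergence PPs are computed at amino-acid level under Dayhoff only (no
  codon-level convergence, no among-site rate variation).
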