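# Methods

`crossmeta` implements a cross-species funnel for nominating metastasis
genes: genes whose expression change between weakly metastatic mouse
melanoma lines and their highly metastatic derivatives is concordant with
the expression level associated with poor patient outcome in two
independent melanoma cohorts. This note records the models, the parameters
that matter, the synthetic-data design, and the numerical choices.

## Gene-wise Cox survival screen

Each gene enters its own Cox proportional-hazards model with the patient's
log2 expression as a continuous covariate; one cohort (Leeds-style,
melanoma-specific survival) is additionally adjusted for age (years) and
sex. The reported hazard ratio is per unit of log2 expression: HR < 1 means
higher expression is protective, so *low* expression of that gene marks
poor outcome.

The partial likelihood is maximised by Newton–Raphson with step halving.
Ties are handled by the Breslow approximation by default (the screen's
historical convention) with Efron available by configuration; the two
coincide on continuous survival times. Convergence requires the score's
max-norm below 1e-9 (fits with score above 1e-6, or |β| > 40, are flagged
non-estimable, as are genes with constant expression or cohorts with no
events). Standard errors come from the inverse observed information; the
Wald p is two-sided. Because a screen refits the same survival data for
thousands of genes, the sort order, tie blocks and event bookkeeping are
precomputed once per cohort (`CoxWorkspace`).

Per-cohort p-values are Benjamini–Hochberg adjusted over all estimable
genes of that cohort's panel — non-estimable genes contribute no p-value
and are excluded from the family. Dual-cohort candidates require FDR < 0.1
in both cohorts; the direction agreement flag compares HR < 1 between
cohorts. Kaplan–Meier median splits assign values strictly above the median
to "high" and ties at the median to "low" (deterministic, documented; only
the split relative to the median is specified by convention).

`wald_p_from_hr_ci` reconstructs a two-sided Wald p from a printed HR and
95% CI assuming log-scale symmetry: SE = (ln hi − ln lo)/(2·z₀.₉₇₅). On the
printed 28-gene candidate table this reproduces every printed p-value
within its printed precision.

## Differential expression

Counts are normalised by median-of-ratios size factors (computed over genes
with nonzero counts in every sample). Note these factors are invariant to a
global rescaling of all counts — the per-gene geometric mean absorbs it —
while scaling a single sample scales that sample's factor proportionally.

The negative-binomial Wald test is a deliberately simple re-implementation:
per-gene dispersion α by method of moments on normalised counts, pooling
within-group variances so real fold changes do not inflate α, floored at
1e-8 to avoid degenerate standard errors; the log2 fold change is the ratio
of group means of normalised counts; its variance comes from the NB
relation Var = μ + αμ² by the delta method. The Wald statistic is referred
to a **t distribution with n₁ + n₂ − 2 degrees of freedom** rather than the
normal: with five replicates per group the variance is estimated from few
observations, and the normal reference is anti-conservative (measured
type-I error ≈ 0.086 at nominal 0.05). With the t reference the type-I
error sits inside binomial 99% bounds at both 0.05 and 0.01 on 5000
simulated null genes; the reference converges to the normal as replication
grows. There is no dispersion shrinkage and no independent filtering beyond
the stated base-mean rule — the thresholds, not tool internals, define the
analysis, and parity with any particular published tool is not attempted.

A comparison filters genes with mean normalised count < 10 *before*
re-running BH on the survivors; the DE call requires padj < 0.01 **and**
|log2FC| ≥ 2 jointly. Unions across comparisons retain per-comparison
directions and flag genes called in opposite directions as ambiguous
(excluded from cross-species concordance). Replicate QC computes Pearson
correlation on log2(FPKM + 1) (a switch allows raw normalised counts),
clusters samples by average linkage on 1 − r, and flags replicates whose
nearest neighbour is outside their own group.

## Orthology and concordance

Mouse genes classified many2many are discarded outright. For one2many
genes the partner with the highest protein percent identity is chosen;
exact identity ties break lexicographically on the human ID with a logged
warning (ties are not otherwise specified by the resolution rule). The
concordance rule: a mouse gene underexpressed in the metastatic derivative
is concordant with a human orthologue whose *low* expression marks poor
outcome (dual HR < 1), and symmetrically over ↔ high. Genes with
discordant cohort directions have undefined poor-outcome direction and drop
out before the concordance call. Candidates are ranked protective-first by
ascending cohort-A HR, ties broken by cohort-B p-value, adverse genes last.

## Randomisation null

The significance of a concordant overlap of size k is assessed by drawing
m mouse genes without replacement from the expressed universe (genes
passing the base-mean filter), assigning each an independent direction
(under with probability p_under = 0.4621429 by default, the observed DE
direction frequency), and counting draws that hit the human poor-outcome
list with matching direction. The empirical p is the inclusive tail
P(X ≥ observed) over 1000 samples, reported both raw (which can be exactly
0) and with the (r+1)/(n+1) correction; the raw value is the headline. The
closed-form check: E = (m/N)·Σ_g p_dir(g) over human-list genes in the
universe, with variance from hypergeometric-thinned Bernoulli terms
including the negative covariance of sampling without replacement. The
engine's 1000-sample mean sits within 3 analytic SEs of E across a
parameter grid.

## Variant filtering without a matched normal

Stages in order: (1) QUAL ≥ 20 and ≥ 5 variant-supporting reads (boundary
values kept; the support count is read from INFO/DP4 alt-strand fields when
present, else INFO/DP; records missing both are removed as unevaluable);
(2) SNVs strictly within 10 bp of an indel's affected span (pos through
pos + len(ref) − 1) are removed, indels never are; (3) exact
(chrom, pos, alt) subtraction of the strain panel, with a position-only
mode; (4) removal within ±50 bp of a structural variant, inclusive at both
padded ends. Multi-allelic records are decomposed before filtering.
Coordinates are 1-based inclusive (VCF convention); BED input is converted.
Every record lands in exactly one bucket, the pipeline is idempotent, and
the final kept set is invariant to permuting the stages with independent
predicates.

## Mutational signatures

SNVs are classified into the 96 trinucleotide classes (pyrimidine-strand
convention, substitution-major ordering C>A…T>G × 5' base × 3' base);
purine-reference records are reverse-complemented. NMF uses Lee–Seung
multiplicative updates minimising generalised Kullback–Leibler divergence
(Frobenius by option), best of n restarts by final divergence, stopping
when the relative improvement falls below 1e-7 (max 2000 iterations); the
objective is non-increasing at every iteration by construction and this is
asserted in tests. Signature rows are normalised to probability vectors
with exposures rescaled. k is a user parameter, default 2; no automatic
rank selection. Matching against a reference matrix takes the maximal
cosine per extracted signature and requires identical class ordering.
Reference signatures used in tests are synthetic (sparse Dirichlet draws);
the loader accepts the standard 96-row probability text format.

## Synthetic data: what it emulates, and what it does not

The generators produce every input with known truth. Survival: expression
standard normal per gene on the log2 scale; event times exponential with
log-hazard Σ β_g x_g + covariate terms; censoring an independent
exponential — proportional hazards holds exactly, so screen recovery is a
fair test. Counts: NB with mean size_factor · baseline · 2^lfc (derivative
group) and variance μ + αμ², via gamma–Poisson mixing (Poisson at α = 0).
Baseline abundances in the end-to-end fixture are log-normal
(median ≈ 150, log-sd 0.8), which is what gives realistic inter-replicate
correlations. One seed drives all sub-generators through a splittable
stream; identical seeds give byte-identical serialised outputs.

**Co-expression of planted prognostic genes.** In the end-to-end fixture
the genes carrying survival effects co-express through a single latent
programme: each effect gene is sign(β)·(√ρ·f + √(1−ρ)·ε) with ρ = 0.3 and f
shared per patient. With fully independent expression, 20–40 conditional
log-hazard effects of |β| = 0.7 would imply a patient-level log-hazard
spread (sd > 3) never seen in real cohorts, and the risk-set selection such
frailty induces attenuates every marginal hazard ratio towards 1 enough to
defeat any marginal screen regardless of sample size budget. Real
prognostic genes co-express in transcriptional programmes, and their
printed per-gene HRs are marginal quantities; the latent-programme design
reproduces that structure. The default ρ is 0 so all single-gene behaviour
(CI coverage, null calibration) is unaffected.

The fixture plants 20 concordant genes (half under/low, half over/high,
|β| = 0.7, |log2FC| = 3), 10 human-significant-only decoys, 10 mouse-DE-only
decoys, 10 direction-discordant decoys and 5 DE genes with many2many
orthology (dropped at mapping); cohorts have 400 patients and 2000 genes,
counts 5 replicates per group. What passing recovery on this fixture does
*not* show: robustness to non-proportional hazards, informative censoring,
batch effects, count outliers, orthology errors, or array-platform
measurement noise — none of which the generators emulate.

Variant fixtures engineer each trigger record to violate exactly one
filter stage (clean records are spaced 1 kb apart, every fifth an
insertion to anchor the SNV-near-indel stage), so per-stage removal counts
are known by construction. Mutation catalogues are multinomial draws from
exposure-weighted signature mixtures; the signature-study generator puts
samples in k groups each dominated by one signature (dominant exposure
0.7–0.95), mirroring cell-line series driven by distinct mutational
processes — with all samples interior mixtures the factorisation is weakly
identifiable and recovery degrades, which is a property of NMF, not of the
implementation.

## Problem sizes used by tests and the acceptance script

End-to-end recovery runs at the full stated scale (2 × 400 patients ×
2000 genes, 5 replicates per group, 20 planted genes) plus 20 null-fixture
seeds; screen calibration uses 200 genes × 300 patients; NB calibration
5000 null genes; NMF recovery 10 samples × 10⁵ mutations; the randomisation
grid uses universes up to N = 1000. These sizes keep the whole suite within
a few minutes on one CPU while leaving the statistical checks
well-powered.

## Known limitations

- The DE stage deliberately omits dispersion shrinkage; at very low counts
  its power is below that of moderated methods, and its padj values are not
  expected to match any specific published tool's output.
- The survival generator draws exponential event times; none of the tests
  probe misspecified (non-PH) hazards.
- The randomisation test treats direction assignment as independent of
  list membership, the literal reading of the procedure it mirrors.
- Cohort B (Lund-style) screens are unadjusted by default; adjustment is a
  configuration flag since only the Leeds-style cohort specifies age/sex
  adjustment.
- Funnel counts from the original patient/cell-line data (976, 763, 1430,
  338, 61, 28) depend on the real cohorts and a specific orthology
  database; they are not reproducible from synthetic data and are not
  targets of this package's tests.
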