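# Methods

`tissuemod` implements an integrative tissue-specificity analysis for
multi-cohort case/control transcriptomics: per-dataset differential
expression, empirical-Bayes batch integration, weighted co-expression
modules correlated with tissue identity, a cross-disease consensus, robust
rank aggregation of per-dataset rankings, window-based GWAS annotation,
and a final evidence join producing tissue-specific gene calls.  This note
records the models, the parameters that matter, and the design choices
made where the design was genuinely open.

## Differential expression and confounder screen

Each dataset (one tissue, one cohort) is log2-transformed
(`log2(x + 1)`; matrices whose maximum is below 30 are taken to be on log
scale already and passed through with a warning, since public microarray
matrices arrive in both states).  Per gene we fit ordinary least squares
of expression on case/control status plus optional covariates; the status
coefficient is the log2 fold change and its t statistic gives a two-sided
p value.  With no covariates this is exactly the pooled two-sample
t-test.  No variance moderation is applied and no multiple-testing
correction is used at this stage: the DEG threshold p < 0.05 is a
deliberately loose pre-filter whose output feeds the network and the rank
aggregation, not an inferential endpoint.

The confounder screen tests every gene against each demographic covariate
(two-sample t-test for binary covariates such as sex, Pearson correlation
with a t-distributed p on n−2 df for continuous ones such as age); a gene
with any confounder p < 0.05 is excluded from the final tissue-specific
calls.  Both alphas are configurable.

## Batch integration

Same-tissue datasets are merged column-wise over the union of their DEG
sets (restricted to genes measured in every member dataset); the network
matrices use case samples only.  Batch (dataset) effects are removed with
the parametric empirical-Bayes location/scale model: per gene, the data
are standardised against the batch-size-weighted grand mean and pooled
residual SD; per batch, the additive effect γ is shrunk toward a normal
prior and the squared scale δ² toward an inverse-gamma prior, both with
moment-matched hyperparameters, by the closed-form coordinate iteration
(relative tolerance 1e-4, at most 100 rounds).  The adjusted value is

    z = (x − α)/σ,    x* = ((z − γ*)/δ*)·σ + α.

A single batch yields the identity (γ* = 0, δ* = 1).  Degenerate priors
(no across-gene spread in the estimates, e.g. noise-free fixtures) fall
back to the unshrunk estimates, which is the correct no-information limit
and makes removal of a pure location/scale effect exact.  The
implementation agrees with the Bioconductor reference implementation
(`sva::ComBat`, parametric priors) to ~1e-13 on stochastic fixtures; the
test suite re-runs that comparison through `Rscript`.

Two consequences of the location/scale form are worth stating because
they bound what "batch removal" can mean:

* the per-gene grand mean is preserved only up to the shrinkage residual
  (the shrunk γ* differs from the raw batch mean by design, exactly as in
  the reference implementation);
* with few batches the absolute per-gene offset is unidentifiable — the
  average of the batch shifts is absorbed into the gene's mean.  The
  diagnostic we report is therefore the RMSE of *batch-centred* gene
  means (each batch's gene mean minus the gene's grand mean) against the
  generator's batch-free truth, plus per-gene one-way batch F statistics
  before and after adjustment.

The cross-tissue network matrix stacks the per-tissue adjusted matrices
over the union of their gene spaces; a tissue missing a union gene is an
error, never imputed (an `intersect` mode is available).

## Co-expression network and modules

Unsigned weighted network: a_ij = |Pearson r|^β (a signed variant,
((1+r)/2)^β, is available behind a flag but unsigned is the default,
matching common practice for this analysis generation).  Topological
overlap:

    T_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    ℓ_ij = Σ_{u≠i,j} a_iu a_uj,  k_i = Σ_{u≠i} a_iu,

computed by matrix product and verified against the literal triple loop
to 1e-12.  Soft-threshold scan: for each β in 1..20 the connectivity
distribution is binned into 10 equal-width bins and log10 density is
regressed on log10 mean connectivity; the signed fit index is
−sign(slope)·R², and the recommended power is the smallest β reaching the
target (default 0.8), else the argmax.  (Equal-width bins and the
−sign(slope) convention are the field-standard definition; an equal-count
binning would make the density constant and the regression degenerate.)

Modules are fixed-height cuts of the average-linkage dendrogram on
D = 1 − T (cut height 0.995, minimum size 30); subtrees below the minimum
fall into module 0.  Fixed-height cutting was chosen over the dynamic
hybrid tree cut because it is fully specifiable and deterministic; the
dynamic variant is an explicit non-goal.  Modules whose eigengenes
cluster below 0.25 on 1 − cor(ME) are merged and renumbered by size.

The module eigengene is the first right-singular vector of the
gene-standardised module submatrix (one value per sample, unit norm, zero
mean), sign-oriented to correlate non-negatively with the module's mean
expression.  kME is the Pearson correlation of a gene with an eigengene;
GS is the correlation of a gene with a 0/1 tissue indicator.  A module is
tissue-specific iff |r| > 0.6 and p < 0.05 for its eigengene against the
indicator, with p from t = r·sqrt((n−2)/(1−r²)).  Hub genes are screened
at |GS| > 0.6 and |kME| > 0.8 (strict inequalities); all four thresholds
are configurable and default to the stated operating points.

Correlating an eigengene with a binary indicator is a point-biserial
correlation; with four tissues the indicator variance is 3/16, which caps
the achievable |r| for a fixed effect size — this is why the generator's
tissue factors need substantial mean shifts for flagged modules to clear
0.6 (see below).

## Cross-disease consensus

The two diseases' TOMs (built on their shared gene set) have different
value distributions; the target TOM is raised elementwise to
log(q_ref)/log(q_tgt), where q is the configured off-diagonal quantile
(default the 98th percentile) and the reference is the input with the
larger quantile.  The quantile is an order statistic of the strict upper
triangle (numpy `method="lower"`), not an interpolated value: a monotone
power transform commutes exactly with an order statistic, so the
post-scaling quantiles agree to machine precision, whereas linear
interpolation would leave a gap of order 1e-5 at n = 50.  The consensus
TOM is the elementwise minimum; consensus modules are detected on
1 − consensus with the same clustering.

Per-disease module–tissue correlation tables over the consensus labels
are merged under the sign-consistency rule: a (module, tissue) cell is
consistent iff r_A·r_B > 0 (strictly — r = 0 carries no sign); the
combined r is the smaller magnitude with the common sign, and the
combined p is max(p_A, p_B), the conservative completion of "all
parameters merge".  Inconsistent cells carry NA throughout.

## Robust rank aggregation

Within each tissue, every member dataset contributes a ranked list — its
significant DEGs ordered by logFC (descending for the up list, ascending
for the down list; ties broken by gene id).  Lists contain DEGs only;
a gene absent from a list simply was not differentially expressed there,
and its aggregation uses n = the number of lists containing it.  This
matters statistically: ranking the full gene panel instead would let any
shared source of logFC noise (such as a co-expression factor) push whole
gene blocks to the extremes of both of a tissue's lists, inflating the
false-call rate of a two-list aggregation several-fold.

A gene's sorted normalised ranks r_(1) ≤ … ≤ r_(n) are scored with beta
order-statistic CDFs, ρ = min_k BetaCDF(r_(k); k, n−k+1), and corrected
over the n list positions: p = min(1, ρ·n).  Genes with p < 0.05 are
robust; the up and down directions are aggregated separately and their
significant sets unioned.  Under independent uniform ranks the procedure
is conservative (the Monte-Carlo calibration in the test suite and the
acceptance script measures a call rate of ~0.03 at α = 0.05).

## GWAS window annotation

Variants are deduplicated by rsID (first occurrence kept; recurring rsIDs
at conflicting positions keep the first with a warning; distinct rsIDs at
one position are all kept).  A 1-based variant locus p maps to every gene
whose 0-based half-open interval [s, e) satisfies
max(0, s − (p−1), (p−1) − (e−1)) ≤ 20,000.  The window is anchored on the
variant and measured to the interval edge (not the TSS); strand is
ignored and distance is unsigned.  Coordinates are taken as given; no
liftover.

## Tissue-specific gene calls and ORA

A gene is called tissue-specific when it survives the hub-gene screen in
a flagged module, carries RRA *or* GWAS evidence (an AND mode exists),
and is not confounder-excluded.  Calls are keyed by (gene, tissue);
shared calls between diseases are the intersection on that key.  Counts
are reported both per tissue and pooled over tissues, since a gene can be
called in more than one tissue.

Enrichment is a generic upper-tail hypergeometric over-representation
test against user-supplied GMT sets, BH-corrected across sets, with the
universe defaulting to the genes that entered the network (a genome-wide
universe would be anti-conservative after DEG pre-filtering).  No term
database or ontology semantics are implied.

## The synthetic study

The generator emulates the study design the pipeline targets: two
diseases, each with 4 tissues (PFC, CRE, PBMC, WB) × 2 datasets × 20
samples (10 case / 10 control), 450 genes.  Expression is built on log2
scale as

    baseline_g + loading_g·f_m(s) + DE shift + confounder effect
    + batch shift_g + batch scale_g · noise,

and exported as 2^x so the pipeline's log transform is exercised.  Five
planted modules of 50 genes: modules 1–4 are tissue-differential — their
latent factor is active only in the home tissue with mean ±2.75 and SD
2.0 (module 4 negative, i.e. suppressed in whole blood) — and module 5
is a second PFC block with a zero-mean factor (SD 2.5), co-expressed
within PFC but not tissue-differential.  The nonzero factor mean is the
single mechanism that produces both within-module correlation and a
module–tissue correlation; a zero-mean factor shifts variances, not
means, and could never flag a module at |r| > 0.6.  Two mean-shifted
modules in the same tissue would share the tissue-indicator pattern and
inevitably fuse in an unsigned network, which is why the second PFC
module is co-expression-only.  Loadings are uniform on (1.0, 1.3); noise
SD is 1.

Sixty DE genes receive a ±1·SD case shift consistent across tissues (so
cross-dataset rank signal exists); 15 background genes follow age
(slope 1 SD per covariate SD) and 15 follow sex (shift 1 SD).  Batch
effects are per-(gene, dataset): additive shifts ~N(0, 0.6²) and
multiplicative noise scales ~LogNormal(0, 0.3²), the exact location/scale
form the batch model assumes.  The ground truth records module labels,
homes, loadings, DE signs, confounder genes, GWAS-proximal genes, and the
batch-free expression of every dataset.

These levels were fixed once by a designed calibration: within-module
correlation ≈ 0.6–0.7 across the merged matrix, module–tissue |r| ≈ 0.75
for home tissues, batch effects large enough that unadjusted integration
visibly corrupts the network but small enough that 2 datasets per tissue
can be integrated at all.  Desk-scale analyses use soft power β = 8,
which suppresses background and residual batch-step correlations (~0.1–
0.4) while preserving within-module adjacency.  Under these conditions
the planted modules are recovered with median adjusted Rand index ≈ 0.93
over 20 replicates and the PFC-specific module is flagged for PFC (and no
other tissue) in ≥ 90% of replicates.

The toy GWAS fixture places genes every 100 kb on one chromosome
(10 kb long), puts hit variants inside truth-selected module genes,
decoys mid-gap (≥ 45 kb from any gene), and emits one duplicated rsID to
exercise recurring-variant merging.

What the generator does *not* emulate: probe-level microarray structure
and probe→symbol mapping, platform differences, heavy-tailed or
intensity-dependent noise, correlated confounders, LD structure, and
realistic gene/variant density.  Passing tests therefore show that the
pipeline's machinery is correct and calibrated under its own model
assumptions — not that the biological findings of any real cohort would
be reproduced.

## Numerical choices

* Quantiles for TOM scaling: order statistic (`method="lower"`), strict
  upper triangle only (diagonal ones would distort it).
* Clustering tie-breaks: SciPy average linkage is deterministic for a
  fixed input; module numbering orders by decreasing size, then smallest
  first-gene position.
* EB guards: pooled variances floored at 1e-12; degenerate priors (zero
  across-gene spread) disable shrinkage for the affected batch.
* Zero-variance genes: p = 1 in the DEG model (logFC by the mean
  difference), kME/GS = 0; zero-variance genes are an error in the
  network itself (correlation undefined).
* Rank ties broken by gene id, making every ranking reproducible.
* All randomness flows from one root seed through named SeedSequence
  spawns (CRC of the stage name), so each stage is independently
  reproducible and every derived seed stays below 2^31.
* Floats are written with 17 significant digits; every table round-trips
  bit-exactly.

## Limitations

* Plain OLS t-statistics, not moderated t; with very small cohorts the
  DEG sets are noisier than the limma equivalent (the downstream stages
  consume only the p < 0.05 sets, which dampens the difference).
* Fixed-height tree cut; deep nested modules that the dynamic hybrid cut
  would separate may merge or fall to module 0.
* The batch model assumes ≥ 2 samples per batch and no biological
  covariates (case-only matrices; tissue handled downstream).
* Two diseases only in the consensus; no weighted or multi-way blends.
* The per-tissue RRA typically runs on very few lists (here 2), where
  the min-beta statistic has limited resolution; robust sets are small
  and conservative by construction.
* The simulated cohorts of the two diseases are independent draws, so
  cross-disease shared calls are near-null here; the shared-call
  machinery is exercised by construction rather than by a planted
  shared-biology effect.
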