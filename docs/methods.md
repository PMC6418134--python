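# Methods

This package implements a seed-anchored gene co-expression network analysis
(GCNA) chain for recurrence prognosis in multi-cohort expression studies,
together with a synthetic-cohort generator that makes every stage testable
without external downloads. This note documents the models, the defaults and
the design choices that were genuinely open.

## Cohort harmonization

Cohorts from different platforms differ in the location and scale of their
log2 intensity distributions. We align each non-reference cohort with a
single global linear map: values declared on a linear scale are first
log2-transformed (non-positive values are rejected), then

    x' = (x - mean_t) / sd_t * sd_ref + mean_ref

where the moments are pooled over all cells of the matrix. After this map the
pooled mean and standard deviation match the reference exactly; skewness and
kurtosis are *diagnostics* — a linear map has two degrees of freedom and
cannot set four moments, so they are reported per cohort before and after
alignment rather than matched. The map is idempotent (re-harmonizing an
aligned cohort is the identity up to rounding).

Pooled rather than per-gene moments are used because the per-gene alternative
destroys between-gene variance structure that the correlation-based network
stage depends on. Probe-level matrices are collapsed to gene level by the
per-gene median across probes; probes without a gene mapping are dropped with
a logged count. Merging takes the gene intersection across cohorts (first
cohort's order) and concatenates samples; sample-ID collisions are an error.
Records with an unknown recurrence status are retained in the expression
matrix but excluded listwise from every survival fit, so a merged study can
have more loaded cases than survival-analyzable cases.

## Synthetic cohorts

The generator plants exactly the structure the analysis is designed to find.

**Co-expressed block.** One standard-normal latent factor `U` per sample
drives the block genes and a subset of "coupled" seed genes:
`g = lambda * U + sqrt(1 - lambda^2) * eps`. For jointly Gaussian variables
the Spearman and Pearson correlations satisfy `rho_S = (6/pi) arcsin(r_P/2)`,
so the loading that yields a target pairwise Spearman `rho` between two block
genes is closed-form: `lambda = sqrt(2 sin(pi * rho / 6))`. The calibration
is therefore exact (no Monte-Carlo tuning), and because Spearman correlation
is rank-based it survives any monotone transform of the gene values.
Non-block genes are independent Gaussian noise. All genes are scaled to mean
7, sd 1 — a typical log2 microarray intensity scale.

**Survival.** Recurrence times are exponential proportional hazards:
`T ~ Exp(h0 * exp(sum_g B_g (x_g - 7) + B_node * node))`. The exponential
baseline is the simplest distribution consistent with a Cox analysis; the
linear predictor is centred so `h0` (default 0.08/year) is the hazard of an
average node-negative sample. `B_g` is the *generating* per-gene coefficient;
note that for a nearly rank-one block of k genes the marginal (single-gene)
association approximately aggregates the whole block's effect, so a planted
per-gene HR of 0.85 over six tightly correlated genes produces marginal
screen HRs well below 0.85. This mirrors the direction, not the magnitude, of
single-gene tables from real cohorts.

**Node status** is Bernoulli with `logit P(node=1) = a + beta * U`, the
intercept solved by quadrature so the prevalence hits its target (default
12%). Because node and the protective block share the latent factor, node's
estimated hazard ratio in index-adjusted models is attenuated relative to its
generating value — an intended consequence of the planted confounding (the
real phenomenon the node adjustment exists for).

**Censoring** combines an administrative follow-up cap (default 15 years)
with independent exponential censoring whose rate is solved by root-finding
so the expected censored fraction equals the target (default 61%). If the cap
alone censors more than the target, the configuration is rejected as
infeasible.

**Defaults** emulate a four-cohort breast-cancer recurrence study: 922 cases
split 286/189/249/198; 13,452 genes; 34 seed candidates of which two anchor
the block; six block genes at pairwise Spearman 0.95 with per-gene HR 0.85;
two records with unknown recurrence; per-cohort location/scale shifts with
the fourth cohort as the unshifted reference. Cohort shifts are applied as
`x -> (x - m) * scale + m + loc` around the cohort's own pooled mean, so a
shift of (+3, x2) moves the pooled mean by exactly +3. Analyses and tests
that need speed override `n_genes` and sample sizes explicitly; the analysis
scripts use 2,000 genes, a size chosen so the full chain runs in seconds
while leaving the seed-vs-background contrast intact.

**What the generator does not emulate:** probe-level array noise, batch
effects beyond location/scale, non-proportional hazards, informative
censoring, and correlation between filler genes. Passing tests therefore
demonstrate correctness of the machinery and calibration of the statistics
under the assumed model, not robustness to real-array artifacts.

## Network construction

For each phenotype stratum (recurrence +/- and node x recurrence by
default), Spearman correlations are computed between every seed gene and
every non-seed gene with the stratum's samples (average ranks for ties;
computed as Pearson on ranks). Edges with rho > 0.9 are candidates — the
threshold is read as *signed* correlation, since the discovered clusters of
interest are positive co-expression blocks; an absolute-value mode is
available behind a flag. Candidates are processed in descending rho and an
edge is kept iff its non-seed partner currently holds fewer than
`edge_limit` (default 1) kept edges. The limit binds the non-seed partner
only — seeds may anchor many spokes. Rho ties are broken by (seed, partner)
lexicographic order so results are reproducible; the greedy rule is verified
against a literal brute-force replay in the tests.

Network genes are clustered by complete-linkage agglomerative clustering on
distance 1 - rho, with the tree cut at (maximum merge height)/1.5. An
alternative reading of the cut rule — (sum of merge heights)/1.5 — is
implemented behind `cut_mode="total"`. Cluster IDs are ordered by each
cluster's alphabetically first member.

Node annotation: icon size is |cv| = |sd/mean| of the gene's expression in
the stratum (zero mean is an error); seeds are diamonds, co-expressed genes
circles, and co-expressed genes with node-adjusted Cox p < 0.05 stars; the
frame is red for 0.01 <= p < 0.05 and yellow for p < 0.01; direction is "up"
when mean expression is higher in recurrent than non-recurrent cases.
Correlations, clusters and cv are stratum-local, but the Cox p-values and
the up/down direction come from the full merged cohort: a stratum defined by
recurrence has no event contrast of its own, so a within-stratum survival
fit is undefined there.

Comparing two strata's networks is set algebra over their non-seed nodes:
common, exclusive-to-A, exclusive-to-B — disjoint and exhaustive by
construction. "Novel genes" are operationalized as non-seed network genes
with node-adjusted Cox p < 0.05.

## Survival screening

Each gene is screened with a two-term Cox model, recurrence ~ gene + node:
the screen is reported per gene ("univariable" in the tabular sense) but
every fit is adjusted for node status. Ties use Efron's approximation.
Missing events or node status are dropped listwise with the count recorded
on each result. Raw p-values are reported (matching the source convention of
the field's tables); a Benjamini-Hochberg column is available as a
non-default extra. Degenerate genes (zero variance, < 2 events) raise;
within a multi-gene screen they become flagged rows rather than aborting the
run. Non-convergence is likewise flagged, never raised. Node association is
quantified by per-gene logistic regression (statsmodels MLE); complete
separation yields a flagged result.

`multivariable_cox` fits all terms jointly and requires a full-rank design;
collinear columns are identified by pivoted QR and named in the error.

## Immune index

Genes in the index set are standardized per gene (correlation-scale PCA —
this makes the index invariant to per-gene affine rescaling and matches the
reported mean-0/sd-1 score), the first principal component is extracted by
SVD, and the scores are re-standardized to mean 0, sd 1 (sample sd). The
eigenvector sign is fixed by requiring positive correlation between the
score and the gene-set mean, removing the backend-dependent sign ambiguity;
higher score = higher block expression = the protective direction.

Dichotomization uses the linearly interpolated empirical percentile (default
40th); scores at or below the cutoff form the low (reference) group. Model 1
fits score + node (continuous); Model 2 fits high-vs-low + node. Predicted
survival curves come from the Breslow-type baseline cumulative hazard of the
fitted discrete model, evaluated as a right-continuous step function with
S(0) = 1, one curve per group x node level.

## Numerical choices and degenerate inputs

- Spearman: average ranks for ties; matches rank-then-Pearson to 1e-12 on
  untied data.
- The censoring-rate and node-intercept solvers use Brent root-finding on
  provably monotone objectives.
- Percentile cutoff ties go to the low group (<=).
- Zero-variance genes: error in single fits and the index; logged skip in
  mass correlation; flagged row in screens.
- All orderings (network export, cluster IDs, table rows) are deterministic,
  and the full pipeline is byte-identical under a fixed seed.

## Problem sizes

The test suite and acceptance script use scaled problem sizes chosen as the
smallest that make each statistical check stable: n = 2000 samples for
block-calibration and end-to-end discovery checks, n = 5000 with 100
replicates for coverage of a planted B = -0.15, 1000 null gene-replicates at
n = 500 for type-I error, and a 922-sample, 2000-gene four-cohort study for
the full-chain acceptance run.

## Known limitations

- The harmonization is a two-moment global map; it will not remove per-gene
  batch effects.
- The screen's marginal coefficients on correlated blocks aggregate the
  block effect (see above); they should be read as association strengths,
  not causal per-gene effects.
- Proportional hazards is assumed, not tested; there is no time-varying
  covariate support.
- The clustering cut rule is ambiguous in its source; both readings are
  implemented, with max-height/1.5 as the default.
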