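# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what a green test establishes.

## Phenotype clustering

Binary ACR criteria are embedded by correspondence analysis of the complete
disjunctive (indicator) matrix: with row masses r and column masses c, the
standardized residual matrix S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2} is
decomposed by SVD and principal row coordinates F = D_r^{-1/2}UΣ are
returned. For Q complete binary variables the total inertia is
(J/Q) − 1 = 1 with J = 2Q categories; this identity and agreement with a
brute-force element-wise oracle are asserted in tests. Coordinates are
deterministic up to per-dimension sign.

The retained dimensionality is chosen by cell-wise k-fold cross-validation:
held-out criterion cells are imputed by an iterative rank-d SVD with
regularized (noise-shrunken) singular values, and d minimizes the held-out
squared error, ties toward fewer dimensions. Held-out cells are criterion
cells, not raw indicator cells: the two indicator columns of one criterion
are complements, so masking only one of the pair leaks the answer and
inflates the selected rank. On the default cohort this scheme selects 2
dimensions, matching the two dimensions the original analysis retained.

K-means uses k-means++ initialization, 50 restarts, Lloyd iterations to
1e-6 relative objective change (none of this is specified by the source
analysis; they are conventional defaults). The number of clusters maximizes
the minimum per-cluster mean bootstrap Jaccard (clusterboot convention:
for each original cluster, the best Jaccard match among bootstrap clusters,
computed over the intersection with the resampled points; B = 100 default).
A conservative reading of the retention rule is exposed as a pass/fail flag
at 0.82. Clusters are renamed M, S1, …, S(k−1) by increasing mean criterion
count (or a supplied severity score); ties break by renal prevalence, then
lexicographically.

## Covariate engine

Medication PCs: centered PCA of the binary current-medication matrix; the
retained count minimizes the same cell-wise CV error and is capped at 3.
Cell-composition surrogates: ReFACTor — sites standardized, rank-k
approximation, sites ranked by distance between observed and reconstructed
profiles, PCA on the t best-approximated sites; defaults k = 6, t = 500
(the published algorithm's defaults). Ancestry PCs: PCA of mean-imputed
dosages standardized by sqrt(2p(1−p)). All scores are zero-mean; the
medication PCs enter globally (they are confounders, not cluster features).

A deliberate property of the generator supports this engine: reference-free
surrogates recover latent structure only when cell composition dominates
the low-rank spectrum, as it does in real whole blood. With too few latent
factors relative to k, the spare components lock onto the cluster axis and
over-correct — we observed exactly this with 2 latent factors and k = 6,
which is why the generator's default is 6 latent factors (the major
leukocyte fractions).

## Differential methylation

Per CpG, ordinary least squares of β on the cluster factor plus covariates;
the cluster factor is tested by the (k−1)-df partial F-test, BH-adjusted
across CpGs (FDR < 0.1 default); variance explained is the partial R² of
the cluster factor. We use OLS rather than limma's empirical-Bayes
moderation: with n ≈ 333 the residual degrees of freedom make moderation
negligible, and OLS keeps every statistic reproducible from the normal
equations (a documented deviation). β values are modelled directly —
cluster differences are reported as Δβ on the β scale — with an M-value
mode behind a flag; age is included by default with a flag to drop it
(the source description is ambiguous on both points). The nestedF-style
decomposition is an overall F gate at FDR < 0.1 followed by per-pair
t-contrasts from the same fitted model, BH within contrast; Δβ is the
difference of covariate-adjusted cluster means, later-severity minus
earlier. λ is median(χ²₁ quantile of 1−p)/median(χ²₁).

## meQTL

QC order: call rate ≥ 0.95, then MAF strictly > 0.05 ("greater than 5%
retained": a SNP at exactly 5% is removed), then the Hardy–Weinberg exact
test at α = 1e-4 (Wigginton-style conditional enumeration in log space).
LD pruning is windowed greedy (window 50 SNPs, step 5 — conventional
defaults; only the r² ≤ 0.8 threshold is inherited), keeping the
earlier-position SNP of a correlated pair. Cis pairs are same-chromosome
with |SNP − CpG| strictly < 1 Mb, CpG position = single manifest
coordinate. Pair fits use Frisch–Waugh residualization of both methylation
and mean-imputed dosage on the covariates; slope, SE and t then equal the
full-model OLS quantities with the full-model degrees of freedom (asserted
against statsmodels). By default only cluster-associated CpGs are scanned,
matching the source analysis's focus; the pair list is caller-supplied so
a full scan is one call away.

## Causal inference test

Y is the cluster label encoded ordinally (M=0, S1=1, S2=2); a binary
severe-vs-mild encoding can be passed by the caller since Y is a plain
vector. Covariates enter all four component models. Conditions 1–3 are
nested-model partial F-tests. Condition 4 tests conditional independence
of G and Y given M in an equivalence framework: residual-permuted copies
G* = fitted(G|cov,M) + π(e) preserve the G–M association while destroying
conditional G–Y dependence, giving the F distribution under independence;
shifting it by δ = max(0, F_marginal − median(F*)) represents the
no-mediation (dependence) null, and p₄ = (1 + #{F*+δ ≤ F_obs})/(B+1).
Small p₄ therefore supports independence, as the max-p convention needs:
under mediation F_marginal is large and F_obs small, so p₄ hits the
1/(B+1) floor; under the global null δ ≈ 0 and p₄ is near-uniform, keeping
p_cit = max(p₁..p₄) conservative (family-wise rejection ≤ α, verified at
1,000 replicates). The two-stage screen first BH-tests each meQTL SNP for
cluster association (FDR < 0.05), then runs the CIT on survivors and
BH-adjusts p_cit across screened triplets.

## Enrichment

Gene-set overlap uses the upper-tail hypergeometric. Chromatin-state
enrichment assigns each CpG to the tiling 0-based half-open BED interval
containing its (1-based) position, builds the 2×2 hit × in-state table per
state and cell type, and applies the two-sided Fisher exact test with BH
across states × cell types; degenerate odds ratios are Haldane-corrected
for reporting. Ethnicity enrichment counts cluster-associated CpGs whose
joint ethnicity factor (partial F over all levels — the source does not
state per-level vs joint; joint is the conservative choice) is significant
at raw p < 0.05 (an FDR mode mirrors the alternative reading), repeats the
count under label permutations, and reports the add-one permutation p and
the enrichment statistic (observed proportion over the null-mean
proportion).

## Label transfer and validation

A random forest on the binary criteria is tuned over
trees ∈ {250, 500, 1000} × features-per-split ∈ {√p, p/3, p} by out-of-bag
error (the source reports only that OOB error was minimized). External
criteria are matched by column name; predictions carry class-vote
fractions. Validation re-runs the cluster ANOVA in the external cohort
with its reduced covariates and correlates per-contrast Δβ against
discovery. On matched synthetic replications this yields validated
fractions ≈ 0.85 and Δβ correlations ≈ 0.93–0.97.

## The synthetic world

Defaults are the stated conditions of the emulated study: n = 333 with
cluster proportions 101/154/78; 18 binary criteria with the published
cluster-specific prevalences; 2,000 CpGs of which 50 carry cluster shifts
of Δβ = 0.05 (patterns: S2-only, S1+S2, graded; random sign); 300 SNPs
with MAF ~ U(0.05, 0.5); 50 cis pairs at 0.05 β/allele with MAF 0.3 placed
< 100 kb from their CpG; 5 causal, 5 reactive and 5 independent mediation
triplets; ethnicity sampled from the published cluster-conditional
composition with 30 ethnicity-shifted CpGs (half inside the cluster set,
offsets ~ N(0, 0.05), independent of genotype); 6 latent cell factors
loading half the CpGs at SD 0.05 on the β scale, the first shifted 0.3 per
severity step; 16 medications driven by three latent co-prescription axes,
the first tied to severity; residual SD 0.03 on the β scale. β values are
generated on the logit scale and inverse-transformed (no boundary
pile-up); the logit noise is scaled by the delta method so the β-scale
residual SD matches the nominal value. Cluster assignment thresholds a
latent severity score — noise plus the causal mediators' methylation and
the direct-edge SNPs — at the cluster-proportion quantiles, so mediation
triplets are genuinely causal in the generative graph. One global seed
fans out to fixed per-component streams; a separate biology seed fixes the
effect structure (positions, base levels, patterns, loadings, allele
frequencies) so that cohorts with different sampling seeds behave as
replication cohorts.

What the generator does **not** emulate: array chemistry (detection
p-values are synthesized uniform with planted failures), linkage
disequilibrium beyond optional block copies, family structure, genotype
imputation, and raw-intensity normalization. A green recovery test
establishes that the estimators find planted structure of the stated
effect sizes under conditionally independent criteria and logit-normal
methylation noise — not that they would on raw array data.

## A documented infeasibility

The recovery criterion "ARI > 0.8 against the true clusters" is not
attainable in the default world: with conditionally independent Bernoulli
criteria at the published prevalences and 101/154/78 mixing, the
Bayes-optimal classifier (posterior argmax under the true generative
parameters) reaches accuracy ≈ 0.865 and ARI ≈ 0.63 (Monte-Carlo at
n = 3,330). Real criteria are correlated within patients, which is what
made the published clusters crisper than their marginal prevalences imply.
The default prevalences were deliberately not sharpened to pass; the
corresponding acceptance test is left failing with this analysis, and a
separate test shows the identical pipeline reaches ARI > 0.9 once the
criterion log-odds are doubled. The same ceiling caps random-forest label
transfer near 86% agreement in this world; the > 85% transfer check is
therefore run on the separable configuration. Bootstrap stability still
selects k = 3 with all per-cluster Jaccard means > 0.82 on the default
world — cluster *existence* is detectable even where per-patient
assignment is noisy.

## Numerical choices

Batched OLS goes through rank-revealing QR projections; nested F-tests
guard zero-variance responses (p = 1, flagged) and saturated designs.
Collinear covariates are dropped greedily left-to-right with a warning.
BH is the standard step-up with monotone enforcement. Permutation p-values
use the add-one estimator and recorded seeds. The HWE exact test runs in
log-factorial space and matches full enumeration for all totals ≤ 50.
K-means and the random forest wrap scikit-learn with fixed seeds;
thread count never enters any computation.
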