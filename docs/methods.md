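# Methods

This note documents the models and procedures `regscore` implements, the
parameters that matter, the numerical conventions, and what the synthetic
cohorts do and do not establish about behavior on real data.

## Data model

Expression enters as a genes × samples matrix of finite, log-scale values
and is treated as already normalized upstream; the pipeline never
re-normalizes across samples. At load, duplicate gene ids are collapsed by
mean (deterministic and order-independent), rows with any missing value are
dropped and counted, and genes at or below a variance floor (default 0) are
removed. Gene sets travel as GMT; clinical data as a TSV with strictly
positive times and a 0/1 event indicator. Written matrices use 10
significant digits, so a write/read round trip preserves values to 1e-9.

## Consensus clustering

For each candidate k, `n_resamples` subsamples of ⌈sample_frac·n⌉ samples
(and ⌈gene_frac·m⌉ genes) are drawn without replacement and clustered by
the inner algorithm; the consensus matrix entry for a sample pair is
(# times co-clustered)/(# times co-drawn). Pairs never co-drawn are scored
0 with a logged warning rather than NaN, keeping downstream clustering
defined. The final assignment cuts an average-linkage tree on
1 − consensus at k. Per-resample RNG substreams derive from
(seed, k, resample counter), so results are independent of execution order.

Defaults: inner clusterer = agglomerative average linkage on
1 − Pearson correlation between samples over the gene panel (k-means with
10 restarts by flag); sample_frac = 0.8, gene_frac = 1.0,
n_resamples = 1000 (200 in the documented test workflows, where the
consensus matrices are already saturated).

k is chosen from the empirical CDF of the upper-triangle consensus values
on a fixed 101-point grid: the AUC per k (trapezoid rule) and the relative
delta-area versus k−1 (defined as the AUC itself at k = 2). The rule —
smallest k whose *next* delta-area falls below 0.1 — makes explicit a
choice that is usually made by eye from the same curves; the full table is
always emitted so a user can override. Note that for an ideal 0/1
consensus the trapezoid AUC differs from the step-function value 1 − p by
at most half a grid cell (≤ 0.005·p).

## ssGSEA

Scores use the integrated running-sum statistic: within each sample, genes
are ranked over the full matrix universe (average ranks for ties; walk
order among tied genes fixed by gene index for determinism). For a set S,
the score is Σ_i [P_hit(i) − P_miss(i)] over all gene positions, where
P_hit accumulates in-set weights rank^α normalized by the set's total
weight and P_miss is the uniform step over out-of-set genes. α defaults to
0.25; α = 0 gives uniform weights. This is the integral form, not the
max-deviation statistic, and it is invariant to any monotone transform of
a sample's expression. Sets covering the whole universe have no out-of-set
step and are dropped with a warning.

The only normalization applied afterwards is the per-signature 0-floor
min–max: (x − min)/(max − min) across samples, constant rows mapping to 0.
No cross-sample rank rescaling is applied before it; the floor
normalization supersedes it. Group comparisons of scores use the Wilcoxon
rank-sum test (exact for small tie-free samples) for two groups and
Kruskal–Wallis for more, BH-adjusted across signatures, with conventional
star annotations at 0.05/0.01/0.001.

## Differential expression

Two independent callers run per gene, and only their intersection counts:

* **Method A** — moderated t: pooled two-sample variance shrunk toward the
  grand median variance with weight w = n_genes/(n_genes + 50) *on the
  median* (heavier moderation for larger panels; under a global null all
  genes share a variance and the moderation is exact), df = n₁ + n₂ − 2.
* **Method B** — two-sided Wilcoxon rank-sum; exact enumeration for
  tie-free samples up to 12 observations, otherwise the normal
  approximation with tie correction.

log-fold-change is the difference of group means on the log scale (second
sorted group label minus first). BH adjustment is applied within each
method; a DEG must pass both adjusted thresholds (raw-p mode by flag) and
|logFC| above the cutoff (defaults 0.05 and 1.0). Cross-cohort signatures
are the ordered intersection of per-cohort DEG lists. The dual-caller
intersection and the cross-cohort overlap are the procedural core; the
specific second caller is a rank test because the pipeline consumes
continuous matrices, not counts.

## Score model

Candidate signature genes are filtered by univariate Cox Wald p < α
(default 0.05, raw p; BH by flag — "prognostic significance" is
conventionally reported unadjusted at this step). Retained genes are
centered and scaled to unit variance across the training cohort
(correlation PCA, making the score invariant to per-gene affine
transforms), and the SVD of the standardized matrix gives the first two
principal directions, each signed so its largest-|loading| entry is
positive. The raw score of a sample is its PC1 projection plus its PC2
projection; standardizing by the training mean X and SD (ddof = 1) yields
training scores with mean 0, SD 1 to machine precision. Rank-1 signature
matrices fall back to PC1 alone with a warning; SD = 0 is an error.

The Σ(PC1_g + PC2_g) formula is read as the per-sample projection (sum
over genes of loading × expression); the alternative reading — a sum of
loadings alone — is sample-independent and therefore meaningless as a
per-sample score.

Because PCA signs are arbitrary, the model is oriented after fitting: a
univariate Cox fit of the training scores decides the joint sign of both
components so that higher score ⇒ higher hazard. Orientation is
deterministic and idempotent, and negating all loadings before orientation
changes nothing after it. The high/low split is at the scored cohort's
median, ties to "low" (deterministic); a fixed external cutoff may be
supplied instead. Applying the model to a second cohort uses the
training-cohort centering, scaling, X and SD — a true out-of-sample
transform — with per-cohort refitting available by flag since scoring each
cohort on its own scale is an equally defensible convention.

## Survival statistics

Kaplan–Meier curves carry Greenwood variances
(var S(t) = S(t)² Σ d_i/(n_i(n_i − d_i))); when the last at-risk group is
exhausted the Greenwood sum diverges and the variance is reported as 0 for
the degenerate S = 0 tail. Confidence bands are plain linear-scale
±1.96·SE clipped to [0, 1]. Median survival is the first event time with
S(t) ≤ 0.5, without interpolation. The log-rank statistic is the standard
multi-group observed-minus-expected chi-square with hypergeometric
variances and df = groups − 1; with two groups it coincides with the Cox
score test at β = 0.

Cox fits maximize the partial likelihood by Newton–Raphson with
step-halving, converging when the largest score component drops below
1e-8 (at most 50 iterations). Efron tie handling is the default — the
convention of the reference survival implementations, and the right choice
for day-granularity data — with Breslow retained; the two agree to 1e-9 on
tie-free data. Covariates are centered internally for conditioning;
categorical covariates are one-hot expanded against the first sorted
level. Monotone-likelihood separation (|β| > 15) is capped with a warning
rather than allowed to diverge. Implementation was verified against grid
maximization of the partial likelihood and against external Cox fits to
12 digits.

## Co-expression modules

A deliberately compact weighted-network variant: unsigned adjacency
a_ij = |cor(i,j)|^β; soft threshold β chosen as the smallest power whose
signed scale-free fit R² (log-binned degree distribution regression,
negative slope counted positive) reaches 0.85, else the argmax, with the
full fit table reported and a forced power accepted. Desk-scale panels of
tens of genes are rarely scale-free, so the argmax fallback governs there
and scatters across seeds; on such panels a forced conventional power
(12 for unsigned networks) is the reproducible choice and is what the
bundled tests use.

Topological overlap is the standard unsigned formula
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij); modules come
from an average-linkage tree on 1 − TOM with a *static* cut at height 0.99
(dynamic tree cutting is out of scope; the static cut is simpler,
deterministic and adequate at desk scale — a documented divergence from
the reference package's default). Clusters under min_module_size (default
30) are grey. Module eigengenes are the first PC of the module's
standardized expression, unit variance, sign-oriented to correlate
positively with the module mean profile; module pairs with eigengene
correlation above merge_cut (default 0.75) merge iteratively,
most-correlated pair first. Gene significance is the absolute Pearson
correlation of a gene with a trait, module membership the signed
correlation with the module eigengene; hub genes satisfy GS ≥ 0.2 and
MM ≥ 0.8 (the customary thresholds, both exposed).

## Correlation and association utilities

`correlate` offers Pearson and Spearman with two-sided p-values from the
t approximation, replaced by the exact permutation distribution of the
coefficient for n ≤ 9 (fully enumerated, vectorized). Association panels
BH-adjust across covariates; response-group comparisons use rank tests on
the score plus a chi-square test (without continuity correction) on the
high/low × response contingency table. Distance correlation is not
implemented; the rank and product-moment coefficients cover every
association the pipeline reports.

## Synthetic cohorts

The generator emulates exactly the structure the analysis assumes: two
latent patterns in fixed ~50/50 proportion (shuffled by seed); a regulator
panel whose per-gene means shift by ±δ/2 between patterns with alternating
shift directions (a panel moving coherently in one direction would be
invisible to correlation-based sample clustering, and real
writer/eraser/reader panels move both ways); two gene programs driven by
per-sample latent factors f = ±δ·z + N(0,1), opposite in sign (immune high
in pattern 1, stemness in pattern 2), whose unit-variance idiosyncratic
component gives each program internal co-expression beyond the pattern
signal — without it the two anti-correlated programs would form a single
unsigned co-expression module by construction; optional overlap genes
loading on the average of both factors; and background N(0, noise_sd)
genes. Survival is exponential with hazard h₀·exp(β_surv·z),
z = ±1/2 by pattern, under independent exponential censoring whose rate is
tuned to the requested censored fraction; proportional hazards holds by
construction. Defaults used throughout the documented workflows:
δ = 3, noise_sd = 1, β_surv = 0.7, h₀ = 0.01, 30% censoring, n = 300 per
cohort, 21 regulators, programs of 40–50 genes with 10% overlap.

What the generator does **not** emulate: count-level noise
(negative-binomial dispersion), batch effects, library-size artifacts,
gene–gene correlation beyond the two programs, informative censoring, and
any real biology of the signatures. Passing recovery tests therefore shows
the pipeline correctly inverts its own generative assumptions — pattern
recovery, signature recall, hazard-coefficient recovery, type-I control —
not that it would make the same calls on a real cohort.

## Test and verification scale

The bundled tests and the acceptance script run the recovery experiments
at n = 300 samples, 600 genes and 200 resamples over 10–50 seeds, the
calibration experiments at 2000 replicates, and every exact-oracle
comparison on ≤10-element instances at 1e-9 or tighter. These sizes keep
the full suite in the minutes range on a single CPU while leaving the
Monte-Carlo error of the reported rates well inside the asserted bands.

## Known limitations

* Method A is a variance-moderated t on continuous values, not a count
  model; matrices of raw counts should be transformed upstream.
* The static tree cut cannot split nested modules the way dynamic cutting
  can; module counts on real data will differ from the reference package.
* The score's cross-cohort transfer assumes comparable log-scale
  normalization between cohorts; it does not correct batch effects.
* Exact Wilcoxon enumeration is limited to small tie-free samples; ties
  switch to the corrected normal approximation regardless of n.
* The k-selection threshold (0.1 on relative delta-area) is a convention
  made explicit, not an inference procedure; inspect the CDF curves.
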