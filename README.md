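# regscore

Tumors differ in how heavily their transcriptomes carry reversible RNA
modifications, and the expression of the writer/eraser/reader proteins that
control those marks stratifies patients into distinct *modification
patterns* with different immune microenvironments, stemness programs and
survival. `regscore` implements that analysis as a reusable, tested Python
pipeline for anyone with a gene-by-sample expression matrix, a clinical
table and a regulator gene list:

1. **Consensus clustering** of samples on the regulator panel
   (resampled co-clustering frequencies; CDF/delta-area selection of the
   number of clusters k).
2. **Single-sample gene-set enrichment (ssGSEA)** of immune-cell and
   pathway signatures, with a 0-floor min–max normalization per signature,
   to quantify microenvironment infiltration per sample.
3. **Dual-method differential expression** between the two clusters
   (moderated t *and* Wilcoxon rank-sum; a gene counts only when both
   methods call it), repeated per cohort, with the **cross-cohort overlap**
   of DEG lists forming the candidate signature.
4. **A per-sample score**: the signature is filtered by univariate Cox
   significance, each surviving gene standardized, and the score of sample
   *s* built from the first two principal components,

   score(s) = [ Σ_g (PC1_g + PC2_g) · x_gs − X ] / SD,

   where X and SD are the mean and standard deviation of the raw sums in
   the training cohort. The sign is oriented so higher score ⇒ higher
   hazard; the cohort median splits samples into high/low groups.
5. **Survival statistics**: Kaplan–Meier with Greenwood variance, log-rank
   tests, and univariate/multivariate Cox proportional-hazards fits
   (Newton–Raphson, Efron or Breslow ties) with forest-table output.
6. **Co-expression modules** (compact weighted-network variant): soft
   threshold by scale-free fit, topological-overlap clustering, module
   eigengenes, module–trait correlation, gene significance / module
   membership and hub-gene extraction.
7. A **synthetic-cohort generator** with two latent patterns, regulator
   shifts, immune/stemness gene programs and pattern-dependent exponential
   survival — the ground truth every recovery test is scored against.

The statsmodels-style front end ties the score construction together:
`M6AScoreModel(expr, signature, surv).fit()` returns an `M6AScoreResults`
with scores, the Cox fit of the score, KM curves and a `summary()` table.

## Worked example

```python
import regscore as rs

# synthetic cohort: 300 samples, two latent patterns, survival signal
expr, truth = rs.generate_cohort(n_samples=300, n_genes=600, n_regulators=21,
                                 delta=3.0, program_size=40, overlap_frac=0.1,
                                 noise_sd=1.0, seed=1, beta_surv=0.7)
surv = rs.generate_survival(truth, baseline_hazard=0.01, censor_rate=0.3, seed=2)

# cluster on the regulator panel, k = 2..4
regs = sorted(truth.regulator_effect)
runs = [rs.consensus_run(expr, regs, k, n_resamples=200, seed=3)
        for k in range(2, 5)]
table = rs.cdf_and_delta(runs)
k = rs.select_k(table, 4)                       # -> 2

# differential expression between the two clusters -> candidate signature
de = rs.de_test(expr, runs[0].assignment)
degs = rs.call_degs(de, alpha=0.05, lfc=1.0)    # -> 93 genes

# score model with survival diagnostics
res = rs.M6AScoreModel(expr, degs, surv).fit(alpha=0.05)
print(res.summary())
```

prints (seeds as above):

```
                       quantity       value
0  signature genes (candidates)   93.000000
1  signature genes (prognostic)   91.000000
2                samples scored  300.000000
3             score HR per unit    1.271185
4           score HR 95% CI low    1.104381
5          score HR 95% CI high    1.463184
6                   score Cox p    0.000828
7   log-rank chi2 (high vs low)   20.500354
8      log-rank p (high vs low)    0.000006
```

91 of the 93 cluster-derived genes carry univariate prognostic signal
(nearly all, because in this simulation the whole cluster contrast is
hazard-linked); one unit of the standardized score multiplies the hazard by
≈1.27, and the median split separates survival decisively (log-rank
p ≈ 6e-6) — the high-score group is the short-survival group by
construction of the sign orientation.

The same flow is available from the shell:

```bash
regscore simulate --n-samples 300 --seed 1 --out-dir sim/
regscore cluster --expression sim/expression.tsv --genes sim/regulators.gmt \
                 --kmax 4 --resamples 200 --seed 3 --out-dir clust/
regscore run --config config.yaml     # full two-cohort pipeline
```

with a config of the form

```yaml
cohorts:
  - name: train
    expression: train/expression.tsv
    clinical: train/clinical.tsv
  - name: valid
    expression: valid/expression.tsv
    clinical: valid/clinical.tsv
regulators_gmt: regulators.gmt
signatures_gmt: signatures.gmt    # optional: enables the ssGSEA stage
training_cohort: train
out_dir: out/
k_max: 5
n_resamples: 1000
seed: 7
```

The run writes every intermediate table (consensus matrices, CDF/delta
table, cluster and score assignments, DE tables, the prognostic filter
report, the score model JSON, Cox forest tables, ssGSEA scores and group
tests) plus a `manifest.json` recording versions, parameters, seeds and
input hashes; re-running the same config and seed reproduces every table
byte for byte.

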