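# Methods

`combosig` implements a complete analysis chain for combination-treatment
transcriptomics — from raw bead-array-style intensities to synergy gene
sets, per-sample enrichment profiles, cohort immune stratification, and
expression-split survival analysis — together with a synthetic-data
generator that plants known truth at every stage. This note records the
models, the defaults and why they were chosen, the numerical conventions,
and what the synthetic benchmarks do and do not demonstrate.

## The synthetic study

The generator emulates a three-drug factorial screen in a triple-negative
breast cancer cell line: eight arms — vehicle (Veh), entinostat (E, an HDAC
inhibitor), all-trans retinoic acid (A), doxorubicin (D), and the
combinations EA, ED, AD, EAD — with replicates assigned round-robin to
batches so that every arm appears in every batch whenever the replicate
count is at least the batch count. Expression is simulated on the log2
scale as

    x_gs = baseline_g + batch_shift_{b(s)} + effect_{g, arm(s)} + ε_gs,
    ε ~ N(0, σ²),

optionally exponentiated to a raw intensity scale so the full preprocessing
chain has realistic input. Gaussian log-scale noise is the simplest model
consistent with quantile-normalized intensities; the batch effect is an
additive per-gene shift drawn once per batch (σ_batch = 0.3), which is the
kind of artifact per-gene batch mean-centering removes exactly.

Planted structure under the default effect model: an interferon (IFN)
module (60 genes) strongly up in ED/EAD (+1.8), a cell-cycle module
(120 genes, a stand-in for MYC/E2F/G2M-style proliferation programs) down
in D-containing arms and most strongly in ED/EAD (−1.5), a growth-arrest
module (50 genes) up in E-containing arms, and per-arm background
signatures whose up/down mix is set by `fraction_up`. The entinostat
default `fraction_up = 0.96` mirrors the strongly upward skew HDAC
inhibition produces in such screens; it is a generator parameter, not a
claim about any particular dataset. Default sizes — 2,000 genes,
4 replicates/arm, residual σ = 0.3 — keep every benchmark in the seconds
range while leaving planted effects at ≥4× noise, where the downstream
stages should recover them.

The cohort generator draws a latent infiltration variable from a
3-component location mixture (locations −2/0/+2, within-component σ = 0.4,
equal weights) and loads it on a core immune module (loading 1.0) and an
IFN module (loading 0.8), with a per-gene Uniform(0.6, 1.4) loading jitter
and residual σ = 0.5. The jitter matters: with perfectly uniform loadings
the immune-restricted profiles would differ between samples by a constant
shift only, and correlation distance would carry no signal. Because both
module scores average 50 genes, the shared latent factor dominates and
their Spearman correlation sits near 0.99 at the defaults — a deliberately
clean planted association, not a calibration to any published cohort
correlation.

Survival times are exponential with rate `λ0 · exp(coef · score)`, censored
at the minimum of an independent exponential draw and an administrative
horizon. Event times and censoring draws are all seeded; identical
(config, seed) reproduces every output byte for byte.

What the generator does **not** emulate: probe-level bead chemistry or dye
bias, count-based noise, correlated gene-gene structure beyond the planted
modules, real cohorts' marginal distributions or subtype structure, and
informative censoring. Passing the recovery benchmarks therefore shows the
pipeline is correct under its own assumptions, not that it would reproduce
any specific published dataset.

## Preprocessing

* **Background subtraction**: per sample, subtract the 5th-percentile
  intensity and floor at ε = 1.0 intensity unit. The percentile stands in
  for control-probe background estimates, which require raw probe data.
* **Quantile normalization**: each column's sorted values are replaced by
  the across-column mean of sorted values. Tied values within a column
  receive the mean of the reference values their rank span covers (the
  common convention). On continuous (tie-free) input the operation is
  exactly idempotent and all column distributions coincide; with ties the
  tie rule perturbs the reference marginally on re-application.
* **log2 transform** with a positive pseudo-offset (default 1.0).
* **Batch centering**: per gene and batch, subtract the batch mean and add
  back the gene's grand mean. This residualizes an additive batch term
  exactly, preserves gene-level means to 1e−10, and refuses designs where a
  batch coincides 1:1 with an arm (the correction would absorb the arm
  effect). More elaborate batch models (empirical-Bayes, surrogate
  variables) are out of scope by design.
* **PCA**: SVD on gene-centered data, no per-gene scaling (standard for
  expression QC). Component signs are fixed by making each loading's
  largest-magnitude entry positive, so results are fully deterministic.

## Differential expression and signatures

The per-gene statistic is a variance-shrinkage moderated t. With pooled
two-sample variance s², residual degrees of freedom df, and prior weight
d0 (default 4), the moderated variance is

    s²_mod = (d0 · s̄² + df · s²) / (d0 + df),

where s̄² is the across-gene mean variance; p-values use a t distribution
on df + d0 degrees of freedom. At d0 = 0 this reduces exactly to the
ordinary pooled-variance t (tested against the textbook formula). The
shrinkage target and prior are intentionally simple — the point is
stability at 2–4 replicates per arm, not full empirical-Bayes machinery.

BH-FDR is the step-up procedure computed directly (q(i) = min_{j≥i}
p(j)·m/j on sorted p-values); it is cross-checked against statsmodels in
the tests. Signatures apply the double threshold |FC| ≥ 2 and q ≤ 0.05. A
**synergy set** for a combination contains genes passing the thresholds
against *both* single agents with a consistent direction — the conservative
reading of "regulated beyond either single agent"; a union mode (either
contrast, direction conflicts still excluded) is available since the
stricter/looser choice is genuinely open. "Top differentially expressed
across arms" is operationalized as the across-arm one-way F ranking with
ceil(fraction·G) genes returned and id-lexicographic tie-breaks.

## Clustering

Distances are 1 − Pearson (default) or euclidean; linkage is average by
default (complete, single, ward available), via scipy's agglomerative
implementation. "Supervised" clustering of a gene set means: restrict the
gene axis to the set, then cluster samples unsupervised on the restriction.
Flat cuts come from the merge history, so a k-cut always refines the
(k−1)-cut.

## Enrichment scoring

The per-sample scorer is an unweighted Kolmogorov–Smirnov running-sum
statistic: rank the sample's genes by descending expression (ties broken by
gene id), add +1/|S∩U| at members and −1/|U∖S| elsewhere, and report the
maximum-magnitude deviation with its sign. Scores lie in [−1, 1], depend
only on within-sample ranks, and are invariant to any strictly monotone
per-sample transform. This is a deliberate simplification of kernel-based
per-sample enrichment methods such as GSVA — the package documents the
substitution and never claims numeric parity with them. When the largest
positive and negative deviations tie in magnitude, the one reached earliest
in the ranking wins; this tie rule keeps the complement antisymmetry
score(S) = −score(U∖S) exact at balanced set sizes, which a fixed-sign rule
would break.

Group-level testing is a textbook one-way F per set across arms with BH
across sets; identical data yields F = 0, p = 1 by convention (no evidence
of a group effect). Preranked testing scores a set against an external
strict ranking and compares |score| to a null of random same-size member
sets; p = (1 + #{|null| ≥ |observed|}) / (n_perm + 1), two-sided on
magnitude with the direction read from the observed sign.

## Immune stratification and the gene-wise permutation test

A **module score** is the per-sample mean of gene-wise z-scores
(sample-variance normalization, ddof = 1); zero-variance members are
dropped with a warning. Stratification clusters samples on the
immune-set-restricted matrix — euclidean/ward by default, because under
near-uniform module loadings correlation distance between samples is
dominated by noise — and relabels the k-cut low → high by ascending mean
immune score. Group differences are tested with one-way ANOVA plus pairwise
two-sided Student t tests, each p multiplied by the number of pairs and
capped at 1 (Bonferroni).

The association between a target module (e.g. IFN) and the immune score is
tested against a **gene-wise permutation null**: draw n_perm random gene
sets of the target's size from the background universe (all genes minus the
immune core set), recompute Spearman's rho for each, and report
p = (1 + #{null ≥ observed}) / (n_perm + 1), one-sided "greater" by default
since the hypothesis is positive association. "Gene-wise" is read as
permuting gene identity, which leaves the infiltration score intact; a
sample-label permutation null is available behind `unit="samples"`. The
add-one estimator never reports zero: at the default n_perm = 10,000 the
smallest reportable p is 1/10,001 ≈ 1.0×10⁻⁴, i.e. "p < 0.001" is the
strongest statement such a test can support.

## Survival

Kaplan–Meier estimation is the product-limit formula over distinct event
times, with events processed before censorings at tied times (the standard
convention). The two-group logrank test sums hypergeometric means and
variances over pooled event times; the hazard ratio is the O/E ratio
(HR = (O_A/E_A)/(O_B/E_B)) with CI exp(log HR ± 1.96·√(1/E_A + 1/E_B)) —
this reuses the logrank machinery and avoids a Cox optimizer, at the price
of the usual O/E conservatism. A group with zero observed or expected
events raises a typed `HazardUndefinedError` rather than returning a
number. Expression splits use the median with ties going low (the
reproducible default; the cutoff is a parameter). The prognosis scan tests
each gene (or one combined mean-z score) per endpoint with BH across genes
within the endpoint; degenerate splits yield NaN rows excluded from the
adjustment. KM curves and logrank p-values are cross-checked against
lifelines in the tests; lifelines is never used in the implementation.

## Orchestration and reproducibility

The CLI (`combosig`) wraps the library thinly. `run-all` executes
simulate → preprocess → de → cluster → enrich → immune → survival from a
flat YAML config with a mandatory integer seed; per-stage seeds derive from
it as `(seed·1,000,003 + stage_index) mod 2³¹` with fixed stage numbering,
so any stage can be rerun alone and reproduce its output. A run directory
carries an `INCOMPLETE` marker until every stage finishes and a manifest
with the config hash and a sha256 per output; identical (config, seed)
gives identical output hashes.

`scripts/acceptance.py` re-runs the whole synthetic study at the default
sizes (2,000 genes × 32 samples; 500-sample cohort; 10,000 permutations)
and writes the measured quantities as JSON. The test-suite calibration
checks use reduced sizes (150–400 genes, 40–80 subjects, n_perm = 500,
200 seeds) chosen so the whole suite runs in well under a minute.

## Known limitations

* The moderated-t prior d0 is fixed, not estimated from the data.
* Quantile-normalization idempotence is exact only on tie-free input.
* The O/E hazard ratio is biased toward 1 relative to Cox estimates when
  hazards are strongly non-proportional.
* The enrichment scorer is unweighted; strongly expression-weighted
  enrichment (GSEA p ≠ 0) is intentionally not implemented.
* The generator's module effects are homogeneous within a module; real
  treatment responses are heterogeneous, so real-data sensitivity will be
  lower than the planted-recovery benchmarks suggest.
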