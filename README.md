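# combosig

Analysis pipeline for **combination-drug transcriptomics**: derive the gene
signature a drug combination induces beyond its single agents, score gene
sets per sample across treatment arms, stratify tumor cohorts by immune
infiltration with a gene-wise permutation association test, and relate
expression-derived scores to patient survival.

The package targets the common experimental design in epigenetic
combination therapy studies — e.g. an HDAC inhibitor (entinostat, E),
all-trans retinoic acid (A) and doxorubicin (D) applied singly and in
combination against vehicle (Veh), in replicate across array batches — and
ships a synthetic-data generator that emulates exactly this design with
planted ground truth, so every stage of the pipeline is testable end to
end.

## What it computes

* **Preprocessing** — per-sample background subtraction, quantile
  normalization, log2 transform, additive batch mean-centering, and PCA for
  design QC (`combosig.preprocess`).
* **Differential expression** — variance-shrinkage moderated t per gene
  (prior d0 = 4), Benjamini–Hochberg FDR, double-threshold signatures
  (|FC| ≥ 2, q ≤ 0.05), and **synergy sets**: genes passing the thresholds
  against *both* single agents of a combination with consistent direction
  (`combosig.diffexpr`).
* **Enrichment** — an unweighted running-sum (Kolmogorov–Smirnov style)
  per-sample gene-set score in [−1, 1], invariant to monotone per-sample
  transforms; across-arm ANOVA per set; preranked permutation testing
  (`combosig.enrichment`).
* **Immune stratification** — mean-z module scores, low/medium/high
  infiltration groups by clustering on a core immune set, ANOVA with
  Bonferroni post-hoc tests, Spearman correlation of module scores, and a
  gene-wise permutation test: the null re-draws random same-size gene sets
  and recomputes the association, p = (1 + #{null ≥ obs})/(N + 1)
  (`combosig.immune`).
* **Survival** — Kaplan–Meier product-limit curves, the two-group logrank
  test with O/E hazard ratio and 95% CI, median expression splits, and a
  per-gene prognosis scan across OS/RFS/DMFS endpoints
  (`combosig.survival`).
* **Simulation** — treatment-experiment, cohort, and survival generators
  with full ground truth and byte-level seed reproducibility
  (`combosig.synthdata`).

See `docs/methods.md` for the models, defaults, and numerical conventions.

## Worked example

```python
from combosig import synthdata as sd, diffexpr as de, immune
from combosig.preprocess import batch_center

# 8 arms x 4 replicates, 2,000 genes, planted module effects
design = sd.default_design()
effects = sd.default_effect_model(n_genes=2000)
matrix, annotation, truth = sd.simulate_treatment_experiment(design, effects, seed=1)
matrix = batch_center(matrix, annotation)

syn = de.synergy_set(
    de.gene_stats(matrix, annotation, "ED", "E"),
    de.gene_stats(matrix, annotation, "ED", "D"),
)
print(len(syn.up), len(syn.down))
```

prints `261 93`: at this seed, 354 genes are regulated by the ED
combination beyond *both* single agents at ≥2-fold and FDR ≤ 0.05 — 261
induced and 93 repressed. On the cohort side:

```python
model = sd.CohortModel(n_samples=500, n_genes=1000)
cohort, ctruth = sd.simulate_cohort(model, seed=2)
genes = cohort.gene_ids
imm = immune.module_score(cohort, [genes[i] for i in model.immune_idx])
res = immune.genewise_permutation_test(
    cohort, [genes[i] for i in model.ifn_idx], imm,
    n_perm=10_000, seed=3, exclude=[genes[i] for i in model.immune_idx],
)
print(round(res.rho, 2), res.p)
```

prints `0.99 9.999000099990002e-05`: the interferon-module score tracks the
immune-infiltration score at Spearman rho 0.99, and none of the 10,000
random same-size gene sets comes close, so the permutation p sits at its
floor 1/10,001 — the "p < 0.001" regime.

A full run from the shell:

```sh
combosig run-all --config config.yaml   # config: flat YAML with a seed
```

executes simulate → preprocess → de → cluster → enrich → immune → survival
into a run directory with a manifest of output hashes.

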