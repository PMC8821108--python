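# hapattern

Expression-pattern discovery and prognostic signature scoring for a
histone-acetylation regulator panel, written for bulk-transcriptomics
cohorts of the kind assembled in hepatocellular carcinoma studies: a
gene-by-sample expression matrix on log2(TPM+1) scale, a clinical table
with overall-survival follow-up, optional immune/pathway gene sets (GMT)
and an optional sample-by-drug AUC table.

The package is aimed at computational biologists who want the full chain —
pattern discovery, signature construction, survival stratification and
downstream association — as tested, seedable library code rather than a
collection of one-off scripts, together with a synthetic-cohort generator
that provides ground truth for every stage.

## What it computes

1. **Histone-acetylation patterns.** Samples are clustered on a regulator
   gene panel (writers/erasers/readers of the acetyl mark; 36 genes by
   default) by resampling consensus clustering: in each of *R* repetitions
   (default 1000) a random 80% of samples is partitioned by k-means on
   per-gene z-scores, and the consensus matrix records, for every sample
   pair, the fraction of co-sampled repetitions in which the pair
   co-clustered. The number of patterns k is selected by the relative
   delta-area elbow of the consensus CDF, with the proportion of ambiguous
   clustering (PAC) reported alongside; final assignments cut an
   average-linkage tree of 1 − consensus.
2. **Phenotype genes.** One-vs-rest moderated t-tests (empirical-Bayes
   variance shrinkage) between the patterns; DEGs are genes with
   adjusted P < 0.001 (Benjamini–Hochberg) and |FC| > 1.5, then filtered
   to those with prognostic value in univariate Cox models (Wald p < 0.05).
3. **HAscore.** Each prognostic DEG is z-scored across samples and the
   samples × genes z-matrix decomposed by SVD; a sample's HAscore is the
   sum of its coordinates on the first two principal components,
   `HAscore_s = PC1_s + PC2_s`, with each component oriented so that high
   score means high signature expression.
4. **Survival stratification.** The HAscore is dichotomized at the
   maximally selected rank statistic (the cutpoint maximizing the
   standardized two-group log-rank statistic over all admissible splits),
   and the groups are compared by Kaplan–Meier curves, log-rank tests and
   univariate/multivariate Cox proportional-hazards models (Efron tie
   correction, Newton–Raphson).
5. **Context.** ssGSEA enrichment of immune-cell and pathway gene sets
   (rank-based running sum, exponent α = 0.25), the EMT score (mean
   mesenchymal minus mean epithelial marker expression), hypergeometric
   over-representation of gene lists, Spearman screening of drug AUCs
   (hits at |Rs| > 0.3 and FDR < 0.05) and chi-square/Fisher tests of
   clinical features.

The synthetic-data module generates cohorts with three latent patterns
(A < C < B in mean expression), exponential survival whose log-hazard is
linear in the latent score, uniform non-informative censoring calibrated to
a target rate, and drug columns with planted Spearman correlations — so
every downstream claim can be checked against known truth.

## Worked example

```python
import numpy as np
import hapattern as hp

cfg = hp.CohortConfig(n_per_pattern=(75, 75, 150), seed=3)
expr, clinical, truth = hp.simulate_cohort(cfg)

cc = hp.ConsensusClustering(k_range=range(2, 7), reps=200, random_state=0)
cc.fit(expr.loc[list(truth.regulator_genes)].to_numpy().T)
print(f"chosen k = {cc.chosen_k_}, PAC = {cc.pac_[cc.chosen_k_]:.3f}")

de = hp.moderated_de(expr, cc.labels_)
degs = hp.select_degs(de, fc_thresh=1.5, adjp_thresh=0.001)
prognostic = hp.prognostic_screen(expr, clinical, degs, p_thresh=0.05)
print(f"{len(degs)} DEGs, {len(prognostic)} prognostic")

score = hp.hascore(expr, prognostic)
cut, stat = hp.best_cutpoint(score, clinical["os_time"], clinical["os_event"])
groups = np.where(score > cut, "high", "low")
chi2, _, p = hp.logrank_test(clinical["os_time"], clinical["os_event"], groups)
print(f"cutpoint = {cut:.2f} (max |z| = {stat:.2f}); log-rank p = {p:.2e}")

z = (score - score.mean()) / score.std()
fit = hp.cox_fit(clinical["os_time"], clinical["os_event"], z.to_numpy(),
                 names=("HAscore",))
lo, hi = fit.ci95[0]
print(f"HR per SD of HAscore = {fit.hr[0]:.3f} (95% CI {lo:.3f}-{hi:.3f})")

drugs = hp.simulate_drug_response(truth, n_drugs=50, n_true=10,
                                  rho_true=0.5, seed=4)
hits = hp.drug_correlation(score, drugs, rs_thresh=0.3, fdr_thresh=0.05)
print(f"{len(hits)} drug hits; strongest: {hits[0].drug} "
      f"(Rs = {hits[0].rs:.3f}, FDR = {hits[0].fdr:.2e})")
```

Output:

```
chosen k = 3, PAC = 0.000
236 DEGs, 236 prognostic
cutpoint = 2.90 (max |z| = 9.38); log-rank p = 6.53e-21
HR per SD of HAscore = 2.065 (95% CI 1.768-2.412)
10 drug hits; strongest: DRUG003 (Rs = 0.525, FDR = 6.17e-21)
```

The three planted patterns are recovered crisply (PAC = 0 at k = 3), all
200 phenotype genes plus the co-regulated regulators pass the DEG and
prognostic filters, the high-HAscore group has sharply worse survival
(the simulated hazard rises with the latent score), and the drug screen
recovers exactly the ten planted correlations.

The same stages are available from the shell: `hapattern simulate`,
`cluster`, `enrich`, `de`, `score`, `surv`, `assoc`, and `hapattern run
--config run.yaml --out results/` for the whole pipeline (every stage
output as TSV plus a run manifest; reruns with the same config and seed
are byte-identical). The YAML config fields mirror
`hapattern.PipelineConfig` — paths (`expression`, `clinical`, `panel`,
optional `gene_sets`, `emt_gene_sets`, `drugs`, `drug_annotation`) and the
parameters shown above.

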