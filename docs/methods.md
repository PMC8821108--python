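# Methods

This note records the models, the numerical choices, and what the test
bench does and does not demonstrate.

## Data model and preprocessing

Expression is a genes × samples matrix on log2(TPM+1) scale. `fpkm_to_tpm`
renormalizes linear FPKM per sample to sum to 10^6 (scale-invariant and
idempotent); the log step is separate and explicit so callers control the
scale. Gene identifiers are matched by exact, case-sensitive string
equality throughout — no alias resolution.

Batch adjustment is a per-gene location-scale harmonisation: within each
batch a gene is standardized by the batch mean and SD (ddof = 1) and
re-expressed on the gene's pooled mean and SD. There is no empirical-Bayes
shrinkage of batch parameters; the package deliberately implements the
simplest adjustment whose post-conditions (equal per-gene batch means and
SDs, pooled mean invariant) are checkable to 1e-8. A gene with zero
variance inside a batch is mean-centered only, with a warning.

Missing or non-numeric cells cause the whole gene row to be dropped at load
time (with a warning) rather than imputed: the downstream SVD and
rank-based enrichment require complete rows, and any imputation scheme
would leak structure into the consensus and signature steps.

## Consensus clustering

Inner clusterer: k-means with multiple restarts on per-gene z-scores,
Euclidean distance. It is deterministic given a seed and cheap enough for
1000 repetitions. Defaults: `reps=1000`, `subsample_frac=0.8`, no gene
subsampling. The RNG stream is documented in the module docstring
(subsample indices, then one k-means seed, per repetition, from a single
`default_rng(seed)`) so an external loop can replay it exactly; the test
bench does precisely this.

Model selection: the area A(k) under the empirical CDF of off-diagonal
consensus values is computed per k; the selection statistic is
Δ(2) = A(2) and Δ(k) = (A(k) − A(k−1))/A(k−1) for k > 2, maximized over
the (contiguous, from 2) k range with ties broken toward smaller k. PAC —
the CDF mass strictly inside (0.1, 0.9) — is reported alongside, and a
PAC above 0.5 at the chosen k logs a "weak cluster structure" warning
(single-blob inputs land here and select k = 2, which should be read as
"no structure", not "two clusters"). Pairs never co-sampled (possible at
very low rep counts) get consensus 0 with a warning; at the default
settings the probability of such a pair is negligible.

Final assignments cut an average-linkage dendrogram of 1 − consensus.
Labels are arbitrary integers but deterministic given the input.

## Moderated differential expression

One-vs-rest contrasts per pattern, union of selected genes across
contrasts. Per contrast the two-group pooled variance (d = n − 2 df) is
shrunk toward a prior (d0, s0²) obtained by matching the mean and variance
of log s² to the scaled log-F model via digamma/trigamma moment inversion
(the trigamma equation is solved by Newton iteration). When the observed
spread of log s² does not exceed what the residual df alone produces, the
excess-variance moment is non-positive and the fit falls back to d0 = 0 —
the ordinary pooled t-test — with a warning. A gene with zero fold change
and zero variance is reported as t = 0, p = 1.

"|FC| > 1.5" is read as linear fold change on log2 data, i.e.
|log2FC| > log2(1.5). The threshold and the adjusted-p cutoff (BH within
contrast) are parameters, not constants.

## ssGSEA

Per sample, genes are ordered by (expression descending, identifier
ascending) — the tie-break makes scores fully deterministic — and the
enrichment score is the sum over all rank positions of the difference
between the weighted in-set empirical CDF and the uniform out-of-set CDF.
Weights are rank^α with per-sample ranks 1..G used in place of raw
expression, making the score invariant under monotone transforms — the
right property when microarray and RNA-seq cohorts are mixed. α defaults
to 0.25, the conventional ssGSEA exponent. Scores are used comparatively;
the optional normalization is per-set min-max across samples. No
permutation significance is attached to individual enrichment scores
(group comparisons downstream are rank-based tests).

## Survival machinery

Cox models maximize the Efron-tie-corrected partial likelihood by
Newton–Raphson with step-halving; convergence at max |score| < 1e-8 or 50
iterations; standard errors from the inverse observed information.
Covariates are centered internally for numerical stability (this does not
change the estimates). Monotone likelihoods (complete separation) are
detected when a coefficient passes ±20 on the partial-likelihood scale;
the coefficient is capped there, the fit flagged, and a warning issued.
Efron rather than Breslow because discretized follow-up times produce
heavy ties, where Breslow is noticeably biased.

The cutpoint search evaluates the standardized two-group log-rank
statistic at every distinct score value whose split leaves at least
⌈minprop·n⌉ subjects on each side (minprop default 0.1), returning the
argmax of the absolute statistic, ties toward the smallest cutpoint. The
log-rank test and the cutpoint statistic share one O−E/variance kernel,
so z² at a split equals the two-group log-rank chi-square there exactly.
No multiplicity-adjusted p-value is attached to the selected maximum: the
cutpoint is used for stratification only, and group significance is
reported by the ordinary log-rank test. When the clinical table carries
batch labels (each with ≥ 20 samples) the pipeline selects a cutpoint
within each batch and pools the resulting high/low groups, keeping the
dichotomization insensitive to residual between-cohort location shifts.

Times are unitless; cutpoints and hazard ratios are consistent within any
cohort whose times share one unit.

## HAscore

The signature matrix (samples × prognostic genes) is z-scored per gene and
decomposed by SVD; a sample's score is its coordinate on PC1 plus its
coordinate on PC2, raw (not variance-normalized). Because singular-vector
signs are arbitrary, each component is oriented to correlate non-negatively
with the per-sample mean z-expression of the signature, pinning "high
HAscore = high signature expression" across linear-algebra backends. The
score formula is read as each sample's *projection* onto the two
components — the alternative reading (summing the loading vectors into a
sample-independent constant) is degenerate, and a unit test demonstrates
the two are not equal. The score is invariant to gene/sample order and to
positive per-gene affine rescaling.

## Drug and clinical association

Spearman rs is the Pearson correlation of mid-ranks; p-values use the t
approximation for n > 10 and exhaustive permutation enumeration for
n ≤ 10 (exact under ties). Drug hits require |Rs| strictly above the
threshold and BH FDR below it, with the GDSC orientation documented as
higher AUC = more resistant; negative-Rs hits are therefore drugs to which
high-score samples are more sensitive. Contingency tests use Pearson
chi-square without continuity correction, switching to Fisher's exact test
when any expected cell is below 5 and the table is 2×2; sparse larger
tables fall back to chi-square with a warning (exact r×c tests are out of
scope).

## Synthetic cohorts

The generator produces the structure the analysis assumes and nothing
more: regulator and phenotype genes are Gaussian with pattern means at
−shift, 0, +shift (patterns A, C, B; unit within-pattern SD), noise genes
standard normal, and the latent score is the standardized mean of the
phenotype genes. Survival is exponential with hazard
`baseline_hazard · exp(hazard_coef · latent)` — the simplest generator
consistent with proportional hazards, which is all the analysis assumes —
and censoring is independent Uniform(0, c) with c solved by root-finding
so the expected censored fraction hits `censor_rate`. Drug columns with
planted correlations use a Gaussian copula on the normal scores of the
latent (Pearson ρ = 2·sin(π·ρ_s/6) to hit the requested population
Spearman), alternating sign; the remainder are independent noise. Batch
labels, when requested, are assigned independently of pattern.

Reference conditions used throughout the bench: 30/30/60 samples (A/B/C),
shift 2.5, 36 regulators, 200 phenotype genes, 500 noise genes, hazard
coefficient 0.7 per SD, 30% censoring; power-hungry checks double the
cohort to 75/75/150.

What the generator does **not** emulate: count-level noise and
mean-variance coupling of RNA-seq, correlated gene-gene noise within
pattern blocks beyond the shared mean shift, informative censoring,
batch effects in expression, and probe-level artefacts of microarrays.
Passing tests therefore demonstrate correctness of the computations and
recoverability of planted structure — not robustness to every failure
mode of real cohorts.

## Problem sizes in the test bench

The module defaults stay at the analysis-scale settings (1000 consensus
repetitions); the bench runs the same code at reduced sizes chosen as the
smallest that still make each check sharp: consensus tests use 60–300
repetitions, the DE null calibration uses 2000 genes × 50 samples with
40–200 replicates, Cox recovery uses 50–100 replicates at n = 500, and the
drug screens use 20 replicates of 50 drugs. The acceptance script prints
each quantity with the problem size it was measured at.

## Known limitations

- k-means is the only inner clusterer; strongly non-spherical pattern
  geometry would favour a different inner algorithm.
- The moderated test assumes roughly constant within-group variance on the
  log2 scale; raw counts should go through a variance-stabilizing
  transform first.
- Fisher's exact test is 2×2 only.
- PC sign orientation uses the mean signature z-expression; a signature
  whose PC is exactly orthogonal to that mean would keep the backend's
  arbitrary sign (deterministic for a fixed backend).
- The batch adjustment is location-scale only and assumes each batch has
  enough samples (≥ 2, realistically many more) to estimate per-gene
  moments.
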