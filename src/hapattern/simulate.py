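"""Synthetic cohorts with known latent structure.

The generator emulates the statistical skeleton the analysis assumes: a
regulator gene panel whose expression follows one of three latent activity
patterns (A < C < B in mean expression), downstream phenotype genes
co-regulated with the same patterns, pure-noise genes, proportional-hazards
survival whose log-hazard is linear in a per-sample latent score, and drug
AUC columns with planted Spearman correlations to that score.

Expression is generated directly on a log2-like scale (Gaussian around the
pattern mean, unit SD) rather than via read counts: every downstream
statistic in the pipeline is rank- or z-based, so count-level noise would
add cost without changing what the tests can show.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = ["CohortConfig", "SyntheticTruth", "DrugResponseTable",
           "simulate_cohort", "simulate_drug_response", "reference_config"]

#: pattern labels in increasing mean-expression order
_PATTERN_ORDER = ("A", "C", "B")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs for :func:`simulate_cohort`.

    ``n_per_pattern`` gives the sizes of patterns (A, B, C);
    ``pattern_shift`` is the separation, in within-pattern SD units, between
    adjacent pattern means (A at -shift, C at 0, B at +shift);
    ``hazard_coef`` is the log-hazard increase per SD of the latent score;
    ``censor_rate`` is the target fraction of censored subjects, achieved by
    independent Uniform(0, c) censoring with c solved numerically.
    """

    n_per_pattern: tuple[int, int, int] = (30, 30, 60)
    n_regulators: int = 36
    n_phenotype_genes: int = 200
    n_noise_genes: int = 500
    pattern_shift: float = 2.5
    hazard_coef: float = 0.7
    baseline_hazard: float = 0.1
    censor_rate: float = 0.3
    n_batches: int = 1
    seed: int = 0

    def __post_init__(self):
        if len(self.n_per_pattern) != 3 or any(n <= 0 for n in self.n_per_pattern):
            raise ValueError("n_per_pattern must be three positive counts")
        if min(self.n_regulators, self.n_phenotype_genes) <= 0 or self.n_noise_genes < 0:
            raise ValueError("gene counts must be positive")
        if self.pattern_shift < 0:
            raise ValueError("pattern_shift must be >= 0")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.n_batches < 1:
            raise ValueError("n_batches must be >= 1")
        if self.n_regulators + self.n_phenotype_genes + self.n_noise_genes < 2:
            raise ValueError("need at least 2 genes in total")
        if sum(self.n_per_pattern) < 4:
            raise ValueError("need at least 4 samples in total")


@dataclass
class SyntheticTruth:
    """Ground truth carried alongside a simulated cohort."""

    pattern_label: pd.Series          # per sample, in {A, B, C}
    latent_score: pd.Series           # standardized, drives the hazard
    regulator_genes: tuple[str, ...]
    true_prognostic_genes: frozenset[str]
    true_drug_correlations: dict[str, float] = field(default_factory=dict)


@dataclass
class DrugResponseTable:
    """Samples x drugs AUC matrix (higher AUC = more resistant) plus a
    drug -> target-pathway annotation."""

    auc: pd.DataFrame
    pathways: dict[str, str]

    def __post_init__(self):
        if self.auc.columns.duplicated().any():
            raise ValueError("duplicate drug names")
        if not np.isfinite(self.auc.to_numpy(dtype=float)).all():
            raise ValueError("AUC values must be finite")


def reference_config(seed: int = 0, **overrides) -> CohortConfig:
    """The reference synthetic cohort used throughout the test bench:
    30/30/60 samples, shift 2.5, hazard coefficient 0.7."""
    return CohortConfig(seed=seed, **overrides)


def _censor_scale(lam: np.ndarray, censor_rate: float) -> float:
    """Solve for c such that Uniform(0, c) censoring of Exp(lam_i) event
    times yields the target expected censored fraction."""

    def frac_censored(c):
        # P(C < T_i) with C ~ U(0,c) is (1 - exp(-lam c)) / (lam c)
        x = lam * c
        return float(np.mean((1.0 - np.exp(-x)) / x))

    lo, hi = 1e-9, 1.0
    while frac_censored(hi) > censor_rate and hi < 1e12:
        hi *= 10.0
    return brentq(lambda c: frac_censored(c) - censor_rate, lo, hi, xtol=1e-10)


def simulate_cohort(cfg: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate (expression, clinical, truth) for one cohort.

    Returns a genes x samples log2-scale expression DataFrame, a clinical
    DataFrame indexed by sample_id with os_time / os_event / batch / age
    columns, and the :class:`SyntheticTruth`.
    Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_a, n_b, n_c = cfg.n_per_pattern
    n = n_a + n_b + n_c
    labels = np.array(["A"] * n_a + ["B"] * n_b + ["C"] * n_c)
    # shuffle so sample order carries no information about pattern
    perm = rng.permutation(n)
    labels = labels[perm]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    mu = {"A": -cfg.pattern_shift, "C": 0.0, "B": cfg.pattern_shift}
    shift = np.array([mu[l] for l in labels])

    reg_names = [f"REG{i + 1:03d}" for i in range(cfg.n_regulators)]
    phe_names = [f"PHE{i + 1:03d}" for i in range(cfg.n_phenotype_genes)]
    noi_names = [f"NSE{i + 1:03d}" for i in range(cfg.n_noise_genes)]

    reg = rng.normal(loc=shift, scale=1.0, size=(cfg.n_regulators, n))
    phe = rng.normal(loc=shift, scale=1.0, size=(cfg.n_phenotype_genes, n))
    noi = rng.normal(loc=0.0, scale=1.0, size=(cfg.n_noise_genes, n))

    expr = pd.DataFrame(
        np.vstack([reg, phe, noi]),
        index=reg_names + phe_names + noi_names,
        columns=sample_ids,
    )

    latent = phe.mean(axis=0)
    latent = (latent - latent.mean()) / latent.std(ddof=1)

    lam = cfg.baseline_hazard * np.exp(cfg.hazard_coef * latent)
    t_event = rng.exponential(1.0 / lam)
    if cfg.censor_rate > 0:
        c = _censor_scale(lam, cfg.censor_rate)
        t_cens = rng.uniform(0.0, c, size=n)
        os_time = np.minimum(t_event, t_cens)
        os_event = (t_event <= t_cens).astype(int)
    else:
        os_time, os_event = t_event, np.ones(n, dtype=int)
    os_time = np.maximum(os_time, 1e-9)

    clinical = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "age": np.round(rng.normal(60.0, 10.0, size=n), 1),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if cfg.n_batches > 1:
        clinical["batch"] = [
            f"batch{b + 1}" for b in rng.integers(0, cfg.n_batches, size=n)
        ]

    truth = SyntheticTruth(
        pattern_label=pd.Series(labels, index=sample_ids, name="pattern"),
        latent_score=pd.Series(latent, index=sample_ids, name="latent_score"),
        regulator_genes=tuple(reg_names),
        true_prognostic_genes=frozenset(phe_names),
    )
    return expr, clinical, truth


def simulate_drug_response(truth: SyntheticTruth, n_drugs: int = 50,
                           n_true: int = 10, rho_true: float = 0.5,
                           seed: int = 0) -> DrugResponseTable:
    """Drug AUC columns with planted rank correlation to the latent score.

    The first ``n_true`` drugs are generated through a Gaussian copula so
    their population Spearman correlation with the latent score is
    approximately ``rho_true``, with alternating sign; the remaining columns
    are independent noise.  ``truth.true_drug_correlations`` is updated with
    the planted (signed) correlations.
    """
    if not 0 <= n_true <= n_drugs:
        raise ValueError("require 0 <= n_true <= n_drugs")
    if not abs(rho_true) < 1:
        raise ValueError("|rho_true| must be < 1")
    rng = np.random.default_rng(seed)
    latent = truth.latent_score.to_numpy()
    n = latent.size
    # normal scores of the latent make the copula exact in the population
    u = (pd.Series(latent).rank(method="average").to_numpy() - 0.5) / n
    from scipy.stats import norm
    z = norm.ppf(u)
    z = (z - z.mean()) / z.std(ddof=1)

    cols = {}
    planted: dict[str, float] = {}
    # Pearson rho on the copula that yields the requested population Spearman
    rho_p = 2.0 * np.sin(np.pi * rho_true / 6.0)
    for j in range(n_drugs):
        name = f"DRUG{j + 1:03d}"
        eps = rng.normal(size=n)
        if j < n_true:
            sign = 1.0 if j % 2 == 0 else -1.0
            cols[name] = sign * (rho_p * z + np.sqrt(1 - rho_p**2) * eps)
            planted[name] = sign * rho_true
        else:
            cols[name] = eps
    truth.true_drug_correlations = planted
    pathway_pool = ["Chromatin histone acetylation", "PI3K/MTOR signaling",
                    "RTK signaling", "ERK MAPK signaling", "DNA replication",
                    "Cell cycle", "Apoptosis regulation"]
    pathways = {name: pathway_pool[j % len(pathway_pool)]
                for j, name in enumerate(cols)}
    auc = pd.DataFrame(cols, index=truth.latent_score.index)
    auc.index.name = "sample_id"
    return DrugResponseTable(auc=auc, pathways=pathways)
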