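"""Moderated differential expression between pattern groups.

For each group a one-vs-rest contrast is tested per gene with a moderated
t-statistic: the two-group pooled residual variance s_g^2 (df d = n - 2) is
shrunk toward a prior (d0, s0^2) estimated from all genes by matching the
first two moments of log s_g^2 to the scaled log-F distribution implied by
the hierarchical model s_g^2 ~ s0^2 * F(d, d0):

    E[log s^2]   = log s0^2 + psi(d/2) - psi(d0/2) + log(d0/d)
    Var[log s^2] = psi'(d/2) + psi'(d0/2)

(psi, psi' the digamma/trigamma functions; the trigamma equation is
inverted by Newton iteration).  The moderated statistic

    t_g = log2FC_g / ( s~_g * sqrt(1/n_g + 1/n_rest) ),
    s~_g^2 = (d0 s0^2 + d s_g^2) / (d0 + d)

is referred to a t distribution with d0 + d degrees of freedom.  When the
observed variance of log s^2 is no larger than psi'(d/2) there is no excess
spread to attribute to a prior and the procedure falls back to the ordinary
pooled t-test (d0 = 0) with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import polygamma, psi
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

__all__ = ["moderated_de", "select_degs", "bh_adjust", "estimate_prior"]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _trigamma_inverse(y: float) -> float:
    """Solve polygamma(1, x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = polygamma(1, x)
        step = tri * (1.0 - tri / y) / polygamma(2, x)
        x = max(x - step, 1e-12)
        if abs(step) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Method-of-moments (d0, s0^2) from per-gene residual variances.

    Returns d0 = 0 (no shrinkage) with a warning when the spread of
    log s^2 does not exceed what d residual df alone would produce.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if not pos.any():
        raise ValueError("zero residual variance everywhere")
    z = np.log(s2[pos])
    excess = z.var(ddof=1) - polygamma(1, d / 2.0) if z.size > 1 else 0.0
    if excess <= 0:
        warnings.warn("no excess variance in log s^2; falling back to the "
                      "ordinary t-test (d0 = 0)")
        return 0.0, float(np.exp(z.mean()))
    d0 = 2.0 * _trigamma_inverse(float(excess))
    log_s0 = z.mean() - psi(d / 2.0) + psi(d0 / 2.0) - np.log(d0 / d)
    return float(d0), float(np.exp(log_s0))


def moderated_de(mat: pd.DataFrame, labels, prior=None) -> pd.DataFrame:
    """One-vs-rest moderated t-tests for every gene and group.

    ``mat`` is genes x samples on log2 scale; ``labels`` assigns each sample
    to a group (>= 2 groups, each with >= 2 samples).  Returns a tidy table
    with one row per gene per contrast: gene, contrast, log2FC, t_mod, p,
    adjP (BH within contrast).

    ``prior`` optionally fixes (d0, s0^2) instead of estimating them;
    ``prior=(0, anything)`` reproduces the ordinary pooled t-test.
    """
    labels = pd.Series(labels)
    if labels.index.inferred_type in ("integer", "range"):
        labels.index = mat.columns
    labels = labels.loc[mat.columns].astype(str)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sizes = labels.value_counts()
    if (sizes < 2).any():
        small = list(sizes[sizes < 2].index)
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")

    X = mat.to_numpy(dtype=float)
    n = X.shape[1]
    frames = []
    for g in groups:
        in_g = (labels == g).to_numpy()
        n_g, n_r = int(in_g.sum()), int((~in_g).sum())
        xg, xr = X[:, in_g], X[:, ~in_g]
        fc = xg.mean(axis=1) - xr.mean(axis=1)
        d = n - 2
        s2 = (xg.var(axis=1, ddof=1) * (n_g - 1)
              + xr.var(axis=1, ddof=1) * (n_r - 1)) / d
        d0, s02 = prior if prior is not None else estimate_prior(s2, d)
        s2_mod = (d0 * s02 + d * s2) / (d0 + d)
        denom = np.sqrt(s2_mod * (1.0 / n_g + 1.0 / n_r))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_mod = np.where(denom > 0, fc / np.where(denom == 0, 1, denom),
                             np.where(fc == 0, 0.0, np.inf * np.sign(fc)))
        df_total = d0 + d if np.isfinite(d0) else np.inf
        p = 2.0 * t_dist.sf(np.abs(t_mod), df_total)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        frames.append(pd.DataFrame({
            "gene": mat.index, "contrast": f"{g}_vs_rest",
            "log2FC": fc, "t_mod": t_mod, "p": p, "adjP": bh_adjust(p),
        }))
    return pd.concat(frames, ignore_index=True)


def select_degs(table: pd.DataFrame, fc_thresh: float = 1.5,
                adjp_thresh: float = 0.001) -> list[str]:
    """Genes passing adjP < adjp_thresh and |log2FC| > log2(fc_thresh) in any
    contrast (the fold-change threshold is given on the linear scale).

    The union across contrasts is returned deduplicated, ordered by first
    appearance in the table.
    """
    if not fc_thresh > 1:
        raise ValueError("fc_thresh must exceed 1 (linear fold change)")
    if not 0 < adjp_thresh < 1:
        raise ValueError("adjp_thresh must be in (0, 1)")
    hit = (table["adjP"] < adjp_thresh) & \
        (table["log2FC"].abs() > np.log2(fc_thresh))
    return list(dict.fromkeys(table.loc[hit, "gene"]))
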