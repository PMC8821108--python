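"""Associations of the HAscore with drug sensitivity and clinical features.

Drug screening follows the GDSC convention that a higher dose-response AUC
means a more resistant cell line, so a drug with negative Spearman rank
correlation to the score is one to which high-score samples are *more
sensitive*.  Hits must pass both |Rs| > 0.3 (strict) and BH FDR < 0.05 by
default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations, islice

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact, rankdata
from scipy.stats import t as t_dist

from .differential import bh_adjust
from .simulate import DrugResponseTable

__all__ = ["CorrelationHit", "spearman", "drug_correlation",
           "categorical_association"]

_EXACT_N_MAX = 10


@dataclass(frozen=True)
class CorrelationHit:
    """One drug passing the correlation screen."""

    drug: str
    rs: float
    p: float
    fdr: float
    direction: str        # "positive" (more resistant) / "negative"
    pathway: str = ""


def _spearman_rs(rx: np.ndarray, ry: np.ndarray) -> float:
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rs is the Pearson correlation of mid-ranks.  For n > 10 the p-value uses
    the usual t approximation with n - 2 df; for n <= 10 it is computed by
    exhaustive permutation (P(|rs_perm| >= |rs_obs|) over all n!
    pairings), which is exact even under ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector")
    rx, ry = rankdata(x), rankdata(y)
    rs = _spearman_rs(rx, ry)
    if n > _EXACT_N_MAX:
        rr = min(max(rs, -1.0), 1.0)
        if abs(rr) == 1.0:
            return rs, 0.0
        t = rr * math.sqrt((n - 2) / (1.0 - rr * rr))
        return rs, float(2.0 * t_dist.sf(abs(t), n - 2))
    # exhaustive permutation, chunked to bound memory
    rx_c = rx - rx.mean()
    denom = math.sqrt((rx_c**2).sum()) * math.sqrt(((ry - ry.mean())**2).sum())
    target = abs(np.dot(rx_c, ry - ry.mean()))
    total = math.factorial(n)
    count = 0
    perm_iter = permutations(ry)
    while True:
        chunk = np.array(list(islice(perm_iter, 200_000)))
        if chunk.size == 0:
            break
        dots = np.abs((chunk - ry.mean()) @ rx_c)
        count += int((dots >= target - 1e-9 * denom).sum())
    return rs, count / total


def drug_correlation(score: pd.Series, drugs: DrugResponseTable,
                     rs_thresh: float = 0.3, fdr_thresh: float = 0.05
                     ) -> list[CorrelationHit]:
    """Screen every drug's AUC for rank correlation with the score.

    Spearman per drug over the shared samples, BH adjustment across all
    drugs, then hits filtered by |rs| > rs_thresh (strict) and
    fdr < fdr_thresh, sorted by |rs| descending.
    """
    auc = drugs.auc
    shared = [s for s in auc.index if s in score.index]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared samples; need >= 10")
    sc = score.loc[shared].to_numpy(dtype=float)
    names, rs_all, p_all = [], [], []
    for drug in auc.columns:
        rs, p = spearman(sc, auc.loc[shared, drug].to_numpy(dtype=float))
        names.append(drug)
        rs_all.append(rs)
        p_all.append(p)
    fdr = bh_adjust(np.clip(p_all, np.finfo(float).tiny, 1.0))
    hits = []
    for drug, rs, p, q in zip(names, rs_all, p_all, fdr):
        if abs(rs) > rs_thresh and q < fdr_thresh:
            hits.append(CorrelationHit(
                drug=drug, rs=rs, p=p, fdr=q,
                direction="positive" if rs > 0 else "negative",
                pathway=drugs.pathways.get(drug, "")))
    hits.sort(key=lambda h: (-abs(h.rs), h.drug))
    for h in hits:  # output contract
        assert abs(h.rs) > rs_thresh and h.fdr < fdr_thresh
    return hits


def categorical_association(groups, feature) -> tuple[str, float, float]:
    """Test independence of a categorical feature from the high/low groups.

    Builds the contingency table; uses Fisher's exact test when any
    expected cell count is below 5 and the table is 2x2 (larger sparse
    tables fall back to chi-square with a warning), otherwise the Pearson
    chi-square test without continuity correction.  Returns
    (test name, statistic, p); Fisher's statistic is the odds ratio.
    """
    groups = pd.Series(groups).astype(str).reset_index(drop=True)
    feature = pd.Series(feature).astype(str).reset_index(drop=True)
    if groups.nunique() < 2:
        raise ValueError("groups has a single level")
    if feature.nunique() < 2:
        raise ValueError("feature has a single level")
    tab = pd.crosstab(groups, feature).to_numpy()
    res = chi2_contingency(tab, correction=False)
    if (res.expected_freq < 5).any():
        if tab.shape == (2, 2):
            odds, p = fisher_exact(tab)
            return "fisher", float(odds), float(p)
        warnings.warn("expected cell count < 5 in a table larger than 2x2; "
                      "falling back to chi-square")
    return "chi2", float(res.statistic), float(res.pvalue)
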