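"""Single-sample gene-set enrichment (ssGSEA) and over-representation tests.

The ssGSEA score of a gene set in a sample is a rank-based running-sum
statistic: genes are ordered by decreasing expression within the sample, and
the enrichment score is the accumulated difference between the weighted
empirical CDF of the in-set genes and the uniform empirical CDF of the
out-of-set genes,

    ES = sum_p [ P_in(p) - P_out(p) ],

summed over all rank positions p.  In-set weights are |rank|^alpha (per-sample
ranks 1..G used in place of raw expression, making the score invariant to
monotone transforms of the data), normalized to sum to 1 over set members;
the out-of-set CDF steps uniformly by 1/(G - m).  alpha defaults to 0.25,
the conventional ssGSEA exponent.

Ties are broken by (expression descending, gene identifier ascending) so
the ordering — and hence the score — is fully deterministic.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .differential import bh_adjust
from .io import GeneSet

__all__ = ["SSGSEA", "ssgsea_score", "ssgsea_table", "normalize_scores",
           "ora_hypergeom"]


def _sample_order(values: np.ndarray, genes: np.ndarray) -> np.ndarray:
    """Indices ordering one sample's genes by (value desc, gene id asc)."""
    return np.lexsort((genes, -values))


def _es_one_sample(values: np.ndarray, genes: np.ndarray,
                   in_set: np.ndarray, alpha: float) -> float:
    """Running-sum enrichment score for one sample (vectorized)."""
    order = _sample_order(values, genes)
    inset_ordered = in_set[order]
    G = values.size
    m = int(in_set.sum())
    # per-sample ranks: highest expression gets rank G
    ranks = np.arange(G, 0, -1, dtype=float)
    w = np.where(inset_ordered, np.abs(ranks) ** alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~inset_ordered) / (G - m)
    return float(np.sum(p_in - p_out))


def _resolve_set(gs, name_default="set") -> GeneSet:
    if isinstance(gs, GeneSet):
        return gs
    return GeneSet(name_default, tuple(gs))


def ssgsea_score(mat: pd.DataFrame, gs: GeneSet, alpha: float = 0.25) -> pd.Series:
    """Per-sample ssGSEA enrichment score of one gene set.

    ``mat`` is genes x samples.  Set genes absent from the matrix are
    dropped with a warning; a set with no gene in the matrix, or covering
    every gene of the matrix, is an error.
    """
    gs = _resolve_set(gs)
    genes = mat.index.to_numpy(dtype=object)
    in_set = np.isin(genes, list(gs.genes))
    n_found = int(in_set.sum())
    if n_found == 0:
        raise ValueError(f"no gene of set {gs.name!r} is present in the matrix")
    if n_found < len(gs):
        warnings.warn(
            f"set {gs.name!r}: {len(gs) - n_found} gene(s) absent from the "
            f"matrix were dropped")
    if n_found == len(genes):
        raise ValueError(
            f"set {gs.name!r} covers every gene in the matrix; the "
            "out-of-set ECDF is undefined")
    values = mat.to_numpy(dtype=float)
    scores = [_es_one_sample(values[:, j], genes, in_set, alpha)
              for j in range(values.shape[1])]
    return pd.Series(scores, index=mat.columns, name=gs.name)


class SSGSEA(TransformerMixin, BaseEstimator):
    """ssGSEA as a transformer: samples x genes in, samples x sets out.

    Parameters
    ----------
    gene_sets : list of GeneSet (or mapping name -> genes)
    alpha : float, default 0.25
        Rank-weight exponent.
    normalize : bool, default False
        Min-max scale each set's scores to [0, 1] across samples.
    """

    def __init__(self, gene_sets=(), alpha=0.25, normalize=False):
        self.gene_sets = gene_sets
        self.alpha = alpha
        self.normalize = normalize

    def _sets(self) -> list[GeneSet]:
        if isinstance(self.gene_sets, dict):
            return [GeneSet(k, tuple(v)) for k, v in self.gene_sets.items()]
        return [_resolve_set(g, f"set{i}") for i, g in enumerate(self.gene_sets)]

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x genes DataFrame "
                            "(gene identifiers as columns)")
        sets = self._sets()
        if not sets:
            raise ValueError("no gene sets provided")
        self.gene_sets_ = sets
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "gene_sets_")
        mat = X.T  # genes x samples
        cols = {gs.name: ssgsea_score(mat, gs, self.alpha)
                for gs in self.gene_sets_}
        out = pd.DataFrame(cols, index=X.index)
        if self.normalize:
            out = normalize_scores(out.T).T
        return out

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "gene_sets_")
        return np.asarray([gs.name for gs in self.gene_sets_], dtype=object)


def ssgsea_table(mat: pd.DataFrame, sets, alpha: float = 0.25,
                 normalize: bool = False) -> pd.DataFrame:
    """Score many gene sets: returns a sets x samples DataFrame."""
    est = SSGSEA(gene_sets=sets, alpha=alpha, normalize=normalize)
    out = est.fit(mat.T).transform(mat.T).T
    out.attrs["normalized"] = normalize
    return out

def normalize_scores(raw: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale each row (gene set) of a sets x samples table to [0, 1].

    A constant row maps to all-zeros with a warning.  Idempotent.
    """
    v = raw.to_numpy(dtype=float)
    lo = v.min(axis=1, keepdims=True)
    rng = v.max(axis=1, keepdims=True) - lo
    flat = rng[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant gene-set row(s) mapped to 0")
    out = np.where(rng == 0, 0.0, (v - lo) / np.where(rng == 0, 1.0, rng))
    res = pd.DataFrame(out, index=raw.index, columns=raw.columns)
    res.attrs["normalized"] = True
    return res


def ora_hypergeom(query, sets, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each set.

    For each set, p = P(X >= overlap) with population |universe|, successes
    |set ∩ universe| and draws |query| (genes outside the universe are
    dropped from the query with a warning).  P-values are BH-adjusted
    across sets.
    """
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uni = set(universe)
    query = list(dict.fromkeys(query))
    outside = [g for g in query if g not in uni]
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside the universe "
                      "were dropped")
    query = [g for g in query if g in uni]
    if not query:
        raise ValueError("query is empty after restricting to the universe")
    qset = set(query)
    rows = []
    for gs in sets:
        gs = _resolve_set(gs)
        in_uni = [g for g in gs.genes if g in uni]
        overlap = len(qset.intersection(in_uni))
        p = float(hypergeom.sf(overlap - 1, len(universe), len(in_uni),
                               len(query)))
        rows.append({"set": gs.name, "set_size": len(in_uni),
                     "overlap": overlap, "p": min(p, 1.0)})
    tab = pd.DataFrame(rows)
    tab["adjP"] = bh_adjust(tab["p"].to_numpy())
    return tab
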