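"""Signature scores: prognostic gene screening, the PCA-based HAscore,
and the EMT score.

HAscore
-------
The per-sample histone-acetylation score is built from a signature of
phenotype-related prognostic genes: each gene is z-scored across samples,
the samples x genes z-matrix is decomposed by SVD, and a sample's score is
the sum of its coordinates on the first two principal components,

    HAscore_s = PC1_s + PC2_s .

Principal-component signs are arbitrary in any SVD; each component is
oriented so that its correlation with the per-sample mean z-expression of
the signature is non-negative, which makes "high HAscore = high signature
expression" reproducible across linear-algebra backends.  The score is
invariant to gene/sample ordering and to positive per-gene affine rescaling
of the input, and the components are not variance-normalized (raw
coordinates are summed).

EMT score
---------
Mean expression of the mesenchymal marker genes minus mean expression of
the epithelial marker genes, per sample, over the markers present in the
matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .io import GeneSet
from .survival import cox_fit

__all__ = ["HAScorer", "prognostic_screen", "hascore", "emt_score"]


class HAScorer(TransformerMixin, BaseEstimator):
    """PCA signature scorer: samples x genes in, one score per sample out.

    Fitting learns per-gene centering/scaling and the first two principal
    axes of the z-scored signature matrix; ``transform`` projects (new)
    samples onto those axes and sums the two coordinates.  On the training
    data ``fit_transform`` reproduces the cohort-level score.

    Parameters
    ----------
    signature : list of gene identifiers or None
        Columns to use; None means all columns.  Signature genes absent
        from the input are dropped with a warning.
    """

    def __init__(self, signature=None):
        self.signature = signature

    def fit(self, X, y=None):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        if self.signature is not None:
            sig = list(dict.fromkeys(self.signature))
            present = [g for g in sig if g in X.columns]
            if not present:
                raise ValueError("no signature gene present in the matrix")
            if len(present) < len(sig):
                warnings.warn(f"{len(sig) - len(present)} signature gene(s) "
                              "absent from the matrix were dropped")
            X = X[present]
        if X.shape[0] < 3:
            raise ValueError("need at least 3 samples")
        v = X.to_numpy(dtype=float)
        sd = v.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(f"{int((~keep).sum())} zero-variance signature "
                          "gene(s) dropped")
        if keep.sum() < 2:
            raise ValueError("fewer than 2 usable signature genes")
        v = v[:, keep]
        self.genes_ = np.asarray(X.columns)[keep]
        self.mean_ = v.mean(axis=0)
        self.scale_ = v.std(axis=0, ddof=1)
        z = (v - self.mean_) / self.scale_
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        coords = u[:, :2] * s[:2]
        mean_z = z.mean(axis=1)
        signs = np.ones(2)
        for c in range(2):
            if coords[:, c].std() > 0 and np.corrcoef(coords[:, c], mean_z)[0, 1] < 0:
                signs[c] = -1.0
        self.components_ = vt[:2].T * signs  # genes x 2, sign-fixed
        self.singular_values_ = s[:2]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=self.genes_)
        v = X[list(self.genes_)].to_numpy(dtype=float)
        z = (v - self.mean_) / self.scale_
        return (z @ self.components_).sum(axis=1, keepdims=True)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(["hascore"], dtype=object)


def hascore(mat: pd.DataFrame, signature) -> pd.Series:
    """Per-sample HAscore (PC1 + PC2 of the z-scored signature matrix).

    ``mat`` is genes x samples; ``signature`` the prognostic gene list.
    """
    scorer = HAScorer(signature=list(signature))
    scores = scorer.fit_transform(mat.T)
    return pd.Series(scores[:, 0], index=mat.columns, name="hascore")


def prognostic_screen(mat: pd.DataFrame, clinical: pd.DataFrame, genes,
                      p_thresh: float = 0.05) -> list[str]:
    """Retain genes whose expression predicts overall survival.

    Each gene is fit in a univariate Cox model against (os_time, os_event);
    genes with Wald p < ``p_thresh`` are kept, in input order.
    """
    genes = list(dict.fromkeys(genes))
    if not genes:
        raise ValueError("empty gene list")
    missing = [g for g in genes if g not in mat.index]
    if missing:
        raise ValueError(f"gene(s) absent from the matrix: {missing[:5]}")
    shared = [s for s in mat.columns if s in clinical.index]
    if len(shared) < 4:
        raise ValueError("fewer than 4 samples shared with the clinical table")
    time = clinical.loc[shared, "os_time"].to_numpy(dtype=float)
    event = clinical.loc[shared, "os_event"].to_numpy()
    kept = []
    for g in genes:
        x = mat.loc[g, shared].to_numpy(dtype=float)
        if x.std() == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = cox_fit(time, event, x, names=(g,))
        if fit.wald_p[0] < p_thresh:
            kept.append(g)
    if not kept:
        raise ValueError(
            f"no gene reached Wald p < {p_thresh}; consider relaxing p_thresh")
    return kept


def emt_score(mat: pd.DataFrame, mesenchymal: GeneSet,
              epithelial: GeneSet) -> pd.Series:
    """EMT score: mean mesenchymal minus mean epithelial expression.

    Computed over the marker genes present in the matrix; a marker set with
    no gene in the matrix is an error.
    """
    def _present(gs: GeneSet) -> list[str]:
        found = [g for g in gs.genes if g in mat.index]
        if not found:
            raise ValueError(f"no gene of set {gs.name!r} present in the matrix")
        if len(found) < len(gs):
            warnings.warn(f"set {gs.name!r}: {len(gs) - len(found)} marker "
                          "gene(s) absent from the matrix")
        return found

    m = mat.loc[_present(mesenchymal)].mean(axis=0)
    e = mat.loc[_present(epithelial)].mean(axis=0)
    out = m - e
    out.name = "emt_score"
    return out
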