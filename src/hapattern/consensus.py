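"""Resampling consensus clustering with delta-area / PAC model selection.

The procedure follows the classic consensus-clustering recipe: repeatedly
subsample the cohort, partition each subsample with an inner clusterer
(k-means on per-feature z-scores), and record for every sample pair the
fraction of co-sampled repetitions in which the pair co-clustered.  The
consensus matrix is then summarised per k by the empirical CDF of its
off-diagonal entries, the area under that CDF, the relative delta-area
(elbow criterion for choosing k), and the proportion of ambiguous
clustering (PAC, the CDF mass between 0.1 and 0.9).  Final assignments cut
an average-linkage dendrogram of 1 - consensus.

RNG stream contract (relied on by replay tests): for each repetition, one
seeded :class:`numpy.random.Generator` first draws the subsample indices
(``rng.choice(n, size, replace=False)``) and then one integer in
[0, 2**31) used as the k-means ``random_state``.  Repetitions for each k
restart from ``default_rng(seed)``, so per-k runs are independent of the
order in which k values are visited.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger("hapattern")

__all__ = ["ConsensusClustering", "ConsensusResult", "consensus_matrix",
           "select_k", "final_assignments"]


def _zscore_columns(X: np.ndarray) -> np.ndarray:
    """z-score features (columns), dropping zero-variance ones with a warning."""
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} zero-variance feature(s)")
    if not keep.any():
        raise ValueError("all features have zero variance")
    return (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]


def _consensus_one_k(Z: np.ndarray, k: int, reps: int, frac: float,
                     seed: int, n_init: int) -> tuple[np.ndarray, np.ndarray]:
    """One consensus matrix; returns (consensus, co_sample_counts)."""
    n = Z.shape[0]
    size = int(np.ceil(frac * n))
    if k > size:
        raise ValueError(f"k={k} exceeds subsample size {size}")
    rng = np.random.default_rng(seed)
    together = np.zeros((n, n))
    sampled = np.zeros((n, n))
    for _ in range(reps):
        idx = rng.choice(n, size=size, replace=False)
        km_seed = int(rng.integers(0, 2**31))
        lab = KMeans(n_clusters=k, n_init=n_init,
                     random_state=km_seed).fit_predict(Z[idx])
        sampled[np.ix_(idx, idx)] += 1.0
        same = lab[:, None] == lab[None, :]
        together[np.ix_(idx, idx)] += same
    never = sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn(
            f"{int(never.sum() // 2)} sample pair(s) never co-sampled; "
            "their consensus is defined as 0 (increase reps)"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(sampled > 0, together / np.where(sampled == 0, 1, sampled), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0
    return consensus, sampled


def _cdf_area(consensus: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Empirical CDF of off-diagonal consensus entries, its area on [0, 1],
    and the PAC (mass strictly inside (0.1, 0.9))."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    v = np.sort(consensus[iu])
    m = v.size
    cdf_y = np.arange(1, m + 1) / m
    # area under the step CDF over [0, 1]
    xs = np.concatenate([[0.0], v, [1.0]])
    ys = np.concatenate([[0.0], cdf_y, [1.0]])
    area = float(np.sum(np.diff(xs) * ys[:-1]))
    pac = float(np.mean((v > 0.1) & (v < 0.9)))
    return v, cdf_y, area, pac


def _cut_consensus(consensus: np.ndarray, k: int) -> np.ndarray:
    """Average-linkage cut of the consensus dissimilarity into k groups."""
    n = consensus.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of samples {n}")
    if k == 1:
        return np.zeros(n, dtype=int)
    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    tree = linkage(squareform(dist, checks=False), method="average")
    lab = fcluster(tree, t=k, criterion="maxclust")
    return lab - 1


@dataclass
class ConsensusResult:
    """Per-k consensus summaries plus the chosen model."""

    k_range: tuple[int, ...]
    consensus: dict[int, pd.DataFrame]
    co_sample_counts: dict[int, pd.DataFrame]
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]
    area: dict[int, float]
    delta_area: dict[int, float]
    pac: dict[int, float]
    chosen_k: int
    assignments: pd.Series

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": list(self.k_range),
            "area": [self.area[k] for k in self.k_range],
            "delta_area": [self.delta_area[k] for k in self.k_range],
            "pac": [self.pac[k] for k in self.k_range],
            "chosen": [int(k == self.chosen_k) for k in self.k_range],
        })


class ConsensusClustering(ClusterMixin, BaseEstimator):
    """Consensus clustering over a range of k with automatic model selection.

    Parameters
    ----------
    k_range : iterable of int, default (2, 3, 4, 5, 6)
        Candidate cluster numbers; must be contiguous and start at >= 2
        (a single value is accepted with a warning).
    reps : int, default 1000
        Resampling repetitions per k.
    subsample_frac : float, default 0.8
        Fraction of samples drawn (without replacement) per repetition.
    n_init : int, default 10
        k-means restarts per repetition.
    zscore : bool, default True
        z-score features before clustering (per-gene standardization).
    random_state : int, default 0

    Attributes
    ----------
    consensus_ : dict mapping k to the (n, n) consensus matrix
    co_sample_counts_ : dict mapping k to pairwise co-sampling counts
    area_, delta_area_, pac_ : dict mapping k to the CDF summaries
    chosen_k_ : selected number of clusters (relative delta-area elbow)
    labels_ : final assignments at ``chosen_k_``
    """

    def __init__(self, k_range=(2, 3, 4, 5, 6), reps=1000, subsample_frac=0.8,
                 n_init=10, zscore=True, random_state=0):
        self.k_range = k_range
        self.reps = reps
        self.subsample_frac = subsample_frac
        self.n_init = n_init
        self.zscore = zscore
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (samples x features)")
        n = X.shape[0]
        ks = tuple(int(k) for k in self.k_range)
        if len(ks) == 0:
            raise ValueError("empty k_range")
        if len(ks) == 1:
            warnings.warn(f"k_range has a single value; using k={ks[0]}")
        elif list(ks) != list(range(ks[0], ks[-1] + 1)) or ks[0] < 2:
            raise ValueError("k_range must be contiguous and start at >= 2")
        if not 0 < self.subsample_frac <= 1:
            raise ValueError("subsample_frac must be in (0, 1]")
        if n < 2 * max(ks):
            raise ValueError(f"need at least {2 * max(ks)} samples for k={max(ks)}")

        Z = _zscore_columns(X) if self.zscore else X
        self.consensus_, self.co_sample_counts_ = {}, {}
        self.cdf_, self.area_, self.pac_ = {}, {}, {}
        for k in ks:
            cons, counts = _consensus_one_k(
                Z, k, self.reps, self.subsample_frac,
                self.random_state, self.n_init)
            self.consensus_[k] = cons
            self.co_sample_counts_[k] = counts
            v, cy, area, pac = _cdf_area(cons)
            self.cdf_[k] = (v, cy)
            self.area_[k] = area
            self.pac_[k] = pac

        self.delta_area_ = {}
        for i, k in enumerate(ks):
            if i == 0:
                self.delta_area_[k] = self.area_[k]
            else:
                prev = self.area_[ks[i - 1]]
                self.delta_area_[k] = (self.area_[k] - prev) / prev if prev > 0 \
                    else self.area_[k]
        best = max(ks, key=lambda k: (self.delta_area_[k], -k))
        # ties broken toward smaller k
        for k in ks:
            if self.delta_area_[k] >= self.delta_area_[best] - 1e-12:
                best = k
                break
        self.chosen_k_ = best
        if self.pac_[best] > 0.5:
            logger.warning(
                "weak cluster structure: PAC=%.3f at chosen k=%d",
                self.pac_[best], best)
        self.labels_ = _cut_consensus(self.consensus_[best], best)
        self.n_features_in_ = X.shape[1]
        return self

    def result(self, sample_ids=None) -> ConsensusResult:
        check_is_fitted(self, "chosen_k_")
        n = next(iter(self.consensus_.values())).shape[0]
        ids = list(sample_ids) if sample_ids is not None \
            else [str(i) for i in range(n)]
        wrap = lambda m: pd.DataFrame(m, index=ids, columns=ids)
        return ConsensusResult(
            k_range=tuple(self.consensus_),
            consensus={k: wrap(m) for k, m in self.consensus_.items()},
            co_sample_counts={k: wrap(m) for k, m in self.co_sample_counts_.items()},
            cdf=dict(self.cdf_),
            area=dict(self.area_),
            delta_area=dict(self.delta_area_),
            pac=dict(self.pac_),
            chosen_k=self.chosen_k_,
            assignments=pd.Series(self.labels_, index=ids, name="cluster"),
        )


def consensus_matrix(mat: pd.DataFrame, panel, k: int, reps: int = 1000,
                     subsample_frac: float = 0.8, seed: int = 0,
                     n_init: int = 10) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Consensus matrix for one k on a gene panel of a genes x samples matrix.

    Panel genes absent from the matrix are dropped with a warning.
    Returns (consensus, co_sample_counts) as sample x sample DataFrames.
    """
    panel = list(panel)
    present = [g for g in panel if g in mat.index]
    if len(present) < len(panel):
        missing = sorted(set(panel) - set(present))
        warnings.warn(f"{len(missing)} panel gene(s) absent from matrix: "
                      f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    if not present:
        raise ValueError("no panel gene present in the matrix")
    X = mat.loc[present].to_numpy(dtype=float).T
    if X.shape[0] < 2 * k:
        raise ValueError(f"need at least {2 * k} samples for k={k}")
    Z = _zscore_columns(X)
    cons, counts = _consensus_one_k(Z, k, reps, subsample_frac, seed, n_init)
    ids = list(mat.columns)
    return (pd.DataFrame(cons, index=ids, columns=ids),
            pd.DataFrame(counts, index=ids, columns=ids))


def select_k(area_by_k: dict[int, float]) -> int:
    """Relative delta-area elbow over a contiguous k range (ties -> smaller k)."""
    ks = sorted(area_by_k)
    if len(ks) == 1:
        warnings.warn(f"single k in range; returning k={ks[0]}")
        return ks[0]
    delta = {}
    for i, k in enumerate(ks):
        if i == 0:
            delta[k] = area_by_k[k]
        else:
            prev = area_by_k[ks[i - 1]]
            delta[k] = (area_by_k[k] - prev) / prev if prev > 0 else area_by_k[k]
    best = max(delta.values())
    for k in ks:
        if delta[k] >= best - 1e-12:
            return k
    return ks[0]


def final_assignments(consensus: pd.DataFrame | np.ndarray, k: int) -> pd.Series:
    """Cut an average-linkage tree of 1 - consensus into k groups."""
    if isinstance(consensus, pd.DataFrame):
        ids = list(consensus.index)
        m = consensus.to_numpy(dtype=float)
    else:
        m = np.asarray(consensus, dtype=float)
        ids = list(range(m.shape[0]))
    lab = _cut_consensus(m, k)
    return pd.Series(lab, index=ids, name="cluster")
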