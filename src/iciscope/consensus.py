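"""Subsampled consensus clustering.

Used twice in the workflow: to partition samples by their 22 immune-cell
fraction profiles (immune subtypes I-III, Spearman distance + Ward
linkage) and to partition samples by DEG expression (gene clusters A-C,
Pearson distance + complete linkage). Repeated hierarchical clustering of
random subsamples yields a consensus matrix of pairwise co-clustering
frequencies; the final partition is hierarchical clustering of
``1 - consensus``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClusterMixin

DISTANCES = ("spearman", "pearson", "euclidean")
LINKAGES = ("ward", "complete", "average")


@dataclass
class ConsensusResult:
    """Consensus matrix plus the final k-partition.

    ``consensus`` is items x items in [0, 1], symmetric with unit
    diagonal; ``labels`` maps each item to a group in ``1..k``.
    """

    items: list
    k: int
    consensus: pd.DataFrame
    labels: pd.Series
    n_reps: int
    subsample_fraction: float


def _pairwise_distance(X: np.ndarray, distance: str) -> np.ndarray:
    """Condensed pairwise distance between rows of X."""
    if distance == "euclidean":
        from scipy.spatial.distance import pdist
        return pdist(X, metric="euclidean")
    if distance == "spearman":
        X = np.apply_along_axis(rankdata, 1, X)
    sd = X.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(f"{const.sum()} constant item(s) under correlation "
                      "distance; using zero distance for them", stacklevel=3)
        sd = np.where(const, 1.0, sd)
    Xc = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    corr = (Xc @ Xc.T) / X.shape[1]
    corr[const, :] = 1.0
    corr[:, const] = 1.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - np.clip(corr, -1.0, 1.0)
    return squareform(dist, checks=False)


def _cut(cond_dist: np.ndarray, k: int, linkage: str) -> np.ndarray:
    Z = hierarchy.linkage(cond_dist, method=linkage)
    return hierarchy.fcluster(Z, t=k, criterion="maxclust")


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel groups 1..k in order of first appearance (determinism)."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


class ConsensusCluster(BaseEstimator, ClusterMixin):
    """Subsampled consensus clustering as an sklearn-style clusterer.

    Parameters
    ----------
    k : int
        Number of clusters (the workflow fixes k = 3).
    n_reps : int
        Number of subsampled clustering repetitions (reference setting
        500; 100 suffices for well-separated data).
    subsample_fraction : float
        Fraction of items drawn (without replacement) per repetition.
    distance : {"spearman", "pearson", "euclidean"}
        Item-item dissimilarity; correlation distances use 1 - corr.
    linkage : {"ward", "complete", "average"}
        Within-repetition hierarchical linkage (Ward in the Ward.D2
        convention scipy implements on precomputed distances).
    random_state : int
        Seed; identical seeds give bit-identical results.

    Attributes
    ----------
    labels_ : ndarray of int
        Final partition (1..k), from average-linkage clustering of
        ``1 - consensus``.
    consensus_ : ndarray
        Items x items co-clustering frequency matrix.
    """

    def __init__(self, k: int = 3, n_reps: int = 500,
                 subsample_fraction: float = 0.9,
                 distance: str = "spearman", linkage: str = "ward",
                 random_state: int = 0):
        self.k = k
        self.n_reps = n_reps
        self.subsample_fraction = subsample_fraction
        self.distance = distance
        self.linkage = linkage
        self.random_state = random_state

    def fit(self, X, y=None) -> "ConsensusCluster":
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if self.k < 2 or self.k > n:
            raise ValueError(f"k={self.k} must be in [2, n_items={n}]")
        if not (0 < self.subsample_fraction <= 1):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if self.distance not in DISTANCES:
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.linkage not in LINKAGES:
            raise ValueError(f"unknown linkage {self.linkage!r}")
        rng = np.random.default_rng(self.random_state)
        m = int(np.ceil(self.subsample_fraction * n))
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        for _ in range(self.n_reps):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            labels = _cut(_pairwise_distance(X[idx], self.distance),
                          self.k, self.linkage)
            same = labels[:, None] == labels[None, :]
            co_sample[np.ix_(idx, idx)] += 1.0
            co_cluster[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(co_sample > 0, co_cluster / co_sample, 0.0)
        np.fill_diagonal(consensus, 1.0)
        final = _cut(squareform(1.0 - consensus, checks=False),
                     self.k, "average")
        self.labels_ = _canonical_labels(final)
        self.consensus_ = consensus
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def consensus_cluster(data: pd.DataFrame, k: int, n_reps: int = 500,
                      subsample_fraction: float = 0.9,
                      distance: str = "spearman", linkage: str = "ward",
                      seed: int = 0) -> ConsensusResult:
    """Consensus-cluster the rows of ``data`` (items x features)."""
    model = ConsensusCluster(k=k, n_reps=n_reps,
                             subsample_fraction=subsample_fraction,
                             distance=distance, linkage=linkage,
                             random_state=seed)
    model.fit(data.to_numpy(dtype=float))
    items = list(data.index)
    return ConsensusResult(
        items=items, k=k,
        consensus=pd.DataFrame(model.consensus_, index=items, columns=items),
        labels=pd.Series(model.labels_, index=items, name="cluster"),
        n_reps=n_reps, subsample_fraction=subsample_fraction)


def consensus_diagnostics(results: dict[int, ConsensusResult]
                          ) -> pd.DataFrame:
    """Companion diagnostics over a range of k.

    For each k: the empirical CDF of off-diagonal consensus values, its
    area (trapezoid rule), the relative area increment over the previous
    k, and the proportion of ambiguous clustering
    PAC = CDF(0.9) - CDF(0.1). Crisp consensus (all entries near 0 or 1)
    gives PAC near 0.
    """
    if len(results) < 2:
        raise ValueError("need results for at least 2 values of k")
    rows = []
    prev_area = None
    for k in sorted(results):
        cons = results[k].consensus.to_numpy()
        iu = np.triu_indices_from(cons, k=1)
        vals = np.sort(cons[iu])
        n = len(vals)
        cdf = np.arange(1, n + 1) / n

        def ecdf(x: float) -> float:
            return float(np.searchsorted(vals, x, side="right")) / n

        area = float(np.sum(np.diff(vals) * cdf[:-1])) if n > 1 else 0.0
        delta = (area if prev_area is None
                 else (area - prev_area) / prev_area if prev_area > 0
                 else 0.0)
        rows.append({"k": k, "area": area, "delta_area": delta,
                     "pac": ecdf(0.9) - ecdf(0.1)})
        prev_area = area
    return pd.DataFrame(rows).set_index("k")
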