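"""Construction of the per-patient immune-cell-infiltration (ICI) score.

The score is built from the DEGs separating immune subtypes:

1. each DEG is assigned to signature gene set A (positively correlated
   with the immune-hot ordering of the gene clusters) or set B (negatively
   correlated),
2. both sets are reduced with the Boruta all-relevant feature-selection
   algorithm (shadow features + random-forest importance),
3. per patient, ICI score A and B are single-sample gene-set enrichment
   (ssGSEA) scores of the two sets and ICI score = score A - score B,
   median-split into high/low groups. A PCA variant projects each set on
   its first principal component instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier


@dataclass
class SignatureGeneSets:
    """ICI signature gene sets A (immune-hot axis) and B (its complement)."""

    set_A: list[str]
    set_B: list[str]

    def __post_init__(self) -> None:
        if set(self.set_A) & set(self.set_B):
            raise ValueError("signature sets A and B must be disjoint")
        if not self.set_A or not self.set_B:
            raise ValueError("both signature sets must be non-empty")


def assign_signature_genes(deg_expr: pd.DataFrame,
                           gene_cluster_labels: pd.Series,
                           ordering: dict | None = None,
                           immune_score: pd.Series | None = None,
                           encoding: str = "ordinal"
                           ) -> SignatureGeneSets:
    """Split DEGs into signature sets A/B by correlation with the gene
    clusters.

    Each sample carries a gene-cluster label; the labels are encoded on a
    numeric axis (default: clusters ranked by their mean immune score, so
    larger means more immune-infiltrated) and every DEG's expression is
    correlated (Pearson) with that encoding. Positive correlation sends
    the gene to set A, negative to set B; exactly-zero or undefined
    correlations are dropped with a warning.

    Parameters
    ----------
    deg_expr : DataFrame
        DEGs x samples expression.
    gene_cluster_labels : Series
        Cluster label per sample.
    ordering : dict, optional
        Explicit label -> numeric score mapping; overrides
        ``immune_score``.
    immune_score : Series, optional
        Per-sample immune score used to rank clusters when ``ordering``
        is not given.
    encoding : {"ordinal", "indicator"}
        "ordinal" uses the single ranked axis (default); "indicator"
        correlates against membership of the top-ranked cluster only.
    """
    labels = gene_cluster_labels.reindex(deg_expr.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a gene-cluster label")
    if ordering is None:
        if immune_score is None:
            raise ValueError("provide either ordering or immune_score")
        means = immune_score.reindex(labels.index).groupby(labels).mean()
        ordering = {lab: float(r) for lab, r in
                    means.rank(ascending=True).items()}
    if encoding == "ordinal":
        axis = labels.map(ordering).to_numpy(dtype=float)
    elif encoding == "indicator":
        top = max(ordering, key=ordering.get)
        axis = (labels == top).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    if np.std(axis) == 0:
        raise ValueError("cluster encoding is constant")

    X = deg_expr.to_numpy(dtype=float)
    axis_c = axis - axis.mean()
    x_c = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((x_c ** 2).sum(axis=1) * (axis_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (x_c @ axis_c) / denom, np.nan)
    set_a = deg_expr.index[r > 0].tolist()
    set_b = deg_expr.index[r < 0].tolist()
    dropped = len(deg_expr.index) - len(set_a) - len(set_b)
    if dropped:
        warnings.warn(f"{dropped} gene(s) with zero/undefined correlation "
                      "dropped from the signature", stacklevel=2)
    return SignatureGeneSets(set_A=set_a, set_B=set_b)


class BorutaSelector(BaseEstimator):
    """Boruta all-relevant feature selection.

    Every candidate feature is paired with a "shadow" copy whose values
    are permuted across samples. Per iteration a random-forest importance
    backend scores candidates and shadows together; a candidate scores a
    *hit* when its importance exceeds the best shadow importance. Binomial
    tests on the accumulated hit counts (success probability 0.5,
    Bonferroni-corrected over candidates) confirm clearly-useful features
    and reject clearly-irrelevant ones; features still tentative at the
    iteration cap are resolved by comparing their median importance with
    the median of the best-shadow importances.

    Attributes
    ----------
    support_ : ndarray of bool
        Confirmed features.
    decision_ : ndarray of str
        "confirmed" / "rejected" / "tentative-confirmed" /
        "tentative-rejected" per feature.
    """

    def __init__(self, max_iter: int = 100, alpha: float = 0.05,
                 n_estimators: int = 100, random_state: int = 0,
                 importance_backend=None):
        self.max_iter = max_iter
        self.alpha = alpha
        self.n_estimators = n_estimators
        self.random_state = random_state
        self.importance_backend = importance_backend

    def _backend(self, seed: int):
        if self.importance_backend is not None:
            return self.importance_backend(seed)
        return RandomForestClassifier(
            n_estimators=self.n_estimators, random_state=seed, n_jobs=1)

    def fit(self, X, y) -> "BorutaSelector":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        n_samples, n_feat = X.shape
        if n_feat == 0:
            raise ValueError("no candidate features")
        if len(np.unique(y)) < 2:
            raise ValueError("need at least 2 target classes")
        rng = np.random.default_rng(self.random_state)

        hits = np.zeros(n_feat, dtype=int)
        n_trials = np.zeros(n_feat, dtype=int)
        imp_history: list[np.ndarray] = []
        shadow_hist: list[float] = []
        active = np.ones(n_feat, dtype=bool)   # undecided
        decision = np.array(["tentative"] * n_feat, dtype=object)

        for it in range(self.max_iter):
            idx = np.nonzero(active)[0]
            if idx.size == 0:
                break
            Xa = X[:, idx]
            shadow = Xa.copy()
            for j in range(shadow.shape[1]):
                shadow[:, j] = rng.permutation(shadow[:, j])
            model = self._backend(int(rng.integers(0, 2 ** 31 - 1)))
            model.fit(np.hstack([Xa, shadow]), y)
            imp = model.feature_importances_
            real_imp, shadow_imp = imp[:idx.size], imp[idx.size:]
            shadow_max = float(shadow_imp.max())
            shadow_hist.append(shadow_max)
            full_imp = np.full(n_feat, np.nan)
            full_imp[idx] = real_imp
            imp_history.append(full_imp)
            hit = real_imp > shadow_max
            hits[idx] += hit
            n_trials[idx] += 1

            thr = self.alpha / n_feat  # Bonferroni over all candidates
            for j in idx:
                n, k = n_trials[j], hits[j]
                if n == 0:
                    continue
                p_hi = stats.binom.sf(k - 1, n, 0.5)
                p_lo = stats.binom.cdf(k, n, 0.5)
                if p_hi < thr:
                    decision[j] = "confirmed"
                    active[j] = False
                elif p_lo < thr:
                    decision[j] = "rejected"
                    active[j] = False

        # resolve leftovers by the median-importance rule
        if active.any():
            med_shadow = float(np.median(shadow_hist))
            imp_arr = np.vstack(imp_history)
            for j in np.nonzero(active)[0]:
                med = np.nanmedian(imp_arr[:, j])
                decision[j] = ("tentative-confirmed" if med > med_shadow
                               else "tentative-rejected")
        self.decision_ = decision
        self.support_ = np.array(
            [d in ("confirmed", "tentative-confirmed") for d in decision])
        self.n_iter_ = len(shadow_hist)
        return self


def boruta_reduce(expr: pd.DataFrame, target_labels: pd.Series,
                  max_iter: int = 100, alpha: float = 0.05,
                  seed: int = 0, n_estimators: int = 100,
                  importance_backend=None) -> list[str]:
    """Reduce a gene panel to the Boruta-confirmed genes.

    ``expr`` is samples x genes; ``target_labels`` gives the class per
    sample (by default the workflow targets the gene-cluster labels).
    Returns the confirmed gene list (tentative genes resolved by the
    median rule, so every gene receives a decision).
    """
    y = target_labels.reindex(expr.index)
    if y.isna().any():
        raise ValueError("every sample needs a target label")
    sel = BorutaSelector(max_iter=max_iter, alpha=alpha, random_state=seed,
                         n_estimators=n_estimators,
                         importance_backend=importance_backend)
    sel.fit(expr.to_numpy(dtype=float), y.to_numpy())
    return [g for g, keep in zip(expr.columns, sel.support_) if keep]


def ssgsea(expr: pd.DataFrame, gene_set, alpha_exp: float = 0.25
           ) -> pd.Series:
    """Single-sample gene-set enrichment score per sample.

    Per sample, genes are ranked by expression (ties get average ranks,
    the top gene rank N); walking down the ranking, set genes contribute
    their rank to the power ``alpha_exp`` (normalized by the set total)
    and non-set genes contribute 1/(N - |set|); the score is the summed
    difference of the two cumulative curves (integrated-difference form).
    Being rank-based, the score is invariant under strictly increasing
    transforms of a sample's expression.
    """
    genes = expr.index
    N = len(genes)
    if N < 2:
        raise ValueError("need at least 2 genes")
    in_set = np.asarray(genes.isin(set(gene_set)))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("no gene of the set is present in the matrix")
    if n_in == N:
        raise ValueError("gene set covers every gene (background empty)")

    X = expr.to_numpy(dtype=float)
    scores = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        x = X[:, j]
        ranks = stats.rankdata(x)              # ascending, average ties
        order = np.lexsort((np.arange(N), -x))  # descending, stable
        hit = in_set[order]
        w = np.where(hit, ranks[order] ** alpha_exp, 0.0)
        p_in = np.cumsum(w) / w.sum()
        p_out = np.cumsum(~hit) / (N - n_in)
        scores[j] = float(np.sum(p_in - p_out))
    return pd.Series(scores, index=expr.columns, name="es")


def _median_split(score: pd.Series) -> pd.Series:
    """High/low groups at the cohort median; ties go to the low group."""
    med = score.median()
    return pd.Series(np.where(score > med, "high", "low"),
                     index=score.index, name="group")


def compute_ici_score_ssgsea(expr: pd.DataFrame,
                             sets: SignatureGeneSets) -> pd.DataFrame:
    """Per-patient ICI score by ssGSEA: score A - score B, median split."""
    score_a = ssgsea(expr, sets.set_A)
    score_b = ssgsea(expr, sets.set_B)
    ici = score_a - score_b
    out = pd.DataFrame({"score_A": score_a, "score_B": score_b,
                        "ici_score": ici, "group": _median_split(ici)})
    out.attrs["method"] = "ssgsea"
    return out


def compute_ici_score_pca(expr: pd.DataFrame,
                          sets: SignatureGeneSets,
                          prognostic_filter: list[str] | None = None,
                          immune_score: pd.Series | None = None,
                          mode: str = "absolute") -> pd.DataFrame:
    """Per-patient ICI score by PCA projection of the two signature sets.

    Genes are z-scored across samples and each set is reduced to its
    first principal component; the component sign is oriented so its
    projection correlates positively with ``immune_score`` (or, absent
    one, with the mean expression of the set's genes), making "high"
    reproducibly the immune-hot direction. The combined score is
    ``|PC1_A| + |PC1_B|`` in the literal "absolute" mode and
    ``PC1_A - PC1_B`` in the directional "difference" mode.

    ``prognostic_filter`` (e.g. genes passing the univariate survival
    screen at p < 0.05) is intersected with both sets first.
    """
    if mode not in ("absolute", "difference"):
        raise ValueError(f"unknown mode {mode!r}")

    def project(gene_list: list[str]) -> pd.Series:
        genes = [g for g in gene_list if g in expr.index]
        if prognostic_filter is not None:
            keep = set(prognostic_filter)
            genes = [g for g in genes if g in keep]
        if len(genes) < 2:
            raise ValueError(
                "fewer than 2 signature genes left after filtering")
        X = expr.loc[genes].to_numpy(dtype=float).T  # samples x genes
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xz = (X - X.mean(axis=0)) / sd
        proj = PCA(n_components=1).fit_transform(Xz).ravel()
        anchor = (immune_score.reindex(expr.columns).to_numpy(dtype=float)
                  if immune_score is not None else Xz.mean(axis=1))
        if np.corrcoef(proj, anchor)[0, 1] < 0:
            proj = -proj
        return pd.Series(proj, index=expr.columns)

    pc_a, pc_b = project(sets.set_A), project(sets.set_B)
    if mode == "absolute":
        ici = pc_a.abs() + pc_b.abs()
    else:
        ici = pc_a - pc_b
    out = pd.DataFrame({"score_A": pc_a, "score_B": pc_b,
                        "ici_score": ici, "group": _median_split(ici)})
    out.attrs["method"] = f"pca-{mode}"
    return out
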