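"""Downstream analyses: drug sensitivity, enrichment, rank statistics.

Drug sensitivity follows the cell-line transfer-learning recipe: per drug,
a ridge regression of log-IC50 on (training-standardized) cell-line
expression, penalty chosen by efficient leave-one-out cross-validation,
then applied to tumor expression to compare predicted sensitivity between
ICI score groups. Enrichment covers preranked GSEA (weighted
Kolmogorov-Smirnov running sum with a gene-label permutation null) and
hypergeometric over-representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import RidgeCV

from iciscope.dge import bh_adjust

DEFAULT_LAMBDA_GRID = np.logspace(-2, 3, 13)


# ---------------------------------------------------------------- drugs

@dataclass
class DrugModel:
    """Ridge model for one drug: coefficients over training genes plus the
    training standardization (mean/sd per gene) used at prediction time."""

    drug_id: str
    genes: list[str]
    coef: np.ndarray
    intercept: float
    lambda_: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray


class RidgeIC50(BaseEstimator, RegressorMixin):
    """Per-drug ridge regression of log-IC50 on cell-line expression.

    ``fit`` takes training expression (genes x lines) and a log-IC50
    table (lines x drugs); features are z-scored with training statistics
    (zero-variance genes dropped with a warning) and the ridge penalty is
    selected per drug by leave-one-out cross-validation over
    ``lambda_grid``. ``predict`` maps tumor expression (genes x samples)
    to predicted log-IC50 per drug; genes absent from the tumor matrix
    are imputed at the training mean (z = 0), and prediction refuses to
    run when fewer than half the model genes are present.
    """

    def __init__(self, lambda_grid=DEFAULT_LAMBDA_GRID,
                 min_gene_overlap: float = 0.5):
        self.lambda_grid = lambda_grid
        self.min_gene_overlap = min_gene_overlap

    def fit(self, train_expr: pd.DataFrame,
            train_log_ic50: pd.DataFrame) -> "RidgeIC50":
        lines = [l for l in train_log_ic50.index
                 if l in train_expr.columns]
        if len(lines) < 3:
            raise ValueError("need at least 3 training lines")
        X = train_expr[lines].to_numpy(dtype=float).T  # lines x genes
        genes = list(train_expr.index)
        sd = X.std(axis=0)
        if (sd == 0).any():
            warnings.warn(f"dropping {(sd == 0).sum()} zero-variance "
                          "gene(s) from drug models", stacklevel=2)
            keep = sd > 0
            X, genes, sd = X[:, keep], list(
                np.array(genes)[keep]), sd[keep]
        mean = X.mean(axis=0)
        Xz = (X - mean) / sd
        self.models_: dict[str, DrugModel] = {}
        for drug in train_log_ic50.columns:
            y = train_log_ic50.loc[lines, drug].to_numpy(dtype=float)
            ridge = RidgeCV(alphas=np.asarray(self.lambda_grid))
            ridge.fit(Xz, y)
            self.models_[drug] = DrugModel(
                drug_id=str(drug), genes=genes,
                coef=ridge.coef_.copy(),
                intercept=float(ridge.intercept_),
                lambda_=float(ridge.alpha_),
                feature_mean=mean, feature_sd=sd)
        return self

    def predict(self, tumor_expr: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "models_"):
            raise ValueError("model is not fitted")
        out = {}
        for drug, m in self.models_.items():
            out[drug] = predict_ic50(m, tumor_expr,
                                     min_overlap=self.min_gene_overlap)
        return pd.DataFrame(out, index=tumor_expr.columns)


def fit_ridge_ic50(train_expr: pd.DataFrame,
                   train_log_ic50: pd.DataFrame,
                   lambda_grid=DEFAULT_LAMBDA_GRID
                   ) -> dict[str, DrugModel]:
    """Fit one ridge model per drug; see :class:`RidgeIC50`."""
    est = RidgeIC50(lambda_grid=lambda_grid)
    est.fit(train_expr, train_log_ic50)
    return est.models_


def predict_ic50(model: DrugModel, tumor_expr: pd.DataFrame,
                 min_overlap: float = 0.5) -> pd.Series:
    """Predict log-IC50 for every tumor sample from one drug model."""
    present = [g for g in model.genes if g in tumor_expr.index]
    if len(present) < min_overlap * len(model.genes):
        raise ValueError(
            f"only {len(present)}/{len(model.genes)} model genes present "
            f"in the tumor matrix (need >= {min_overlap:.0%})")
    Z = np.zeros((tumor_expr.shape[1], len(model.genes)))
    gene_pos = {g: i for i, g in enumerate(model.genes)}
    for g in present:
        i = gene_pos[g]
        Z[:, i] = ((tumor_expr.loc[g].to_numpy(dtype=float)
                    - model.feature_mean[i]) / model.feature_sd[i])
    pred = Z @ model.coef + model.intercept
    return pd.Series(pred, index=tumor_expr.columns, name=model.drug_id)


def rank_drugs_between_groups(predictions: pd.DataFrame,
                              groups: pd.Series,
                              top_k: int | None = None) -> pd.DataFrame:
    """Rank drugs by differential predicted sensitivity between groups.

    ``predictions`` is samples x drugs; ``groups`` is a two-level label
    (e.g. high/low ICI score). Per drug a two-sided rank-sum test
    compares predicted log-IC50 between groups; output is sorted by p
    ascending (ties broken by effect magnitude) with the median
    difference as the direction.
    """
    groups = groups.reindex(predictions.index)
    levels = sorted(groups.dropna().unique().tolist())
    if len(levels) != 2:
        raise ValueError("need exactly 2 groups")
    a_idx = groups == levels[0]
    b_idx = groups == levels[1]
    rows = []
    for drug in predictions.columns:
        a = predictions.loc[a_idx, drug].to_numpy()
        b = predictions.loc[b_idx, drug].to_numpy()
        u, p = rank_stats(a, b)
        effect = float(np.median(a) - np.median(b))
        rows.append({"drug": drug, "p": p, "effect": effect,
                     "direction": (f"lower_in_{levels[0]}" if effect < 0
                                   else f"lower_in_{levels[1]}")})
    out = (pd.DataFrame(rows)
           .assign(_abs=lambda d: d["effect"].abs())
           .sort_values(["p", "_abs"], ascending=[True, False],
                        kind="mergesort")
           .drop(columns="_abs")
           .set_index("drug"))
    return out.head(top_k) if top_k else out


# ----------------------------------------------------------- enrichment

def _running_es(in_set: np.ndarray, scores: np.ndarray,
                weight: float) -> float:
    """Weighted KS enrichment score of a pre-sorted ranking.

    ``in_set`` marks set members along the ranking (best first); hits
    step up proportionally to |score|^weight, misses step down by
    1/(N - n_set). Returns the running-sum value of maximum deviation
    from zero.
    """
    n = len(in_set)
    n_in = int(in_set.sum())
    w = np.abs(scores) ** weight if weight != 0 else np.ones(n)
    hit_w = np.where(in_set, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        return 0.0
    steps = hit_w / total - (~in_set) / (n - n_in)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_preranked(ranked_genes: pd.Series,
                   gene_sets: dict[str, list[str]],
                   n_perm: int = 1000, weight: float = 1.0,
                   seed: int = 0) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    ``ranked_genes`` maps gene -> ranking score (e.g. moderated t from
    the high-vs-low ICI contrast); genes are sorted descending. Per set,
    ES is the weighted KS maximum deviation; the null re-draws the set's
    positions uniformly (equivalent to permuting gene labels);
    NES = ES / mean(|null ES| of matching sign); p is one-sided on the
    matching sign with add-one smoothing, so p >= 1/(n_perm+1). BH FDR is
    applied across sets.
    """
    if len(ranked_genes) < 10:
        raise ValueError("need at least 10 ranked genes")
    order = ranked_genes.sort_values(ascending=False, kind="mergesort")
    genes = order.index.to_numpy()
    scores = order.to_numpy(dtype=float)
    N = len(genes)
    rng = np.random.default_rng(seed)
    rows = []
    for name, members in gene_sets.items():
        mask = np.isin(genes, list(members))
        n_in = int(mask.sum())
        if n_in < 2:
            raise ValueError(f"set {name!r} has < 2 genes in the ranking")
        if n_in == N:
            raise ValueError(f"set {name!r} covers the whole ranking")
        es = _running_es(mask, scores, weight)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.zeros(N, dtype=bool)
            perm[rng.choice(N, size=n_in, replace=False)] = True
            null[b] = _running_es(perm, scores, weight)
        same = null * np.sign(es) > 0
        denom = np.abs(null[same]).mean() if same.any() else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        hits = int(np.sum(same & (np.abs(null) >= abs(es))))
        p = (hits + 1) / (n_perm + 1)
        rows.append({"set_name": name, "size": n_in, "es": es,
                     "nes": nes, "p": p})
    out = pd.DataFrame(rows).set_index("set_name")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def ora_hypergeometric(query: list[str],
                       term_sets: dict[str, list[str]],
                       universe: list[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each term set.

    p = P(X >= k) with population N = |universe|, K = |term ∩ universe|
    successes and n = |query| draws; BH FDR across terms.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    if not q <= uni:
        raise ValueError("query must be a subset of the universe")
    N, n = len(uni), len(q)
    rows = []
    for name, members in term_sets.items():
        term = set(members) & uni
        k = len(q & term)
        p = float(stats.hypergeom.sf(k - 1, N, len(term), n))
        rows.append({"term": name, "term_size": len(term), "overlap": k,
                     "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("term")
    out["fdr"] = bh_adjust(np.clip(out["p"].to_numpy(),
                                   np.finfo(float).tiny, 1.0))
    return out


# -------------------------------------------------------- rank statistics

def rank_stats(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration for small groups (min n <= 8, no ties), normal
    approximation with tie correction otherwise; fully tied data gives
    p = 1. Returns (U statistic, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least 1 observation")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return float(len(x) * len(y) / 2.0), 1.0
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(groups: list) -> tuple[float, int, float]:
    """Kruskal-Wallis H test across >= 2 groups; returns (H, df, p)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group needs at least 1 observation")
    df = len(arrays) - 1
    combined = np.concatenate(arrays)
    if np.all(combined == combined[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), df, float(p)


def response_rate_summary(response: pd.Series,
                          groups: pd.Series) -> pd.DataFrame:
    """Objective-response-rate summary per group (responders / total),
    for immunotherapy-style cohorts with binary responder labels."""
    groups = groups.reindex(response.index)
    rows = []
    for g in sorted(groups.dropna().unique()):
        r = response[groups == g].astype(bool)
        rows.append({"group": g, "n": len(r),
                     "responders": int(r.sum()),
                     "orr": float(r.mean())})
    return pd.DataFrame(rows).set_index("group")
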