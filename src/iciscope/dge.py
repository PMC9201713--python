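"""Empirical-Bayes moderated differential expression.

Two-group comparisons use the moderated t-statistic: per-gene residual
variances are shrunk toward a pooled prior estimated by method of moments
on the log variances (digamma/trigamma matching, with the trigamma inverse
found by Newton iteration), and the resulting t-statistic gains the prior
degrees of freedom. DEG selection applies the conventional cutoffs
|fold change| > 1.5 and Benjamini-Hochberg FDR < 0.05 in one-vs-rest
contrasts, assigning each DEG to the cluster where it is up-regulated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats


def _trigamma_inverse(y: float, tol: float = 1e-8,
                      max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/x scale."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif / x) < tol:
            return x
    return np.inf  # divergence -> caller falls back to a fully pooled prior


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior (d0, s0^2) to observed
    residual variances ``s2`` with ``df`` degrees of freedom each.

    Matches the mean and variance of log s^2 against the theoretical
    digamma/trigamma moments. Returns ``d0 = inf`` (fully pooled) when the
    excess variance is non-positive or the trigamma inversion diverges.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(s2[ok].mean()) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_var = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e.mean()))
    half_d0 = _trigamma_inverse(e_var)
    if not np.isfinite(half_d0):
        return np.inf, float(np.exp(e.mean()))
    d0 = 2.0 * half_d0
    s0_2 = float(np.exp(e.mean() + special.digamma(half_d0)
                        - np.log(half_d0)))
    return d0, s0_2


def moderated_t(expr_log: pd.DataFrame,
                group_a: list[str], group_b: list[str],
                d0: float | None = None) -> pd.DataFrame:
    """Moderated two-group t-test per gene.

    Parameters
    ----------
    expr_log : DataFrame
        Genes x samples on the log2 scale.
    group_a, group_b : lists of sample ids
        Each with at least 2 samples; ``log2fc`` is mean(A) - mean(B).
    d0 : float, optional
        Prior degrees of freedom; ``None`` estimates (d0, s0^2) from the
        data, 0 reproduces the ordinary equal-variance t-test, ``inf``
        pools completely.

    Returns
    -------
    DataFrame with columns log2fc, t_mod, p, df_total indexed by gene.
    """
    for name, g in (("group_a", group_a), ("group_b", group_b)):
        if len(g) < 2:
            raise ValueError(f"{name} needs at least 2 samples")
    A = expr_log[list(group_a)].to_numpy(dtype=float)
    B = expr_log[list(group_b)].to_numpy(dtype=float)
    na, nb = A.shape[1], B.shape[1]
    beta = A.mean(axis=1) - B.mean(axis=1)
    ss = (((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
          + ((B - B.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
    df_resid = na + nb - 2
    s2 = ss / df_resid

    if d0 is None:
        d0_est, s0_2 = estimate_prior(s2, df_resid)
    else:
        d0_est = float(d0)
        _, s0_2 = estimate_prior(s2, df_resid)
    if d0_est == 0:
        s2_post = s2
    elif np.isinf(d0_est):
        s2_post = np.full_like(s2, s0_2)
    else:
        s2_post = (d0_est * s0_2 + df_resid * s2) / (d0_est + df_resid)

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    df_total = d0_est + df_resid
    df_eff = min(df_total, 1e6)  # t with huge df ~ normal
    p = 2.0 * stats.t.sf(np.abs(t), df_eff)
    p = np.where(se > 0, np.clip(p, np.finfo(float).tiny, 1.0), 1.0)
    return pd.DataFrame(
        {"log2fc": beta, "t_mod": t, "p": p, "df_total": df_total},
        index=expr_log.index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    q_i = min_{j >= i} p_(j) * m / j over the ascending order, capped at
    1; computed literally as that minimum so it agrees bit-for-bit with
    a direct evaluation of the definition.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    stepped = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(stepped[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def select_degs(expr: pd.DataFrame, cluster_labels: pd.Series,
                fc_cut: float = 1.5, fdr_cut: float = 0.05,
                log_transform: bool = True) -> pd.DataFrame:
    """Select DEGs between clusters via one-vs-rest moderated t-tests.

    A gene is a DEG when |log2 fold change| strictly exceeds
    ``log2(fc_cut)`` and the within-contrast BH FDR is below ``fdr_cut``
    in at least one one-vs-rest comparison. Each DEG is assigned to the
    cluster with the highest mean expression among the comparisons where
    it is significantly up-regulated (falling back to the overall
    highest-mean cluster for the rare purely-down gene).

    Returns a table (gene, cluster, log2fc, t, p, fdr) where ``cluster``
    is empty for non-DEGs; log2fc/t/p/fdr come from the smallest-p
    contrast.
    """
    cluster_labels = cluster_labels.reindex(expr.columns)
    if cluster_labels.isna().any():
        raise ValueError("every sample needs a cluster label")
    clusters = sorted(cluster_labels.unique().tolist())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    counts = cluster_labels.value_counts()
    if (counts < 2).any():
        raise ValueError("every cluster needs at least 2 samples")

    X = np.log2(expr + 1.0) if log_transform else expr
    lfc_cut = np.log2(fc_cut)
    per_cluster: dict = {}
    for c in clusters:
        in_c = cluster_labels.index[cluster_labels == c].tolist()
        rest = cluster_labels.index[cluster_labels != c].tolist()
        res = moderated_t(X, in_c, rest)
        res["fdr"] = bh_adjust(res["p"].to_numpy())
        res["mean_in"] = X[in_c].mean(axis=1)
        per_cluster[c] = res

    genes = expr.index
    rows = []
    for g in genes:
        sig_any = False
        up_sig: list[tuple[float, str]] = []
        best = None  # (p, cluster)
        for c in clusters:
            r = per_cluster[c].loc[g]
            if best is None or r["p"] < best[0]:
                best = (r["p"], c)
            if abs(r["log2fc"]) > lfc_cut and r["fdr"] < fdr_cut:
                sig_any = True
                if r["log2fc"] > 0:
                    up_sig.append((r["mean_in"], c))
        assigned = ""
        if sig_any:
            if up_sig:
                assigned = max(up_sig)[1]
            else:
                assigned = max((per_cluster[c].loc[g, "mean_in"], c)
                               for c in clusters)[1]
        r = per_cluster[best[1]].loc[g]
        rows.append({"gene": g, "cluster": assigned,
                     "log2fc": r["log2fc"], "t": r["t_mod"],
                     "p": r["p"], "fdr": r["fdr"]})
    return pd.DataFrame(rows).set_index("gene")
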