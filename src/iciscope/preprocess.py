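"""Unit conversion and cross-cohort batch correction.

``fpkm_to_tpm`` rescales each sample so transcript abundances sum to one
million. ``combat_correct`` removes additive and multiplicative batch
effects with the parametric empirical-Bayes procedure (location/scale model
with normal / inverse-gamma priors on the per-batch parameters, shrunken by
a method-of-moments fit and an iterative fixed point), operating on
log2(x+1) values and back-transforming to linear space.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def fpkm_to_tpm(expr: pd.DataFrame) -> pd.DataFrame:
    """Convert an FPKM matrix (genes x samples) to TPM.

    TPM(g, j) = FPKM(g, j) / sum_g FPKM(g, j) * 1e6, so each sample column
    sums to 1e6. Raises on all-zero columns (the normalization is
    undefined) and on input already tagged as TPM.
    """
    if expr.attrs.get("unit", "FPKM").upper() == "TPM":
        raise ValueError("input is already TPM (unit tag)")
    if (expr.to_numpy() < 0).any():
        raise ValueError("negative expression values")
    col_sums = expr.sum(axis=0)
    zero = col_sums[col_sums == 0]
    if len(zero):
        raise ValueError(
            f"all-zero sample column(s): {zero.index.tolist()[:5]}")
    out = expr.div(col_sums, axis=1) * 1e6
    out.attrs["unit"] = "TPM"
    return out


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m ** 2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m ** 3) / s2


def _it_sol(z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
            g_bar: float, t2: float, a: float, b: float,
            tol: float = 1e-4, max_iter: int = 500
            ) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-point iteration for the shrunken batch location gamma* and
    scale delta^2* of one batch (rows = genes, cols = batch samples)."""
    n = z.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        ss = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * ss + b) / (n / 2.0 + a - 1.0)
        change = max(np.max(np.abs(g_new - g_old) / np.abs(g_old + 1e-30)),
                     np.max(np.abs(d_new - d_old) / np.abs(d_old + 1e-30)))
        g_old, d_old = g_new, d_new
        if change < tol:
            break
    return g_old, d_old


def _nonparam_sol(z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Non-parametric empirical-Bayes estimates: for each gene, weight every
    other gene's (gamma_hat, delta_hat) by the normal likelihood of this
    gene's batch residuals under those parameters (Monte Carlo integration
    over the empirical prior). O(G^2); intended for small panels."""
    n = z.shape[1]
    G = len(g_hat)
    g_star = np.empty(G)
    d_star = np.empty(G)
    for i in range(G):
        mask = np.arange(G) != i
        g, d = g_hat[mask], d_hat[mask]
        resid2 = ((z[i][None, :] - g[:, None]) ** 2).sum(axis=1)
        log_lik = -n / 2.0 * np.log(2 * np.pi * d) - resid2 / (2 * d)
        w = np.exp(log_lik - log_lik.max())
        w_sum = w.sum()
        g_star[i] = (w * g).sum() / w_sum
        d_star[i] = (w * d).sum() / w_sum
    return g_star, d_star


def combat_correct(expr: pd.DataFrame,
                   batch_labels: pd.Series,
                   parametric: bool = True,
                   log_transform: bool = True,
                   tol: float = 1e-4) -> pd.DataFrame:
    """Empirical-Bayes batch correction of an expression matrix.

    Parameters
    ----------
    expr : DataFrame
        Genes x samples, non-negative linear-scale values.
    batch_labels : Series
        Batch label per sample (index must cover all sample columns).
        With a single batch the function is the identity.
    parametric : bool
        Parametric normal/inverse-gamma priors (default); ``False``
        switches to the non-parametric weighted estimator.
    log_transform : bool
        Work on log2(x+1) and back-transform (default); set ``False`` if
        the input is already on a log-like scale.

    Notes
    -----
    Genes with zero pooled variance are passed through untouched (with a
    warning) — merged cohorts routinely contain them. A batch with a
    single sample raises, since its scale parameter is undefined.
    """
    batch_labels = batch_labels.reindex(expr.columns)
    if batch_labels.isna().any():
        missing = expr.columns[batch_labels.isna()].tolist()
        raise ValueError(f"samples without batch label: {missing[:5]}")
    batches = batch_labels.unique().tolist()
    if len(batches) == 1:
        return expr.copy()
    counts = batch_labels.value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"batch(es) with a single sample: {bad}")

    X = expr.to_numpy(dtype=float)
    if log_transform:
        X = np.log2(X + 1.0)

    n_total = X.shape[1]
    masks = {b: (batch_labels == b).to_numpy() for b in batches}
    batch_means = np.column_stack(
        [X[:, masks[b]].mean(axis=1) for b in batches])
    n_per = np.array([masks[b].sum() for b in batches])
    grand = batch_means @ (n_per / n_total)
    resid = X.copy()
    for i, b in enumerate(batches):
        resid[:, masks[b]] = X[:, masks[b]] - batch_means[:, [i]]
    var_pooled = (resid ** 2).mean(axis=1)

    keep = var_pooled > 0
    if not keep.all():
        warnings.warn(
            f"{(~keep).sum()} gene(s) with zero pooled variance passed "
            "through unadjusted", stacklevel=2)
    Z = np.zeros_like(X)
    sd = np.sqrt(var_pooled[keep])
    Z[keep] = (X[keep] - grand[keep, None]) / sd[:, None]

    adjusted = Z.copy()
    for i, b in enumerate(batches):
        m = masks[b]
        zb = Z[keep][:, m]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        d_hat = np.maximum(d_hat, 1e-12)
        if parametric:
            g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
            a, b_pr = _aprior(d_hat), _bprior(d_hat)
            g_star, d_star = _it_sol(zb, g_hat, d_hat, g_bar, t2, a, b_pr,
                                     tol=tol)
        else:
            g_star, d_star = _nonparam_sol(zb, g_hat, d_hat)
        block = (zb - g_star[:, None]) / np.sqrt(d_star)[:, None]
        tmp = adjusted[keep]
        tmp[:, m] = block
        adjusted[keep] = tmp

    out = X.copy()
    out[keep] = adjusted[keep] * sd[:, None] + grand[keep, None]
    if log_transform:
        out = np.clip(np.exp2(out) - 1.0, 0.0, None)
    res = pd.DataFrame(out, index=expr.index, columns=expr.columns)
    res.attrs.update(expr.attrs)
    return res
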