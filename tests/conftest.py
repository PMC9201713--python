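import numpy as np
import pandas as pd
import pytest

from iciscope import syndata


@pytest.fixture(scope="session")
def signature():
    """220-gene, 22-type marker-block signature (10 markers per type)."""
    return syndata.make_signature_matrix(220, 22, seed=1)


@pytest.fixture(scope="session")
def noisy_cohort(signature):
    """Three-subtype cohort at the reference noise level (n=200)."""
    return syndata.simulate_bulk_cohort(signature, n_samples=200,
                                        noise_sd=0.1, seed=2)


@pytest.fixture(scope="session")
def hot_cold_cohort(signature):
    """Two-subtype (hot/cold) cohort for binary-truth experiments."""
    profiles = syndata.hot_cold_profiles(list(signature.columns))
    return syndata.simulate_bulk_cohort(
        signature, n_samples=200, subtype_profiles=profiles,
        noise_sd=0.1, hazard_multiplier={"hot": 1.0, "cold": 2.0},
        seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def brute_force_ssgsea(expr: pd.DataFrame, gene_set, alpha: float = 0.25
                       ) -> pd.Series:
    """O(N * |set|) reference ssGSEA (integrated difference), computed
    with explicit per-position loops; independent of the package path."""
    from scipy.stats import rankdata
    gs = set(gene_set)
    out = {}
    for s in expr.columns:
        x = expr[s]
        ranks = rankdata(x.to_numpy())
        order = np.lexsort((np.arange(len(x)), -x.to_numpy()))
        genes = x.index.to_numpy()[order]
        rk = ranks[order]
        N = len(genes)
        n_in = sum(g in gs for g in genes)
        w_sum = sum(rk[i] ** alpha for i in range(N) if genes[i] in gs)
        p_in = p_out = es = 0.0
        for i in range(N):
            if genes[i] in gs:
                p_in += rk[i] ** alpha / w_sum
            else:
                p_out += 1.0 / (N - n_in)
            es += p_in - p_out
        out[s] = es
    return pd.Series(out)


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Double-loop BH step-up oracle."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank, i in enumerate(order, start=1):
        best = min(p[j] * m / (list(order).index(j) + 1)
                   for j in order[rank - 1:])
        q[i] = min(best, 1.0)
    return q
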