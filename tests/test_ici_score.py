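import numpy as np
import pandas as pd
import pytest

from iciscope import ici_score
from iciscope.ici_score import SignatureGeneSets

from conftest import brute_force_ssgsea


class TestAssignSignatureGenes:
    @pytest.fixture()
    def clustered(self, rng):
        samples = [f"s{i}" for i in range(60)]
        labels = pd.Series(["A"] * 20 + ["B"] * 20 + ["C"] * 20,
                           index=samples)
        ordering = {"A": 3.0, "B": 2.0, "C": 1.0}
        axis = labels.map(ordering).to_numpy()
        up = np.vstack([axis * 2 + rng.normal(0, 0.1, 60)
                        for _ in range(5)])
        down = np.vstack([-axis * 2 + rng.normal(0, 0.1, 60)
                          for _ in range(5)])
        expr = pd.DataFrame(np.vstack([up, down]),
                            index=[f"up{i}" for i in range(5)]
                            + [f"dn{i}" for i in range(5)],
                            columns=samples)
        return expr, labels, ordering

    def test_monotone_gene_goes_to_set_a(self, clustered):
        expr, labels, ordering = clustered
        sets = ici_score.assign_signature_genes(expr, labels,
                                                ordering=ordering)
        assert set(sets.set_A) == {f"up{i}" for i in range(5)}
        assert set(sets.set_B) == {f"dn{i}" for i in range(5)}

    def test_negated_gene_lands_in_opposite_set(self, clustered):
        expr, labels, ordering = clustered
        expr2 = expr.copy()
        expr2.loc["neg"] = -expr.loc["up0"]
        sets = ici_score.assign_signature_genes(expr2, labels,
                                                ordering=ordering)
        assert "up0" in sets.set_A and "neg" in sets.set_B

    def test_immune_score_ordering_used_when_no_explicit(self, clustered):
        expr, labels, ordering = clustered
        imm = labels.map(ordering) * 10.0  # cluster A most immune
        sets = ici_score.assign_signature_genes(expr, labels,
                                                immune_score=imm)
        assert set(sets.set_A) == {f"up{i}" for i in range(5)}

    def test_constant_gene_dropped_with_warning(self, clustered):
        expr, labels, ordering = clustered
        expr2 = expr.copy()
        expr2.loc["flat"] = 1.0
        with pytest.warns(UserWarning, match="dropped"):
            sets = ici_score.assign_signature_genes(expr2, labels,
                                                    ordering=ordering)
        assert "flat" not in sets.set_A + sets.set_B

    def test_sets_must_be_disjoint_nonempty(self):
        with pytest.raises(ValueError):
            SignatureGeneSets(set_A=["g1"], set_B=["g1"])
        with pytest.raises(ValueError):
            SignatureGeneSets(set_A=[], set_B=["g1"])


class TestBoruta:
    def _classed_data(self, rng, n=150, informative=5, noise=50):
        y = pd.Series(rng.integers(0, 2, size=n),
                      index=[f"s{i}" for i in range(n)])
        sig = np.outer(y.to_numpy(), rng.uniform(2, 3, informative))
        X = np.hstack([sig + rng.normal(0, 0.3, (n, informative)),
                       rng.normal(0, 1, (n, noise))])
        cols = [f"inf{i}" for i in range(informative)] + \
               [f"noise{i}" for i in range(noise)]
        return pd.DataFrame(X, index=y.index, columns=cols), y

    def test_informative_confirmed_noise_rejected(self, rng):
        X, y = self._classed_data(rng)
        kept = ici_score.boruta_reduce(X, y, max_iter=25, seed=1,
                                       n_estimators=60)
        assert set(f"inf{i}" for i in range(5)) <= set(kept)
        n_noise_kept = sum(1 for g in kept if g.startswith("noise"))
        assert n_noise_kept <= 5

    def test_all_noise_nothing_confirmed(self, rng):
        y = pd.Series(rng.integers(0, 2, size=100),
                      index=[f"s{i}" for i in range(100)])
        X = pd.DataFrame(rng.normal(size=(100, 20)), index=y.index,
                         columns=[f"n{i}" for i in range(20)])
        kept = ici_score.boruta_reduce(X, y, max_iter=20, seed=2,
                                       n_estimators=40)
        assert len(kept) <= 2

    def test_single_iteration_still_decides_everything(self, rng):
        X, y = self._classed_data(rng, n=60, informative=3, noise=10)
        sel = ici_score.BorutaSelector(max_iter=1, random_state=3,
                                       n_estimators=30)
        sel.fit(X.to_numpy(), y.to_numpy())
        assert set(sel.decision_) <= {"tentative-confirmed",
                                      "tentative-rejected"}
        assert len(sel.support_) == X.shape[1]

    def test_deterministic_under_seed(self, rng):
        X, y = self._classed_data(rng, n=80, informative=3, noise=15)
        k1 = ici_score.boruta_reduce(X, y, max_iter=10, seed=5,
                                     n_estimators=30)
        k2 = ici_score.boruta_reduce(X, y, max_iter=10, seed=5,
                                     n_estimators=30)
        assert k1 == k2


class TestSsgsea:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(30, 120))
            expr = pd.DataFrame(
                rng.uniform(0, 10, size=(n, 3)),
                index=[f"g{i}" for i in range(n)], columns=list("abc"))
            gene_set = list(rng.choice(expr.index,
                                       int(rng.integers(3, 15)),
                                       replace=False))
            got = ici_score.ssgsea(expr, gene_set)
            want = brute_force_ssgsea(expr, gene_set)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_top_ranked_set_is_maximal(self, rng):
        expr = pd.DataFrame({"s": np.arange(100, 0, -1.0)},
                            index=[f"g{i}" for i in range(100)])
        top = [f"g{i}" for i in range(10)]
        es_top = ici_score.ssgsea(expr, top)["s"]
        for _ in range(25):
            other = list(rng.choice(expr.index, 10, replace=False))
            assert es_top >= ici_score.ssgsea(expr, other)["s"]

    def test_monotone_transform_invariance(self, rng):
        expr = pd.DataFrame(rng.uniform(1, 5, size=(50, 4)),
                            index=[f"g{i}" for i in range(50)],
                            columns=list("wxyz"))
        gs = list(expr.index[:8])
        a = ici_score.ssgsea(expr, gs)
        b = ici_score.ssgsea(np.exp(expr) * 3, gs)
        pd.testing.assert_series_equal(a, b)

    def test_degenerate_sets_rejected(self, rng):
        expr = pd.DataFrame(rng.uniform(size=(10, 2)),
                            index=[f"g{i}" for i in range(10)],
                            columns=["a", "b"])
        with pytest.raises(ValueError, match="no gene"):
            ici_score.ssgsea(expr, ["zz"])
        with pytest.raises(ValueError, match="every gene"):
            ici_score.ssgsea(expr, list(expr.index))


class TestICIScore:
    def test_identical_sets_cancel(self, rng):
        expr = pd.DataFrame(rng.uniform(0, 5, size=(40, 6)),
                            index=[f"g{i}" for i in range(40)],
                            columns=[f"s{i}" for i in range(6)])
        gs = list(expr.index[:6])
        a = ici_score.ssgsea(expr, gs)
        diff = a - a
        assert (diff.abs() < 1e-15).all()

    def test_median_split_half_half_ties_to_low(self, rng):
        expr = pd.DataFrame(rng.uniform(0, 5, size=(40, 10)),
                            index=[f"g{i}" for i in range(40)],
                            columns=[f"s{i}" for i in range(10)])
        sets = SignatureGeneSets(set_A=list(expr.index[:5]),
                                 set_B=list(expr.index[5:10]))
        tab = ici_score.compute_ici_score_ssgsea(expr, sets)
        assert tab["ici_score"].equals(tab["score_A"] - tab["score_B"])
        assert (tab["group"] == "high").sum() <= 5
        assert (tab.loc[tab["ici_score"] <= tab["ici_score"].median(),
                        "group"] == "low").all()

    def test_sample_permutation_equivariance(self, rng):
        expr = pd.DataFrame(rng.uniform(0, 5, size=(30, 8)),
                            index=[f"g{i}" for i in range(30)],
                            columns=[f"s{i}" for i in range(8)])
        sets = SignatureGeneSets(set_A=list(expr.index[:4]),
                                 set_B=list(expr.index[4:8]))
        t1 = ici_score.compute_ici_score_ssgsea(expr, sets)
        perm = list(expr.columns[::-1])
        t2 = ici_score.compute_ici_score_ssgsea(expr[perm], sets)
        pd.testing.assert_frame_equal(t1.loc[perm], t2)


class TestPCAScore:
    def test_rank_one_expression_recovers_loading_direction(self, rng):
        u = rng.uniform(1, 2, size=10)   # genes
        v = rng.normal(size=40)          # samples
        expr = pd.DataFrame(np.outer(u, v),
                            index=[f"a{i}" for i in range(10)],
                            columns=[f"s{i}" for i in range(40)])
        expr_b = pd.DataFrame(rng.normal(size=(5, 40)),
                              index=[f"b{i}" for i in range(5)],
                              columns=expr.columns)
        full = pd.concat([expr, expr_b])
        sets = SignatureGeneSets(set_A=list(expr.index),
                                 set_B=list(expr_b.index))
        tab = ici_score.compute_ici_score_pca(full, sets,
                                              mode="difference")
        # PC1 of a rank-1 block is the sample factor (z-scored scale)
        r = np.corrcoef(tab["score_A"], v)[0, 1]
        assert abs(r) > 0.999999

    def test_orientation_makes_result_sign_stable(self, rng):
        expr = pd.DataFrame(rng.normal(size=(12, 30)),
                            index=[f"g{i}" for i in range(12)],
                            columns=[f"s{i}" for i in range(30)])
        sets = SignatureGeneSets(set_A=list(expr.index[:6]),
                                 set_B=list(expr.index[6:]))
        imm = pd.Series(rng.normal(size=30), index=expr.columns)
        t1 = ici_score.compute_ici_score_pca(expr, sets,
                                             immune_score=imm)
        t2 = ici_score.compute_ici_score_pca(expr.iloc[::-1], sets,
                                             immune_score=imm)
        np.testing.assert_allclose(t1["ici_score"], t2["ici_score"],
                                   atol=1e-8)
        assert (np.corrcoef(t1["score_A"], imm)[0, 1] > 0)

    def test_absolute_mode_is_sum_of_magnitudes(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 20)),
                            index=[f"g{i}" for i in range(10)],
                            columns=[f"s{i}" for i in range(20)])
        sets = SignatureGeneSets(set_A=list(expr.index[:5]),
                                 set_B=list(expr.index[5:]))
        tab = ici_score.compute_ici_score_pca(expr, sets, mode="absolute")
        np.testing.assert_allclose(
            tab["ici_score"],
            tab["score_A"].abs() + tab["score_B"].abs())

    def test_filter_leaving_too_few_genes_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(6, 10)),
                            index=[f"g{i}" for i in range(6)],
                            columns=[f"s{i}" for i in range(10)])
        sets = SignatureGeneSets(set_A=list(expr.index[:3]),
                                 set_B=list(expr.index[3:]))
        with pytest.raises(ValueError, match="fewer than 2"):
            ici_score.compute_ici_score_pca(expr, sets,
                                            prognostic_filter=["g0"])
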