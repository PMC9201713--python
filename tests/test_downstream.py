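import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from iciscope import downstream, syndata


class TestRidgeIC50:
    def test_noiseless_training_residuals_vanish(self):
        expr, ic50, _ = syndata.simulate_drug_training(
            n_lines=60, n_genes=20, n_drugs=3, noise_sd=0.0, seed=1)
        est = downstream.RidgeIC50(lambda_grid=[1e-6]).fit(expr, ic50)
        pred = est.predict(expr)
        resid = (pred - ic50).to_numpy()
        assert np.abs(resid).max() < 1e-3

    def test_held_out_prediction_accuracy(self):
        expr, ic50, _ = syndata.simulate_drug_training(
            n_lines=200, n_genes=50, n_drugs=5, noise_sd=0.2, seed=2)
        train = list(expr.columns[:140])
        test = list(expr.columns[140:])
        est = downstream.RidgeIC50().fit(expr[train], ic50.loc[train])
        pred = est.predict(expr[test])
        for d in ic50.columns:
            r = np.corrcoef(pred[d], ic50.loc[test, d])[0, 1]
            assert r >= 0.9

    def test_null_drug_prediction_uncorrelated(self):
        expr, ic50, _ = syndata.simulate_drug_training(
            n_lines=150, n_genes=30, n_drugs=2, noise_sd=0.3,
            null_drugs=["drug_00"], seed=3)
        train = list(expr.columns[:100])
        test = list(expr.columns[100:])
        est = downstream.RidgeIC50().fit(expr[train], ic50.loc[train])
        pred = est.predict(expr[test])
        r = np.corrcoef(pred["drug_00"], ic50.loc[test, "drug_00"])[0, 1]
        assert abs(r) < 0.35

    def test_training_line_predicts_its_fitted_value(self):
        expr, ic50, _ = syndata.simulate_drug_training(
            n_lines=40, n_genes=10, n_drugs=2, noise_sd=0.1, seed=4)
        est = downstream.RidgeIC50().fit(expr, ic50)
        one = expr[[expr.columns[0]]]
        again = est.predict(one)
        full = est.predict(expr)
        np.testing.assert_allclose(again.iloc[0], full.iloc[0])

    def test_missing_genes_imputed_but_total_absence_rejected(self):
        expr, ic50, _ = syndata.simulate_drug_training(
            n_lines=30, n_genes=10, n_drugs=1, seed=5)
        est = downstream.RidgeIC50().fit(expr, ic50)
        partial = expr.iloc[:6]  # 60% of genes present
        est.predict(partial)  # imputes the rest at z=0
        none = expr.iloc[:2]
        with pytest.raises(ValueError, match="model genes"):
            est.predict(none)

    def test_too_few_lines_rejected(self):
        expr, ic50, _ = syndata.simulate_drug_training(
            n_lines=10, n_genes=5, n_drugs=1, seed=6)
        with pytest.raises(ValueError, match="3 training lines"):
            downstream.RidgeIC50().fit(expr.iloc[:, :2], ic50.iloc[:2])


class TestRankDrugs:
    def test_planted_differential_drug_ranks_first(self, rng):
        samples = [f"s{i}" for i in range(60)]
        groups = pd.Series(["high"] * 30 + ["low"] * 30, index=samples)
        preds = pd.DataFrame(rng.normal(size=(60, 21)), index=samples,
                             columns=[f"d{i}" for i in range(21)])
        preds["d0"] += np.where(groups == "high", -2.0, 0.0)
        out = downstream.rank_drugs_between_groups(preds, groups)
        assert out.index[0] == "d0"
        assert out.loc["d0", "direction"] == "lower_in_high"

    def test_top_k_truncation(self, rng):
        samples = [f"s{i}" for i in range(20)]
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=samples)
        preds = pd.DataFrame(rng.normal(size=(20, 15)), index=samples)
        out = downstream.rank_drugs_between_groups(preds, groups,
                                                   top_k=12)
        assert len(out) == 12

    def test_identical_groups_deterministic_order(self, rng):
        samples = [f"s{i}" for i in range(12)]
        groups = pd.Series(["a", "b"] * 6, index=samples)
        vals = rng.normal(size=(12, 4))
        p1 = downstream.rank_drugs_between_groups(
            pd.DataFrame(vals, index=samples), groups)
        p2 = downstream.rank_drugs_between_groups(
            pd.DataFrame(vals, index=samples), groups)
        pd.testing.assert_frame_equal(p1, p2)


class TestGSEA:
    @staticmethod
    def brute_force_es(ranked, members, weight=1.0):
        order = ranked.sort_values(ascending=False, kind="mergesort")
        genes = list(order.index)
        gs = set(members)
        n = len(genes)
        n_in = sum(g in gs for g in genes)
        total = sum(abs(order[g]) ** weight for g in genes if g in gs)
        running = best = 0.0
        for g in genes:
            if g in gs:
                running += abs(order[g]) ** weight / total
            else:
                running -= 1.0 / (n - n_in)
            if abs(running) > abs(best):
                best = running
        return best

    def test_es_matches_running_sum_oracle(self, rng):
        genes = [f"g{i}" for i in range(100)]
        for _ in range(10):
            ranked = pd.Series(rng.normal(size=100), index=genes)
            members = list(rng.choice(genes, 12, replace=False))
            res = downstream.gsea_preranked(ranked, {"S": members},
                                            n_perm=10, seed=0)
            want = self.brute_force_es(ranked, members)
            assert res.loc["S", "es"] == pytest.approx(want, abs=1e-12)

    def test_top_set_attains_minimal_p(self, rng):
        ranked = pd.Series(np.linspace(5, -5, 100),
                           index=[f"g{i}" for i in range(100)])
        top5 = [f"g{i}" for i in range(5)]
        res = downstream.gsea_preranked(ranked, {"TOP": top5},
                                        n_perm=200, seed=1)
        assert res.loc["TOP", "es"] > 0
        assert res.loc["TOP", "p"] == pytest.approx(1 / 201)
        assert res.loc["TOP", "nes"] > 1

    def test_weight_zero_invariant_to_monotone_score_transform(self, rng):
        genes = [f"g{i}" for i in range(50)]
        ranked = pd.Series(rng.uniform(1, 2, size=50), index=genes)
        members = genes[::7]
        a = downstream.gsea_preranked(ranked, {"S": members}, n_perm=20,
                                      weight=0.0, seed=2)
        b = downstream.gsea_preranked(ranked ** 3, {"S": members},
                                      n_perm=20, weight=0.0, seed=2)
        assert a.loc["S", "es"] == pytest.approx(b.loc["S", "es"],
                                                 abs=1e-12)

    def test_unrepresented_set_rejected(self, rng):
        ranked = pd.Series(rng.normal(size=20),
                           index=[f"g{i}" for i in range(20)])
        with pytest.raises(ValueError, match="< 2 genes"):
            downstream.gsea_preranked(ranked, {"S": ["zz"]}, n_perm=10)


class TestORA:
    def test_exact_match_closed_form(self):
        uni = [f"u{i}" for i in range(100)]
        q = uni[:10]
        res = downstream.ora_hypergeometric(q, {"T": q}, uni)
        assert res.loc["T", "p"] == pytest.approx(
            1 / comb(100, 10, exact=True), rel=1e-9)

    def test_zero_overlap_p_is_one(self):
        uni = [f"u{i}" for i in range(30)]
        res = downstream.ora_hypergeometric(uni[:5], {"T": uni[20:]},
                                            uni)
        assert res.loc["T", "p"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_universe(self):
        # enumerate every possible draw of |query| items from N<=20
        uni = [f"u{i}" for i in range(12)]
        term = set(uni[:5])
        query = uni[3:7]  # overlap k = 2
        k_obs = len(set(query) & term)
        hits = total = 0
        for draw in itertools.combinations(uni, len(query)):
            total += 1
            if len(set(draw) & term) >= k_obs:
                hits += 1
        res = downstream.ora_hypergeometric(query, {"T": list(term)}, uni)
        assert res.loc["T", "p"] == pytest.approx(hits / total, rel=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            downstream.ora_hypergeometric([], {"T": ["a"]}, [])


class TestRankStats:
    def test_exact_enumeration_small_groups(self):
        u, p = downstream.rank_stats([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_all_tied_data_p_one(self):
        u, p = downstream.rank_stats([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0

    def test_identical_groups_h_zero(self):
        h, df, p = downstream.kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0)
        assert df == 1

    def test_three_group_null_calibration(self):
        rng = np.random.default_rng(30)
        rejections = 0
        reps = 400
        for _ in range(reps):
            g = [rng.normal(size=15) for _ in range(3)]
            _, _, p = downstream.kruskal_wallis(g)
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.08

    def test_response_rate_summary_counts(self):
        resp = pd.Series([1, 1, 0, 0, 1, 0],
                         index=[f"s{i}" for i in range(6)]).astype(bool)
        groups = pd.Series(["hi"] * 3 + ["lo"] * 3, index=resp.index)
        orr = downstream.response_rate_summary(resp, groups)
        assert orr.loc["hi", "orr"] == pytest.approx(2 / 3)
        assert orr.loc["lo", "responders"] == 1
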