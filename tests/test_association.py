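import numpy as np
import pandas as pd
import pytest
from scipy import stats

from neuromodes.association import (
    manova_pillai,
    mode_score,
    pattern_similarity,
    stratified_patterns,
)
from neuromodes.scca import CanonicalVariates

ITEMS4 = list("abcd")


def _items(rng, n, p=4):
    return pd.DataFrame(rng.standard_normal((n, p)), columns=ITEMS4[:p])


class TestModeScore:
    def test_mean_of_two_zscored_variates(self, rng):
        xu = rng.standard_normal(50)
        yv = rng.standard_normal(50)
        ms = mode_score(CanonicalVariates(xu=xu, yv=yv, index=1))
        zx = (xu - xu.mean()) / xu.std(ddof=1)
        zy = (yv - yv.mean()) / yv.std(ddof=1)
        np.testing.assert_allclose(ms.score, (zx + zy) / 2, atol=1e-12)

    def test_identical_variates_give_their_zscore(self, rng):
        x = rng.standard_normal(30)
        ms = mode_score(CanonicalVariates(xu=x, yv=x.copy(), index=1))
        np.testing.assert_allclose(
            ms.score, (x - x.mean()) / x.std(ddof=1), atol=1e-12
        )

    def test_mean_and_sum_scores_perfectly_correlated(self, rng):
        """Averaging versus adding the variates differs by a constant factor,
        so every correlation-based statistic downstream is identical."""
        xu, yv = rng.standard_normal((2, 60))
        ms = mode_score(CanonicalVariates(xu=xu, yv=yv, index=1))
        summed = ms.variate_fc + ms.variate_task
        np.testing.assert_allclose(summed, 2 * ms.score, atol=1e-12)
        other = rng.standard_normal(60)
        r_mean = np.corrcoef(ms.score, other)[0, 1]
        r_sum = np.corrcoef(summed, other)[0, 1]
        assert r_mean == pytest.approx(r_sum, abs=1e-12)

    def test_constant_variate_rejected(self):
        with pytest.raises(ValueError):
            mode_score(CanonicalVariates(xu=np.ones(10), yv=np.arange(10.0), index=1))


class TestManovaPillai:
    def test_saturated_univariate_case(self, rng):
        x = rng.standard_normal(30)
        items = pd.DataFrame({"only": 2.0 * x})
        pred = pd.DataFrame({"x": x})
        tp = manova_pillai(items, pred, zscore_items=False)[0]
        assert tp.pillai == pytest.approx(1.0, abs=1e-10)
        # raw slope recovered (coefficients are reported per SD of predictor)
        assert tp.coefficients["only"] / x.std(ddof=1) == pytest.approx(2.0)

    def test_matches_eigenvalue_oracle(self, rng):
        items = _items(rng, 40, 3)
        pred = pd.DataFrame({
            "m": rng.standard_normal(40), "c": rng.standard_normal(40)
        })
        items["a"] += 0.4 * pred["m"]
        patterns = manova_pillai(items, pred, zscore_items=True)
        # independent oracle: V = sum(lambda / (1 + lambda)), eigenvalues of
        # inv(E) @ H from an explicitly built Type III hypothesis
        Y = items.to_numpy()
        Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        X = np.column_stack([np.ones(40), pred.to_numpy()])
        G = np.linalg.inv(X.T @ X)
        B = G @ X.T @ Y
        E = (Y - X @ B).T @ (Y - X @ B)
        for j, tp in enumerate(patterns, start=1):
            L = np.zeros((1, 3))
            L[0, j] = 1
            LB = L @ B
            H = LB.T @ np.linalg.inv(L @ G @ L.T) @ LB
            lam = np.linalg.eigvals(np.linalg.inv(E) @ H).real
            V = np.sum(lam / (1 + lam))
            assert tp.pillai == pytest.approx(V, abs=1e-8)
            s = 1.0
            df_err = 40 - 3
            nn = (df_err - 3 - 1) / 2
            m = (abs(1 - 3) - 1) / 2
            F = ((2 * nn + s + 1) / (2 * m + s + 1)) * (V / (s - V))
            assert tp.f_stat == pytest.approx(F, abs=1e-8)

    def test_matches_statsmodels(self, rng):
        sm_manova = pytest.importorskip("statsmodels.multivariate.manova")
        items = _items(rng, 60, 4)
        pred = pd.DataFrame({
            "m1": rng.standard_normal(60), "age": rng.uniform(18, 31, 60)
        })
        items["a"] += 0.5 * pred["m1"]
        patterns = manova_pillai(items, pred, zscore_items=True)
        Y = items.to_numpy()
        Y = (Y - Y.mean(0)) / Y.std(0, ddof=1)
        X = np.column_stack([np.ones(60), pred.to_numpy()])
        mv = sm_manova.MANOVA(Y, X)
        hyps = [("m1", np.array([[0, 1, 0]]), None),
                ("age", np.array([[0, 0, 1]]), None)]
        res = mv.mv_test(hypotheses=hyps)
        for tp in patterns:
            row = res.results[tp.predictor]["stat"].loc["Pillai's trace"]
            assert tp.pillai == pytest.approx(float(row["Value"]), abs=1e-10)
            assert tp.f_stat == pytest.approx(float(row["F Value"]), abs=1e-8)
            assert tp.p_value == pytest.approx(float(row["Pr > F"]), abs=1e-10)

    def test_null_p_values_calibrated(self):
        """Under independence the Pillai F test rejects at close to its
        nominal level."""
        rejections = 0
        n_rep = 1000
        for rep in range(n_rep):
            rng = np.random.default_rng(3000 + rep)
            items = _items(rng, 40, 3)
            pred = pd.DataFrame({"m": rng.standard_normal(40)})
            tp = manova_pillai(items, pred, zscore_items=True)[0]
            rejections += tp.p_value < 0.05
        assert 0.03 <= rejections / n_rep <= 0.07

    def test_invariant_to_joint_linear_item_transform(self, rng):
        items = _items(rng, 50, 4)
        pred = pd.DataFrame({"m": rng.standard_normal(50)})
        items["a"] += 0.5 * pred["m"]
        base = manova_pillai(items, pred, zscore_items=False)[0]
        A = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        transformed = pd.DataFrame(items.to_numpy() @ A, columns=items.columns)
        alt = manova_pillai(transformed, pred, zscore_items=False)[0]
        assert alt.pillai == pytest.approx(base.pillai, abs=1e-8)
        assert alt.f_stat == pytest.approx(base.f_stat, abs=1e-6)

    def test_orthogonal_noise_covariate_leaves_coefficients(self, rng):
        items = _items(rng, 60, 4)
        pred = pd.DataFrame({"m": rng.standard_normal(60)})
        items["b"] += 0.6 * pred["m"]
        base = manova_pillai(items, pred, zscore_items=True)[0]
        noise = rng.standard_normal(60)
        design = np.column_stack([np.ones(60), pred["m"]])
        noise -= design @ np.linalg.lstsq(design, noise, rcond=None)[0]
        pred2 = pred.assign(noise=noise)
        augmented = manova_pillai(items, pred2, zscore_items=True)[0]
        np.testing.assert_allclose(
            augmented.coefficients, base.coefficients, atol=1e-10
        )

    def test_collinear_predictors_named(self, rng):
        pred = pd.DataFrame({"m": rng.standard_normal(40)})
        pred["copy"] = 2.0 * pred["m"]
        with pytest.raises(ValueError, match="copy"):
            manova_pillai(_items(rng, 40), pred)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="n > "):
            manova_pillai(_items(rng, 5), pd.DataFrame({"m": np.arange(5.0)}))


class TestStratifiedPatterns:
    ITEMS13 = [f"i{k}" for k in range(13)]

    @classmethod
    def _strata_table(cls, rng, n, effect=0.0, permute_day=None):
        ids = [f"s{i}" for i in range(n)]
        z = rng.standard_normal(n)
        loadings = effect * np.array(
            [1, -1, 0.5, -0.5, 1, 0, 0, 0, 0, 0, 0, 0, 0]
        )
        frames = []
        for day in (1, 2):
            items = rng.standard_normal((n, 13)) + np.outer(z, loadings)
            if permute_day == day:
                items = items[rng.permutation(n)]
            f = pd.DataFrame(items, columns=cls.ITEMS13)
            f.insert(0, "day", day)
            f.insert(0, "condition", "0-back")
            f.insert(0, "subject_id", ids)
            frames.append(f)
        table = pd.concat(frames, ignore_index=True)
        predictors = pd.DataFrame({"m": z}, index=pd.Index(ids, name="subject_id"))
        return table, predictors

    def test_identical_strata_give_identical_patterns(self, rng):
        table, predictors = self._strata_table(rng, 40, effect=0.5)
        day1 = table[table["day"] == 1].assign(day=1)
        duplicated = pd.concat(
            [day1, day1.assign(day=2)], ignore_index=True
        )
        out = stratified_patterns(duplicated, predictors, by="day",
                                  item_columns=self.ITEMS13)
        np.testing.assert_allclose(
            out[1][0].coefficients, out[2][0].coefficients, atol=1e-12
        )

    def test_consistent_coupling_yields_similar_patterns(self):
        rs = []
        for rep in range(30):
            rng = np.random.default_rng(500 + rep)
            table, predictors = self._strata_table(rng, 80, effect=0.8)
            out = stratified_patterns(table, predictors, by="day",
                                      item_columns=self.ITEMS13)
            r, _ = pattern_similarity(
                out[1][0].coefficients, out[2][0].coefficients
            )
            rs.append(r)
        assert np.median(rs) >= 0.9

    def test_permuted_stratum_decorrelates(self):
        rs = []
        for rep in range(30):
            rng = np.random.default_rng(900 + rep)
            table, predictors = self._strata_table(
                rng, 80, effect=0.8, permute_day=2
            )
            out = stratified_patterns(table, predictors, by="day",
                                      item_columns=self.ITEMS13)
            r, _ = pattern_similarity(
                out[1][0].coefficients, out[2][0].coefficients
            )
            rs.append(abs(r))
        assert np.median(rs) < 0.4

    def test_undersized_stratum_named(self, rng):
        table, predictors = self._strata_table(rng, 40)
        small = table[(table["day"] == 1) | (table["subject_id"] == "s0")]
        with pytest.raises(ValueError, match="day=2"):
            stratified_patterns(small, predictors, by="day",
                                item_columns=self.ITEMS13)


class TestPatternSimilarity:
    def test_identical_and_negated(self, rng):
        v = rng.standard_normal(13)
        assert pattern_similarity(v, v)[0] == pytest.approx(1.0)
        assert pattern_similarity(v, -v)[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        a, b = rng.standard_normal((2, 13))
        r, p = pattern_similarity(a, b)
        am, bm = a - a.mean(), b - b.mean()
        r_manual = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
        assert r == pytest.approx(r_manual, abs=1e-12)
        t = r_manual * np.sqrt(11 / (1 - r_manual**2))
        p_manual = 2 * stats.t.sf(abs(t), 11)
        assert p == pytest.approx(p_manual, abs=1e-10)

    def test_constant_pattern_rejected(self):
        with pytest.raises(ValueError):
            pattern_similarity(np.ones(5), np.arange(5.0))
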