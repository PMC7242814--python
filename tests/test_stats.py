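"""Inferential layer: formula oracles, ANOVA sum-of-squares decomposition,
library cross-checks, and invariances."""

import numpy as np
import pandas as pd
import pytest

from dediff.stats import (
    StatsError,
    apply_factor_loadings,
    cohens_d,
    interaction_screen_regression,
    mixed_anova,
    partial_correlation,
    welch_t,
)


class TestWelch:
    def test_identical_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = welch_t(x, x.copy())
        assert res.statistic == 0.0 and res.p == 1.0

    def test_hand_formula_oracle(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([3.0, 4, 5, 6, 7])
        res = welch_t(x, y)
        # independent evaluation of Welch's formulas
        v1, v2, n = x.var(ddof=1), y.var(ddof=1), 5
        t = (x.mean() - y.mean()) / np.sqrt(v1 / n + v2 / n)
        df = (v1 / n + v2 / n) ** 2 / ((v1 / n) ** 2 / 4 + (v2 / n) ** 2 / 4)
        assert res.statistic == pytest.approx(t, abs=1e-10)
        assert res.df == pytest.approx(df, abs=1e-10)

    def test_scipy_cross_check(self, rng):
        from scipy import stats as sps

        x, y = rng.normal(size=15), rng.normal(size=22) + 0.3
        res = welch_t(x, y)
        ref = sps.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_satterthwaite_df_bounds(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=30) * 4
        res = welch_t(x, y)
        assert min(8, 30) - 1 <= res.df <= 8 + 30 - 2

    def test_small_sample_raises(self):
        with pytest.raises(StatsError):
            welch_t([1.0], [1.0, 2.0])


class TestCohensD:
    def test_unit_case(self):
        rng = np.random.default_rng(1)
        x = rng.normal(1.0, 1.0, 5000)
        y = rng.normal(0.0, 1.0, 5000)
        assert cohens_d(x, y) == pytest.approx(1.0, abs=0.06)

    def test_equal_means_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cohens_d(x, x[::-1]) == 0.0

    def test_brute_force_oracle(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=17)
        n1, n2 = len(x), len(y)
        s2 = (sum((v - x.mean()) ** 2 for v in x) + sum((v - y.mean()) ** 2 for v in y)) / (n1 + n2 - 2)
        assert cohens_d(x, y) == pytest.approx((x.mean() - y.mean()) / np.sqrt(s2), abs=1e-12)


def brute_force_split_plot(data, dv, between, within, subject):
    """Independent sum-of-squares oracle: explicit loops over dictionaries,
    one between factor x one within factor, balanced."""
    obs = {(r[subject], r[within]): r[dv] for _, r in data.iterrows()}
    grp = {r[subject]: r[between] for _, r in data.iterrows()}
    subjects = sorted(grp)
    wlev = sorted({w for _, w in obs})
    glev = sorted(set(grp.values()))
    grand = np.mean(list(obs.values()))
    k, n_s = len(wlev), len(subjects)

    def mean_subj(s):
        return np.mean([obs[(s, w)] for w in wlev])

    def mean_grp(g):
        return np.mean([obs[(s, w)] for s in subjects if grp[s] == g for w in wlev])

    def mean_w(w):
        return np.mean([obs[(s, w)] for s in subjects])

    def mean_gw(g, w):
        return np.mean([obs[(s, w)] for s in subjects if grp[s] == g])

    ss_a = k * sum(
        sum(1 for s in subjects if grp[s] == g) * (mean_grp(g) - grand) ** 2
        for g in glev
    )
    ss_sa = k * sum((mean_subj(s) - mean_grp(grp[s])) ** 2 for s in subjects)
    ss_w = n_s * sum((mean_w(w) - grand) ** 2 for w in wlev)
    ss_aw = sum(
        sum(1 for s in subjects if grp[s] == g)
        * (mean_gw(g, w) - mean_grp(g) - mean_w(w) + grand) ** 2
        for g in glev for w in wlev
    )
    ss_wsa = sum(
        (obs[(s, w)] - mean_subj(s) - mean_gw(grp[s], w) + mean_grp(grp[s])) ** 2
        for s in subjects for w in wlev
    )
    n_per = n_s // len(glev)
    return {
        between: (ss_a, len(glev) - 1, ss_sa, len(glev) * (n_per - 1)),
        within: (ss_w, k - 1, ss_wsa, len(glev) * (n_per - 1) * (k - 1)),
        f"{between} x {within}": (ss_aw, (len(glev) - 1) * (k - 1),
                                  ss_wsa, len(glev) * (n_per - 1) * (k - 1)),
    }


def _toy_mixed(rng, n_per_group=4, k=2, effects=True):
    rows = []
    for gi, g in enumerate(("g1", "g2")):
        for s in range(n_per_group):
            sid = f"{g}_s{s}"
            for w in range(k):
                val = rng.normal()
                if effects:
                    val += 0.8 * gi + 0.5 * w + 0.7 * gi * (w == 0)
                rows.append({"subject": sid, "group": g, "cond": f"w{w}", "dv": val})
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_matches_brute_force_oracle(self, rng):
        """F for every effect of a 2 x 2 toy design within 1e-8 of the
        explicit-loop sum-of-squares oracle."""
        df = _toy_mixed(rng, n_per_group=4, k=2)
        res = mixed_anova(df, "dv", "group", "cond", "subject").set_index("effect")
        oracle = brute_force_split_plot(df, "dv", "group", "cond", "subject")
        for eff, (ss, df1, ss_err, df2) in oracle.items():
            F = (ss / df1) / (ss_err / df2)
            assert res.loc[eff, "F"] == pytest.approx(F, abs=1e-8)
            assert res.loc[eff, "SS"] == pytest.approx(ss, abs=1e-8)

    def test_two_level_within_epsilon_is_one(self, rng):
        df = _toy_mixed(rng, k=2)
        res = mixed_anova(df, "dv", "group", "cond", "subject")
        assert (res.epsilon == 1.0).all()

    def test_location_invariance(self, rng):
        df = _toy_mixed(rng, n_per_group=5, k=3)
        res1 = mixed_anova(df, "dv", "group", "cond", "subject")
        df2 = df.assign(dv=df.dv + 100.0)
        res2 = mixed_anova(df2, "dv", "group", "cond", "subject")
        assert np.allclose(res1.F, res2.F)
        assert np.allclose(res1.p, res2.p)

    def test_pingouin_cross_check(self, rng):
        """F, SS, partial-eta2 match pingouin's mixed ANOVA; epsilon agrees
        to the tolerance expected between pooled and unpooled covariance
        conventions."""
        pg = pytest.importorskip("pingouin")
        df = _toy_mixed(rng, n_per_group=8, k=4)
        mine = mixed_anova(df, "dv", "group", "cond", "subject").set_index("effect")
        ref = pg.mixed_anova(data=df, dv="dv", within="cond", between="group",
                             subject="subject", correction=True, effsize="np2")
        pairs = {"group": "group", "cond": "cond", "group x cond": "Interaction"}
        for eff, src in pairs.items():
            row = ref[ref.Source == src].iloc[0]
            assert mine.loc[eff, "F"] == pytest.approx(row.F, abs=1e-8)
            assert mine.loc[eff, "SS"] == pytest.approx(row.SS, abs=1e-8)
            assert mine.loc[eff, "partial_eta_sq"] == pytest.approx(row.np2, abs=1e-8)
        eps_ref = float(ref.loc[ref.Source == "cond", "eps"].iloc[0])
        assert mine.loc["cond", "epsilon"] == pytest.approx(eps_ref, abs=0.1)

    def test_two_within_factors_against_r_style_decomposition(self, rng):
        """Total SS is fully partitioned in the 2 x 2 x 2 design and the
        within-stratum errors are orthogonal (checked via the residual
        identity)."""
        rows = []
        for g in ("g1", "g2"):
            for s in range(5):
                sid = f"{g}{s}"
                for w1 in ("f", "sc"):
                    for w2 in ("rem", "forg"):
                        rows.append({"subject": sid, "group": g, "cat": w1,
                                     "mem": w2, "dv": rng.normal()})
        df = pd.DataFrame(rows)
        res = mixed_anova(df, "dv", "group", ["cat", "mem"], "subject")
        ss_effects = res.SS.sum()
        ss_errors = res.drop_duplicates("SS_error").SS_error.sum()
        ss_total = ((df.dv - df.dv.mean()) ** 2).sum()
        assert ss_effects + ss_errors == pytest.approx(ss_total, rel=1e-10)
        assert len(res) == 7  # 3 mains + 3 two-way + 1 three-way

    def test_unbalanced_raises(self, rng):
        df = _toy_mixed(rng).iloc[:-1]
        with pytest.raises(StatsError, match="unbalanced"):
            mixed_anova(df, "dv", "group", "cond", "subject")


class TestPartialCorrelation:
    def test_orthogonal_covariate_equals_plain(self, rng):
        n = 64
        x = rng.normal(size=n)
        y = 0.5 * x + rng.normal(size=n)
        c = rng.normal(size=n)
        # project c off span{1, x, y}: partialling it out then changes nothing
        Z = np.column_stack([np.ones(n), x, y])
        c = c - Z @ np.linalg.lstsq(Z, c, rcond=None)[0]
        plain = partial_correlation(x, y).effect_size
        part = partial_correlation(x, y, c).effect_size
        assert part == pytest.approx(plain, abs=1e-10)

    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=20)
        assert partial_correlation(x, x.copy()).effect_size == pytest.approx(1.0)

    def test_residualize_then_correlate_oracle(self, rng):
        n = 40
        C = rng.normal(size=(n, 2))
        x = C @ [1.0, -0.5] + rng.normal(size=n)
        y = C @ [0.3, 0.8] + 0.4 * x + rng.normal(size=n)
        res = partial_correlation(x, y, C)
        Z = np.column_stack([np.ones(n), C])
        rx = x - Z @ np.linalg.solve(Z.T @ Z, Z.T @ x)
        ry = y - Z @ np.linalg.solve(Z.T @ Z, Z.T @ y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.effect_size == pytest.approx(oracle, abs=1e-10)

    def test_pingouin_cross_check(self, rng):
        pg = pytest.importorskip("pingouin")
        n = 30
        x, y, c = rng.normal(size=n), rng.normal(size=n), rng.normal(size=n)
        res = partial_correlation(x, y, c)
        ref = pg.partial_corr(data=pd.DataFrame({"x": x, "y": y, "c": c}),
                              x="x", y="y", covar="c")
        assert res.effect_size == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)

    def test_collinear_covariates_raise(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        c = rng.normal(size=20)
        with pytest.raises(StatsError, match="collinear"):
            partial_correlation(x, y, np.column_stack([c, 2 * c]))


class TestInteractionScreen:
    def test_strong_interaction_retained(self, rng):
        n = 40
        g = np.repeat(["a", "b"], n // 2)
        x = rng.normal(size=n)
        y = np.where(g == "b", 5.0 * x, -5.0 * x) + 0.2 * rng.normal(size=n)
        res = interaction_screen_regression(y, x, g)
        assert res.kept_model == "full"
        assert res.partial is None

    def test_null_interaction_type1_near_alpha(self):
        rng = np.random.default_rng(7)
        n = 24
        g = np.repeat(["a", "b"], n // 2)
        kept_full = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=n)
            y = x * 0.5 + rng.normal(size=n)
            if interaction_screen_regression(y, x, g).kept_model == "full":
                kept_full += 1
        rate = kept_full / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3.5 * se

    def test_reduced_model_partial_matches_partial_correlation(self, rng):
        n = 30
        g = np.repeat(["a", "b"], n // 2)
        x = rng.normal(size=n)
        y = 0.4 * x + (g == "b") * 0.5 + rng.normal(size=n)
        res = interaction_screen_regression(y, x, g, alpha=1e-9)
        expected = partial_correlation(x, y, (g == "b").astype(float))
        assert res.partial.effect_size == pytest.approx(expected.effect_size)
        assert res.partial.p == pytest.approx(expected.p)


class TestFactorLoadings:
    def test_identity_loadings_return_zscores(self, rng):
        scores = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        loadings = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("xyz"))
        out = apply_factor_loadings(scores, loadings)
        z = (scores - scores.mean()) / scores.std(ddof=1)
        assert np.allclose(out.to_numpy(), z.to_numpy())

    def test_zero_loadings_zero_factor(self, rng):
        scores = pd.DataFrame(rng.normal(size=(8, 2)), columns=list("ab"))
        loadings = pd.DataFrame({"f1": [0.0, 0.0]}, index=list("ab"))
        assert np.allclose(apply_factor_loadings(scores, loadings), 0.0)

    def test_matrix_product_oracle(self, rng):
        from dediff.io import NEUROPSYCH_LOADINGS

        scores = pd.DataFrame(
            rng.normal(size=(12, len(NEUROPSYCH_LOADINGS))),
            columns=NEUROPSYCH_LOADINGS.index,
        )
        out = apply_factor_loadings(scores, NEUROPSYCH_LOADINGS)
        X = scores.to_numpy()
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        oracle = Z @ NEUROPSYCH_LOADINGS.to_numpy()
        assert np.max(np.abs(out.to_numpy() - oracle)) <= 1e-12

    def test_zero_variance_column_raises(self):
        scores = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        loadings = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("xy"))
        with pytest.raises(StatsError, match="zero-variance"):
            apply_factor_loadings(scores, loadings)
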