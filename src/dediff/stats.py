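"""Inferential statistics: Welch t tests, Cohen's d, mixed-design ANOVA with
nonsphericity-corrected degrees of freedom and partial eta-squared, partial
correlations, interaction-screened regressions, and factor-score projection.

The mixed ANOVA supports balanced split-plot designs with one between-subject
factor and one or two within-subject factors.  Within-subject effects are
corrected with the Greenhouse-Geisser epsilon (Huynh-Feldt available as an
option); sphericity cannot be violated with two-level factors, where epsilon
is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class StatTestResult:
    statistic: float
    df: float
    p: float
    effect_size: float | None = None

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "effect_size": self.effect_size,
        }


def welch_t(x, y) -> StatTestResult:
    """Welch's unequal-variance t test with Satterthwaite df (two-sided).

    Effect size is Cohen's d (pooled SD, first sample minus second).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("welch_t requires n >= 2 per sample")
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatTestResult(float(t), float(df), float(p), cohens_d(x, y))


def cohens_d(x, y) -> float:
    """Standardized mean difference: (mean(x) - mean(y)) / pooled SD."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("cohens_d requires n >= 2 per sample")
    n1, n2 = len(x), len(y)
    pooled = np.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2))
    if pooled == 0:
        raise StatsError("zero pooled SD")
    return float((x.mean() - y.mean()) / pooled)


def _check_balanced(data: pd.DataFrame, between: str, within: list[str], subject: str) -> None:
    cells = data.groupby([subject] + within, observed=True).size()
    k_total = int(np.prod([data[w].nunique() for w in within]))
    per_subject = data.groupby(subject, observed=True).size()
    if (cells != 1).any() or (per_subject != k_total).any():
        bad = sorted(
            {idx[0] for idx in cells[cells != 1].index}
            | set(per_subject[per_subject != k_total].index)
        )
        raise StatsError(f"unbalanced design: subjects {bad} lack exactly one "
                         "observation per within-cell")
    groups = data.groupby(subject, observed=True)[between].nunique()
    if (groups != 1).any():
        raise StatsError("each subject must belong to exactly one group")
    n_per = data.drop_duplicates(subject).groupby(between, observed=True).size()
    if n_per.nunique() != 1:
        raise StatsError(f"unequal group sizes: {dict(n_per)}")


def _gg_epsilon(cell_matrix: np.ndarray, groups: np.ndarray, contrast: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance of
    within-subject cell scores, under the orthonormal ``contrast``."""
    k = cell_matrix.shape[1]
    dfn = contrast.shape[0]
    if k == 2:
        return 1.0
    S = np.zeros((k, k))
    dof = 0
    for g in np.unique(groups):
        sub = cell_matrix[groups == g]
        if len(sub) > 1:
            S += np.cov(sub, rowvar=False) * (len(sub) - 1)
            dof += len(sub) - 1
    S /= dof
    E = contrast @ S @ contrast.T
    return float(np.trace(E) ** 2 / (dfn * np.trace(E @ E)))


def _hf_epsilon(eps_gg: float, n_subjects: int, n_groups: int, dfn: int) -> float:
    num = (n_subjects - n_groups + 1) * dfn * eps_gg - 2
    den = dfn * (n_subjects - n_groups - dfn * eps_gg)
    return float(min(1.0, num / den)) if den > 0 else 1.0


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    between: str,
    within,
    subject: str,
    epsilon_method: str = "gg",
) -> pd.DataFrame:
    """Balanced mixed-design (split-plot) ANOVA.

    Returns one row per effect with columns ``SS``, ``df1``, ``df2``,
    ``epsilon``, ``df1_corr``, ``df2_corr``, ``F``, ``p``, ``partial_eta_sq``.
    Nonsphericity correction (``epsilon_method`` = ``"gg"`` or ``"hf"``) is
    applied to within-subject effects; between-subject effects carry
    epsilon = 1.
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 2:
        raise StatsError("mixed_anova supports one or two within factors")
    if epsilon_method not in ("gg", "hf"):
        raise StatsError("epsilon_method must be 'gg' or 'hf'")
    cols = [subject, between, dv] + within
    data = data[cols].copy()
    _check_balanced(data, between, within, subject)

    def m(*factors) -> pd.Series:
        """Cell means over the listed factors."""
        if not factors:
            return data[dv].mean()
        return data.groupby(list(factors), observed=True)[dv].mean()

    subj_group = data.drop_duplicates(subject).set_index(subject)[between]
    a = data[between].nunique()
    n = len(subj_group) // a
    levels = {w: data[w].nunique() for w in within}
    b = levels[within[0]]
    c = levels[within[1]] if len(within) == 2 else 1
    N = len(data)
    grand = float(m())

    A, S = between, subject
    B = within[0]
    ya = m(A)
    ys = m(S)
    ysA = subj_group.map(ya)  # group mean of each subject's group

    effects: list[dict] = []

    def add(name, ss, df1, error_name=None):
        effects.append({"effect": name, "SS": float(ss), "df1": int(df1), "error": error_name})

    # between stratum
    ss_A = n * (N // (a * n)) * ((ya - grand) ** 2).sum()
    ss_SA = (N // len(ys)) * ((ys - ysA) ** 2).sum()
    add(A, ss_A, a - 1, "S(A)")
    strata = {"S(A)": (float(ss_SA), a * (n - 1))}

    def interaction_ss(factors: list[str], mult: float) -> float:
        """Inclusion-exclusion SS for a crossed effect of the given factors."""
        cells = data.groupby(factors, observed=True)[dv].mean().reset_index()
        val = cells[dv].to_numpy(copy=True).astype(float)
        from itertools import combinations

        for r in range(len(factors)):
            for sub in combinations(factors, r):
                sign = (-1) ** (len(factors) - r)
                if not sub:
                    val += sign * grand
                else:
                    sub_means = data.groupby(list(sub), observed=True)[dv].mean()
                    if len(sub) == 1:
                        val += sign * cells[sub[0]].map(sub_means).to_numpy()
                    else:
                        key = pd.MultiIndex.from_frame(cells[list(sub)])
                        val += sign * sub_means.reindex(key).to_numpy()
        return float(mult * (val**2).sum())

    # per-within-factor strata
    for w in within:
        k = levels[w]
        other = [x for x in within if x != w]
        mult_w = N / k
        ss_w = interaction_ss([w], mult_w)
        ss_aw = interaction_ss([A, w], N / (a * k))
        # error: w x subject(A)
        ysw = data.groupby([S, w], observed=True)[dv].mean().reset_index()
        gw_key = pd.MultiIndex.from_arrays([ysw[S].map(subj_group), ysw[w]])
        ysw["fit"] = (
            ysw[S].map(ys).to_numpy()
            + m(A, w).reindex(gw_key).to_numpy()
            - ysw[S].map(subj_group).map(ya).to_numpy()
        )
        mult_e = N / (len(subj_group) * k)
        ss_wsa = mult_e * ((ysw[dv] - ysw["fit"]) ** 2).sum()
        err_name = f"{w} x S(A)"
        add(w, ss_w, k - 1, err_name)
        add(f"{A} x {w}", ss_aw, (a - 1) * (k - 1), err_name)
        strata[err_name] = (float(ss_wsa), a * (n - 1) * (k - 1))

    if len(within) == 2:
        w1, w2 = within
        ss_bc = interaction_ss([w1, w2], N / (b * c))
        ss_abc = interaction_ss([A, w1, w2], N / (a * b * c))
        # residual stratum: BC x S(A)
        ss_total = float(((data[dv] - grand) ** 2).sum())
        accounted = (
            ss_A
            + ss_SA
            + sum(e["SS"] for e in effects if e["effect"] not in (A,))
            + sum(v[0] for kname, v in strata.items() if kname != "S(A)")
            + ss_bc
            + ss_abc
        )
        ss_bcsa = ss_total - accounted
        err_name = f"{w1} x {w2} x S(A)"
        add(f"{w1} x {w2}", ss_bc, (b - 1) * (c - 1), err_name)
        add(f"{A} x {w1} x {w2}", ss_abc, (a - 1) * (b - 1) * (c - 1), err_name)
        strata[err_name] = (max(ss_bcsa, 0.0), a * (n - 1) * (b - 1) * (c - 1))

    # epsilons per within stratum
    eps: dict[str, float] = {"S(A)": 1.0}
    groups_arr = subj_group.to_numpy()
    subj_order = subj_group.index
    for w in within:
        pivot = data.pivot_table(index=S, columns=w, values=dv, observed=True).loc[subj_order]
        e = _gg_epsilon(pivot.to_numpy(), groups_arr, helmert(levels[w], full=False))
        if epsilon_method == "hf":
            e = _hf_epsilon(e, len(subj_group), a, levels[w] - 1)
        eps[f"{w} x S(A)"] = e
    if len(within) == 2:
        w1, w2 = within
        pivot = data.pivot_table(index=S, columns=[w1, w2], values=dv, observed=True).loc[subj_order]
        contrast = np.kron(helmert(b, full=False), helmert(c, full=False))
        e = _gg_epsilon(pivot.to_numpy(), groups_arr, contrast)
        if epsilon_method == "hf":
            e = _hf_epsilon(e, len(subj_group), a, (b - 1) * (c - 1))
        eps[f"{w1} x {w2} x S(A)"] = e

    rows = []
    for e in effects:
        ss_err, df_err = strata[e["error"]]
        epsilon = eps[e["error"]]
        df1c, df2c = epsilon * e["df1"], epsilon * df_err
        ms_eff = e["SS"] / e["df1"]
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else np.inf
        rows.append(
            {
                "effect": e["effect"],
                "SS": e["SS"],
                "SS_error": ss_err,
                "df1": e["df1"],
                "df2": df_err,
                "epsilon": epsilon,
                "df1_corr": df1c,
                "df2_corr": df2c,
                "F": float(F),
                "p": float(sps.f.sf(F, df1c, df2c)),
                "partial_eta_sq": e["SS"] / (e["SS"] + ss_err) if e["SS"] + ss_err > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def partial_correlation(x, y, covariates=None) -> StatTestResult:
    """Correlation of x and y after projecting out covariates (+ intercept).

    With an empty covariate set this reduces to the plain Pearson
    correlation.  p is two-sided from a t distribution with
    df = n - 2 - n_covariates; the effect size field carries r itself.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.column_stack([np.ones(n), C])
        k = C.shape[1]
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise StatsError("collinear covariates")
    if n <= k + 2:
        raise StatsError(f"need n > {k + 2} observations for {k} covariates")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - k
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(df / (1 - r_clip**2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatTestResult(float(t), float(df), float(p), r)


@dataclass(frozen=True)
class RegressionScreenResult:
    kept_model: str  # 'full' (interaction retained) or 'reduced'
    interaction_p: float
    coefficients: dict
    partial: StatTestResult | None  # predictor partial r controlling group (reduced only)


def interaction_screen_regression(
    y, predictor, group, alpha: float = 0.05
) -> RegressionScreenResult:
    """Regression of y on predictor + group, screening the interaction term.

    Fits ``y ~ predictor + group + predictor:group``; when the interaction
    does not reach ``alpha`` the model is refit without it and the
    predictor's partial correlation controlling for group is reported.
    """
    import statsmodels.api as sm

    y = np.asarray(y, float)
    x = np.asarray(predictor, float)
    g = np.asarray(group)
    if len(y) < 8:
        raise StatsError("need n >= 8 for the interaction screen")
    glev = np.unique(g)
    if len(glev) != 2:
        raise StatsError("group must be binary")
    gnum = (g == glev[1]).astype(float)

    X_full = sm.add_constant(np.column_stack([x, gnum, x * gnum]))
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise StatsError("degenerate design (collinear predictor/group)")
    full = sm.OLS(y, X_full).fit()
    p_int = float(full.pvalues[3])
    if p_int < alpha:
        coefs = dict(zip(["intercept", "predictor", "group", "interaction"], full.params))
        return RegressionScreenResult("full", p_int, coefs, None)
    reduced = sm.OLS(y, sm.add_constant(np.column_stack([x, gnum]))).fit()
    coefs = dict(zip(["intercept", "predictor", "group"], reduced.params))
    partial = partial_correlation(x, y, gnum)
    return RegressionScreenResult("reduced", p_int, coefs, partial)


def apply_factor_loadings(scores: pd.DataFrame, loadings: pd.DataFrame) -> pd.DataFrame:
    """Project standardized test scores onto rotated component loadings.

    ``scores`` has one row per participant and one column per test;
    ``loadings`` has one row per test (matching score columns) and one column
    per component.  Each test column is z-scored across the sample (mean 0,
    SD 1, n-1 denominator) and matrix-multiplied by the loadings.
    """
    missing = [t for t in loadings.index if t not in scores.columns]
    if missing:
        raise StatsError(f"score table lacks test columns: {missing}")
    X = scores[list(loadings.index)].to_numpy(float)
    if len(X) < 2:
        raise StatsError("need at least 2 participants to standardize")
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise StatsError(
            f"zero-variance test column(s): {[loadings.index[i] for i in zero]}"
        )
    Z = (X - X.mean(axis=0)) / sd
    out = Z @ loadings.to_numpy(float)
    return pd.DataFrame(out, index=scores.index, columns=loadings.columns)
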