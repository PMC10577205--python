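"""Group-level statistics: rank tests, mixed logistic error models, Spearman
correlations, and the ERP-biomarker regression models.

Conventions follow the study design this package reproduces: two groups
(burnout / non-burnout), Kruskal–Wallis rank-sum tests for skewed continuous
outcomes (df = k - 1 = 1 for two groups), per-trial error probabilities
modelled with a logistic regression carrying a per-subject random intercept,
and ordinary least squares for the questionnaire-score ~ ERP-parameter
models.  No multiple-testing correction is applied; all p-values are nominal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

# ---------------------------------------------------------------------------
# Rank tests


@dataclass
class ChiSqResult:
    statistic: float
    df: int
    p_value: float
    medians: dict
    iqrs: dict
    degenerate: bool = False


def _median_iqr(x: np.ndarray) -> tuple[float, float]:
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return float(q50), float(q75 - q25)


def kruskal_wallis(values_a, values_b, labels: tuple[str, str] = ("a", "b")) -> ChiSqResult:
    """Two-group Kruskal–Wallis rank-sum test (midranks, tie correction).

    Degenerate inputs (all values identical across both groups) return
    statistic 0 and p 1 with a flag rather than an error.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    med_a, iqr_a = _median_iqr(a)
    med_b, iqr_b = _median_iqr(b)
    meds = {labels[0]: med_a, labels[1]: med_b}
    iqrs = {labels[0]: iqr_a, labels[1]: iqr_b}
    if np.all(np.concatenate([a, b]) == a[0]):
        return ChiSqResult(0.0, 1, 1.0, meds, iqrs, degenerate=True)
    h, p = stats.kruskal(a, b)
    return ChiSqResult(float(h), 1, float(p), meds, iqrs)


# ---------------------------------------------------------------------------
# Spearman


@dataclass
class RhoResult:
    rho: float
    p_value: float
    n: int
    degenerate: bool = False


def spearman(x, y, exact: bool = False) -> RhoResult:
    """Spearman rank correlation (midranks; p via the t approximation).

    ``exact=True`` computes the permutation p-value by full enumeration and
    is only accepted for n <= 10.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    n = int(x.size)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return RhoResult(np.nan, np.nan, n, degenerate=True)
    rho, p = stats.spearmanr(x, y)
    if exact:
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        from itertools import permutations
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        obs = abs(rho)
        perms = np.array(list(permutations(ry)))
        rhos = np.array([stats.pearsonr(rx, pr)[0] for pr in perms])
        p = float(np.mean(np.abs(rhos) >= obs - 1e-12))
    return RhoResult(float(rho), float(p), n)


# ---------------------------------------------------------------------------
# Mixed-effects logistic regression (random intercept per subject)


@dataclass
class MixedLogitResult:
    """Fitted random-intercept logistic model.

    Fixed effects are reported as odds ratios with Wald 95% CIs on the
    log-odds scale; ``re_sd`` is the estimated random-intercept SD.
    """

    terms: list[str]
    coef: np.ndarray               # log-odds scale, incl. intercept
    se: np.ndarray
    re_sd: float
    loglik: float
    n_obs: int
    n_groups: int
    separation: bool = False

    def odds_ratios(self) -> pd.DataFrame:
        z = 1.959963984540054
        rows = []
        for name, b, s in zip(self.terms, self.coef, self.se):
            if name == "(Intercept)":
                continue
            unbounded = self.separation or not np.isfinite(s)
            rows.append({
                "term": name,
                "odds_ratio": math.exp(b),
                "ci_low": 0.0 if unbounded else math.exp(b - z * s),
                "ci_high": math.inf if unbounded else math.exp(b + z * s),
                "unbounded_ci": unbounded,
            })
        return pd.DataFrame(rows)


def _gh_nodes(k: int = 41) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(k)
    return x, w / math.sqrt(math.pi)


def _make_mixed_logit_objective(X: np.ndarray, y: np.ndarray,
                                group_idx: np.ndarray,
                                nodes: tuple[np.ndarray, np.ndarray]):
    """Closure returning (nll, grad) of the Gauss–Hermite-approximated
    marginal log-likelihood for a random-intercept logistic model.

    Observations are pre-sorted by group so per-group sums reduce to
    ``np.add.reduceat`` over contiguous slices.
    """
    order = np.argsort(group_idx, kind="stable")
    Xs, ys, gs = X[order], y[order].astype(float), group_idx[order]
    bounds = np.flatnonzero(np.r_[True, np.diff(gs) != 0])
    xk, wk = nodes

    def objective(params: np.ndarray) -> tuple[float, np.ndarray]:
        beta, log_sd = params[:-1], params[-1]
        sd = math.exp(log_sd)
        b = math.sqrt(2.0) * sd * xk                       # (K,)
        lin = (Xs @ beta)[:, None] + b[None, :]            # (n_obs, K)
        ll_obs = np.where(ys[:, None] == 1.0, -np.logaddexp(0.0, -lin),
                          -np.logaddexp(0.0, lin))
        resid = ys[:, None] - 1.0 / (1.0 + np.exp(-lin))   # y - p, (n_obs, K)
        ll_grp = np.add.reduceat(ll_obs, bounds, axis=0)   # (n_groups, K)
        m = ll_grp.max(axis=1, keepdims=True)
        fk = np.exp(ll_grp - m)                            # scaled likelihoods
        lik = fk @ wk
        nll = -float(np.sum(m.ravel() + np.log(lik)))
        # posterior node weights per group
        post = fk * wk / lik[:, None]                      # (n_groups, K)
        # d ll_grp / d beta_j = sum_{obs in grp} x_j * resid
        grad_beta = np.empty(beta.size)
        for j in range(beta.size):
            s = np.add.reduceat(Xs[:, j][:, None] * resid, bounds, axis=0)
            grad_beta[j] = -float(np.sum(post * s))
        # d lin / d log_sd = b_k
        s_sd = np.add.reduceat(resid, bounds, axis=0) * b[None, :]
        grad = np.append(grad_beta, -float(np.sum(post * s_sd)))
        return nll, grad

    return objective


def fit_mixed_logit(df: pd.DataFrame, response: str, fixed: list[str],
                    group: str = "subject", n_quad: int = 41) -> MixedLogitResult:
    """Fit a logistic regression with a per-subject random intercept by
    maximising the Gauss–Hermite-approximated marginal likelihood.

    ``fixed`` columns may be binary/boolean or two-level categorical; each is
    coded 0/1 against its first sorted level.  Complete separation (an
    all-0/all-1 outcome overall or within a predictor level) is flagged and
    the affected CIs reported as unbounded.
    """
    y = df[response].to_numpy()
    if y.dtype != np.dtype(bool) and not np.isin(y, [0, 1]).all():
        raise ValueError("response must be binary")
    y = y.astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("outcome constant: model is completely separated")

    cols = [np.ones(len(df))]
    terms = ["(Intercept)"]
    separation = False
    for f in fixed:
        v = df[f]
        levels = sorted(v.unique())
        if len(levels) != 2:
            raise ValueError(f"fixed effect {f!r} must have exactly two levels")
        x = (v == levels[1]).to_numpy().astype(float)
        for lev_mask in (x == 0, x == 1):
            ymask = y[lev_mask]
            if ymask.size and (ymask.sum() == 0 or ymask.sum() == ymask.size):
                separation = True
        cols.append(x)
        terms.append(f"{f}[{levels[1]}]")
    X = np.column_stack(cols)

    groups, group_idx = np.unique(df[group].to_numpy(), return_inverse=True)
    nodes = _gh_nodes(n_quad)
    p = X.shape[1]

    objective = _make_mixed_logit_objective(X, y, group_idx, nodes)
    x0 = np.zeros(p + 1)
    x0[0] = math.log(max(y.mean(), 1e-6) / max(1 - y.mean(), 1e-6))
    x0[-1] = math.log(0.3)
    res = optimize.minimize(objective, x0, jac=True, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 500})
    # observed-information SEs: central differences of the analytic gradient
    hess = _numeric_hessian_from_grad(lambda q: objective(q)[1], res.x)
    se = np.full(p, np.inf)
    try:
        cov = np.linalg.inv(hess)
        d = np.diag(cov)[:p]
        se = np.where(d > 0, np.sqrt(np.maximum(d, 0.0)), np.inf)
    except np.linalg.LinAlgError:
        separation = True
    return MixedLogitResult(terms=terms, coef=res.x[:p], se=se,
                            re_sd=math.exp(res.x[-1]), loglik=-res.fun,
                            n_obs=len(df), n_groups=len(groups),
                            separation=separation)


def _numeric_hessian_from_grad(grad, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n); e[i] = h
        H[:, i] = (grad(x + e) - grad(x - e)) / (2 * h)
    return 0.5 * (H + H.T)


ERROR_TYPES = ("total", "incorrect", "miss", "commission")


def error_response_frame(outcomes: pd.DataFrame, error_type: str) -> pd.DataFrame:
    """Per-trial binary response for one error type, on its dichotomisation
    domain (commission: NoGo trials only; incorrect/miss: Go trials only;
    total: all trials)."""
    df = outcomes[~outcomes["is_practice"]].copy() if "is_practice" in outcomes \
        else outcomes.copy()
    if error_type == "total":
        df["y"] = (df["class_total"] == "error").astype(int)
    elif error_type == "incorrect":
        df = df[df["condition"] == "Go"]
        df["y"] = (df["class_incorrect"] == "incorrect").astype(int)
    elif error_type == "miss":
        df = df[df["condition"] == "Go"]
        df["y"] = (df["class_miss"] == "miss").astype(int)
    elif error_type == "commission":
        df = df[df["condition"] == "NoGo"]
        df["y"] = (df["class_commission"] == "commission_error").astype(int)
    else:
        raise ValueError(f"unknown error type {error_type!r}")
    return df


def fit_error_model(outcomes: pd.DataFrame, error_type: str) -> MixedLogitResult:
    """Mixed logistic model for one error type: fixed effects group,
    stimulator status, and emotional valence; random intercept per subject."""
    df = error_response_frame(outcomes, error_type)
    return fit_mixed_logit(df, "y", ["group", "stimulator", "distractor"],
                           group="subject")


# ---------------------------------------------------------------------------
# Biomarker regression


@dataclass
class RegressionSummary:
    response: str
    predictors: list[str]
    coefficients: dict
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    r_squared: float
    adj_r_squared: float
    n: int


def fit_biomarker_model(predictors: pd.DataFrame, response: pd.Series,
                        response_name: str) -> RegressionSummary:
    """OLS of a questionnaire score on ERP parameters (complete cases only)."""
    import statsmodels.api as sm

    df = predictors.copy()
    df["_y"] = np.asarray(response, float)
    df = df.dropna()
    y = df.pop("_y")
    n, p = df.shape
    if n <= p + 1:
        raise ValueError("too few complete cases for the predictor count")
    X = sm.add_constant(df)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear predictors: rank-deficient fit refused")
    fit = sm.OLS(y, X).fit()
    return RegressionSummary(
        response=response_name, predictors=list(df.columns),
        coefficients=dict(fit.params),
        f_statistic=float(fit.fvalue), df1=int(fit.df_model),
        df2=int(fit.df_resid), p_value=float(fit.f_pvalue),
        r_squared=float(fit.rsquared), adj_r_squared=float(fit.rsquared_adj),
        n=n,
    )


# ---------------------------------------------------------------------------
# Full analysis


QUESTIONNAIRES = ("bbi15", "bdi21", "brief_bri", "brief_mi", "brief_gec")
ERP_HEADLINE = (
    # (condition, pool, column, label)
    ("NoGo", "frontal", "n2_amplitude_uv", "frontal N2 NoGo amplitude"),
    ("Go", "frontal", "n2_amplitude_uv", "frontal N2 Go amplitude"),
    ("Go", "centroparietal", "p3_amplitude_uv", "CP P3 Go amplitude"),
    ("NoGo", "centroparietal", "p3_amplitude_uv", "CP P3 NoGo amplitude"),
    ("Go", "centroparietal", "p3_latency_ms", "CP P3 Go latency"),
    ("Go", "centroparietal", "n2_p3_ipl_ms", "CP N2-P3 Go IPL"),
)


def _erp_wide(measurements: pd.DataFrame) -> pd.DataFrame:
    """Eligible Go/CP measurements in wide per-subject form."""
    m = measurements[measurements["eligible"]]
    go_cp = m[(m["condition"] == "Go") & (m["pool"] == "centroparietal")]
    return go_cp.set_index("subject")[
        ["p3_amplitude_uv", "p3_latency_ms", "n2_p3_ipl_ms"]]


def run_full_analysis(measurements: pd.DataFrame, profiles: pd.DataFrame,
                      outcomes: pd.DataFrame | None = None,
                      behavior: pd.DataFrame | None = None) -> dict:
    """Assemble the full report: questionnaire contrasts, behavioural error
    models, ERP group contrasts, the correlation matrix, and both biomarker
    regression pairs.

    Returns a nested dict of plain tables; missing ingredients (e.g. an
    absent group) produce a partial report with explicit gaps rather than an
    exception.
    """
    report: dict = {"flags": []}
    prof = profiles.set_index("subject_id")
    groups = sorted(prof["group"].unique())
    if len(groups) < 2:
        report["flags"].append(f"partial: only groups {groups} present")

    def by_group(series: pd.Series) -> dict:
        return {g: series[prof["group"] == g].dropna() for g in groups}

    # questionnaire group contrasts
    qrows = []
    for q in QUESTIONNAIRES:
        vals = by_group(prof[q])
        if len(groups) == 2 and all(len(v) >= 2 for v in vals.values()):
            r = kruskal_wallis(vals[groups[0]], vals[groups[1]], tuple(groups))
            qrows.append({"scale": q, "chi_sq": r.statistic, "p": r.p_value,
                          **{f"median_{g}": r.medians[g] for g in groups}})
        else:
            qrows.append({"scale": q, "chi_sq": np.nan, "p": np.nan})
    report["questionnaires"] = pd.DataFrame(qrows)

    # behavioural summaries and per-error-type mixed logistic models
    if behavior is not None:
        brows = []
        for col in ("median_rt_ms", "pct_total_errors", "pct_incorrect",
                    "pct_missing", "pct_commission"):
            vals = {g: behavior.set_index("subject_id")[col][prof["group"] == g].dropna()
                    for g in groups}
            if len(groups) == 2 and all(len(v) >= 2 for v in vals.values()):
                r = kruskal_wallis(vals[groups[0]], vals[groups[1]], tuple(groups))
                brows.append({"measure": col, "chi_sq": r.statistic, "p": r.p_value,
                              **{f"median_{g}": r.medians[g] for g in groups},
                              **{f"iqr_{g}": r.iqrs[g] for g in groups}})
        report["behavior"] = pd.DataFrame(brows)
    if outcomes is not None and len(groups) == 2:
        ors = {}
        for et in ERROR_TYPES:
            try:
                ors[et] = fit_error_model(outcomes, et).odds_ratios()
            except ValueError as e:
                ors[et] = str(e)
                report["flags"].append(f"error model {et}: {e}")
        report["error_models"] = ors

    # ERP contrasts (headline: frontal N2 NoGo, CP P3 Go, CP IPL Go)
    m = measurements[measurements["eligible"]]
    erows = []
    for cond, pool, col, label in ERP_HEADLINE:
        sub = m[(m["condition"] == cond) & (m["pool"] == pool)].set_index("subject")
        vals = {g: sub[col][prof["group"] == g].dropna() for g in groups}
        if len(groups) == 2 and all(len(v) >= 2 for v in vals.values()):
            r = kruskal_wallis(vals[groups[0]], vals[groups[1]], tuple(groups))
            erows.append({"measure": label, "chi_sq": r.statistic, "p": r.p_value,
                          **{f"median_{g}": r.medians[g] for g in groups},
                          **{f"iqr_{g}": r.iqrs[g] for g in groups}})
    report["erp_contrasts"] = pd.DataFrame(erows)

    # ERP x questionnaire correlation matrix and biomarker regressions
    wide = _erp_wide(measurements).join(prof[list(QUESTIONNAIRES)], how="inner")
    crows = []
    for q in QUESTIONNAIRES:
        row = {"scale": q}
        for col, label in (("p3_amplitude_uv", "amp"), ("p3_latency_ms", "lat"),
                           ("n2_p3_ipl_ms", "ipl")):
            sub = wide[[col, q]].dropna()
            if len(sub) >= 3:
                r = spearman(sub[col], sub[q])
                row[f"rho_{label}"], row[f"p_{label}"] = r.rho, r.p_value
        crows.append(row)
    report["correlations"] = pd.DataFrame(crows)

    report["regressions"] = {}
    for resp_col, resp_name in (("bbi15", "BBI-15"), ("brief_mi", "MI")):
        for preds, tag in ((["p3_amplitude_uv", "p3_latency_ms"], "amp_lat"),
                           (["p3_amplitude_uv", "n2_p3_ipl_ms"], "amp_ipl")):
            sub = wide[preds + [resp_col]].dropna()
            if len(sub) > len(preds) + 1:
                report["regressions"][f"{resp_name}~{tag}"] = fit_biomarker_model(
                    sub[preds], sub[resp_col], resp_name)
            else:
                report["flags"].append(f"regression {resp_name}~{tag}: too few cases")

    report["n_by_group"] = {g: int((prof["group"] == g).sum()) for g in groups}
    eligible_subjects = set(_erp_wide(measurements).index)
    report["n_erp_eligible"] = {
        g: int(sum(1 for s in eligible_subjects
                   if s in prof.index and prof.loc[s, "group"] == g))
        for g in groups}
    return report
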