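"""Mixed-model comparison and the NHST battery.

Quantitative route: each encoding model's regressor is entered as the
single fixed-effect predictor of the per-subject, per-condition median RT
(or inverse efficiency) in a linear mixed-effects model with random
intercepts for subject and for the subject x condition cell, fitted by
maximum likelihood so that AIC/BIC are comparable across fixed-effect
regressors. The fitted slope is tested with a Wald chi-square (the squared
z of the coefficient, df = 1).

Qualitative route: repeated-measures ANOVA with Greenhouse-Geisser
correction and partial eta squared, follow-up paired t-tests with
Benjamini-Hochberg FDR control and Cohen's d, and a JZS (Cauchy-prior)
Bayesian paired t-test for predicted-null contrasts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import integrate, stats
from statsmodels.regression.mixed_linear_model import MixedLM, VCSpec
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .encoding_models import RegressorTable

__all__ = [
    "FitResult",
    "compare_models",
    "condition_means",
    "fit_lme",
    "jzs_bayes_t",
    "pairwise_tests",
    "rm_anova",
    "wald_test",
]


@dataclass(frozen=True)
class FitResult:
    """One mixed-model fit of a parametric regressor to condition data."""

    model_id: str
    beta_hat: float
    intercept: float
    se: float
    loglik: float
    aic: float
    bic: float
    n_obs: int
    n_params: int
    converged: bool


def condition_means(
    summaries: pd.DataFrame, factor: str, dv: str = "median_rt"
) -> pd.DataFrame:
    """Average the 12-cell summaries over the other factor.

    Returns one row per subject x level of ``factor`` ('spatial' ->
    ``p_tgt``, 'value' -> ``value_config``) with columns subject,
    condition, and the dv (renamed ``response``).
    """
    col = {"spatial": "p_tgt", "value": "value_config"}[factor]
    if col not in summaries.columns:
        raise KeyError(f"summaries lack the {col!r} column")
    out = (
        summaries.groupby(["subject", col])[dv]
        .mean()
        .reset_index()
        .rename(columns={col: "condition", dv: "response"})
    )
    return out


def fit_lme(
    summaries: pd.DataFrame,
    regressor: RegressorTable,
    dv: str = "median_rt",
) -> FitResult:
    """Fit response = intercept + beta * regressor + u_subj + u_cell + e.

    ``summaries`` is the 12-cell summary table; the response is first
    averaged over the factor the regressor does not vary on, leaving one
    observation per subject x condition. Fitted by ML. Non-convergence is
    flagged on the result, never silently replaced.
    """
    data = condition_means(summaries, regressor.factor, dv=dv)
    missing = set(data["condition"]) - set(regressor.entries)
    if missing:
        raise ValueError(f"regressor lacks entries for conditions {sorted(map(str, missing))}")
    if data["response"].isna().any():
        raise ValueError("missing response cells; preprocess before fitting")
    data = data.copy()
    data["x"] = data["condition"].map(regressor.entries).astype(float)
    data = data.sort_values("subject", kind="stable")

    endog = data["response"].to_numpy(dtype=float)
    exog = np.column_stack([np.ones(len(data)), data["x"].to_numpy(dtype=float)])
    groups = data["subject"].to_numpy()
    # one variance component shared by all subject x condition cells
    conditions = sorted(data["condition"].unique(), key=str)
    cond_idx = data["condition"].map({c: i for i, c in enumerate(conditions)}).to_numpy()
    mats = []
    for g in pd.unique(groups):
        rows = np.flatnonzero(groups == g)
        dummies = np.zeros((len(rows), len(conditions)))
        dummies[np.arange(len(rows)), cond_idx[rows]] = 1.0
        mats.append(dummies)
    colnames = [f"cell[{c}]" for c in conditions]
    vcs = VCSpec(["cell"], [[colnames] * len(mats)], [mats])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = MixedLM(
            endog, exog, groups=groups, exog_re=np.ones((len(endog), 1)), exog_vc=vcs
        )
        try:
            res = model.fit(reml=False)
            converged = bool(res.converged)
        except Exception:
            res = model.fit(reml=False, method="powell", maxiter=2000)
            converged = bool(res.converged)

    # parameters: intercept + slope, subject variance, cell variance, residual
    k = 2 + 2 + 1
    llf = float(res.llf)
    n = int(len(data))
    return FitResult(
        model_id=regressor.model_id,
        beta_hat=float(np.asarray(res.params)[1]),
        intercept=float(np.asarray(res.params)[0]),
        se=float(np.asarray(res.bse)[1]),
        loglik=llf,
        aic=-2.0 * llf + 2.0 * k,
        bic=-2.0 * llf + k * math.log(n),
        n_obs=n,
        n_params=k,
        converged=converged,
    )


def compare_models(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fits by AIC (primary) and BIC; ties reported, never broken.

    All fits must be on the same response data (equal n_obs).
    """
    if not fits:
        raise ValueError("no fits to compare")
    if len({f.n_obs for f in fits}) > 1:
        raise ValueError("fits were made on different data (n_obs mismatch)")
    df = pd.DataFrame(
        [
            dict(model_id=f.model_id, aic=f.aic, bic=f.bic, beta_hat=f.beta_hat,
                 se=f.se, loglik=f.loglik, converged=f.converged)
            for f in fits
        ]
    ).sort_values(["aic", "model_id"], kind="stable").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    df["delta_bic"] = df["bic"] - df["bic"].min()
    df["rank"] = df["aic"].rank(method="min").astype(int)
    df["tied"] = df.duplicated("aic", keep=False)
    return df


def wald_test(fit: FitResult) -> dict:
    """Wald chi-square on the fitted slope: W = (beta/se)^2, df = 1."""
    if fit.se == 0 or not np.isfinite(fit.se):
        raise ValueError("standard error is zero or non-finite; Wald test undefined")
    w = (fit.beta_hat / fit.se) ** 2
    return dict(
        model_id=fit.model_id,
        statistic=float(w),
        df=1,
        p=float(stats.chi2.sf(w, df=1)),
    )


def _check_balanced(data: pd.DataFrame, subject: str, within: list[str]) -> None:
    counts = data.groupby([subject, *within]).size()
    if counts.nunique() > 1:
        raise ValueError("unbalanced within-subject cells")
    full = data.groupby(subject).size()
    expected = counts.iloc[0] * int(np.prod([data[w].nunique() for w in within]))
    if (full != expected).any():
        raise ValueError("incomplete within-subject design")


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str] | str,
    subject: str = "subject",
    between: str | None = None,
) -> pd.DataFrame:
    """Repeated-measures (or mixed) ANOVA with Greenhouse-Geisser dfs.

    Supports a one- or two-factor within design, or one within factor
    crossed with a between-subject group. Returns a tidy table with the
    corrected p (``p``), GG epsilon, corrected dfs and partial eta squared.
    """
    within = [within] if isinstance(within, str) else list(within)
    _check_balanced(data, subject, within)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        if between is None:
            raw = pg.rm_anova(
                data=data, dv=dv, within=within if len(within) > 1 else within[0],
                subject=subject, correction=True, detailed=len(within) > 1,
                effsize="np2",
            )
        else:
            if len(within) != 1:
                raise ValueError("mixed design supports a single within factor")
            raw = pg.mixed_anova(
                data=data, dv=dv, within=within[0], subject=subject,
                between=between, correction=True, effsize="np2",
            )
    raw = raw.rename(columns={"DF1": "ddof1", "DF2": "ddof2"})
    out = pd.DataFrame(
        {
            "effect": raw["Source"],
            "F": raw["F"],
            "eps": raw.get("eps", pd.Series(np.nan, index=raw.index)),
        }
    )
    eps = out["eps"].fillna(1.0)
    out["df1"] = raw["ddof1"] * eps
    out["df2"] = raw["ddof2"] * eps
    out["p"] = raw["p_GG_corr"].fillna(raw["p_unc"]) if "p_GG_corr" in raw else raw["p_unc"]
    out["p_unc"] = raw["p_unc"]
    out["np2"] = raw["np2"]
    return out.dropna(subset=["F"]).reset_index(drop=True)


def pairwise_tests(
    data: pd.DataFrame,
    contrasts: list[tuple[str, str]],
    dv: str = "response",
    condition: str = "condition",
    subject: str = "subject",
    q: float = 0.05,
) -> pd.DataFrame:
    """Paired t-tests over condition contrasts with BH-FDR control.

    Cohen's d is for paired data: mean difference / sd of differences.
    ``significant`` flags discoveries at FDR level ``q``.
    """
    wide = data.pivot_table(index=subject, columns=condition, values=dv)
    if len(wide) < 2:
        raise ValueError("paired tests need at least 2 subjects")
    rows = []
    for a, b in contrasts:
        diffs = (wide[a] - wide[b]).dropna()
        n = len(diffs)
        sd = diffs.std(ddof=1)
        if sd == 0:
            t, p, d = (0.0, 1.0, 0.0) if np.allclose(diffs, 0) else (np.inf, 0.0, np.inf)
        else:
            t, p = stats.ttest_rel(wide[a], wide[b], nan_policy="omit")
            d = diffs.mean() / sd
        rows.append(dict(contrast=f"{a} - {b}", mean_diff=float(diffs.mean()),
                         t=float(t), df=n - 1, p=float(p), d=float(d)))
    out = pd.DataFrame(rows)
    reject, p_adj, _, _ = multipletests(out["p"], alpha=q, method="fdr_bh")
    out["p_adj"] = p_adj
    out["significant"] = reject
    return out


def jzs_bayes_t(diffs: np.ndarray, r: float = math.sqrt(2) / 2) -> float:
    """JZS Bayes factor (BF10) for a paired/one-sample t-test.

    Cauchy(0, r) prior on the standardised effect size, evaluated by
    adaptive quadrature of the non-central-t marginal likelihood.
    BF10 < 1 favours the null.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    sd = diffs.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences; Bayes factor undefined")
    t = diffs.mean() / (sd / math.sqrt(n))
    return jzs_bayes_t_stat(t, n, r=r)


def jzs_bayes_t_stat(t: float, n: int, r: float = math.sqrt(2) / 2) -> float:
    """BF10 from a t statistic and sample size (one-sample df = n - 1)."""
    nu = n - 1

    def integrand(delta: float) -> float:
        return stats.nct.pdf(t, nu, delta * math.sqrt(n)) * stats.cauchy.pdf(delta, 0.0, r)

    m1, _ = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    m0 = stats.t.pdf(t, nu)
    return float(m1 / m0)
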