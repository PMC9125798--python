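"""Age-trend inference: candidate mixed models with AICc, and correlations.

Per-cycle responses (peak T in ng/g, or cycle period in cm) are modelled
against the age at which each cycle occurred with whale as grouping factor.
Three Gaussian candidates are fit by maximum likelihood —

    null:                   response ~ 1   + (1 | whale)
    random intercept:       response ~ age + (1 | whale)
    random intercept+slope: response ~ age + (1 + age | whale), unstructured

— ranked by AICc with k counting fixed effects plus all variance/covariance
parameters plus the residual variance, and the winner refit by REML for the
reported estimates.  Fixed-effect t statistics use the nested-observation
denominator df = N - G - q, where q is the number of fixed covariates that
vary within whales (the convention of the standard nested-grouping software,
giving df = 126 - 9 - 1 = 116 at this study's data shape).  Cross-whale
plate summaries are related to terminal age by two-tailed Pearson tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "LMMResult",
    "ModelSelection",
    "CorrelationResult",
    "ConvergenceError",
    "VARIANTS",
    "denominator_df",
    "aicc",
    "fit_lmm",
    "select_model",
    "pearson_corr_test",
]

VARIANTS = ("null", "random_intercept", "random_intercept_slope")

#: boundary-variance flag threshold, as a fraction of the residual variance
_BOUNDARY_FRAC = 1e-6


class ConvergenceError(RuntimeError):
    """The mixed-model optimizer failed to converge."""


@dataclass(frozen=True)
class LMMResult:
    variant: str
    estimation: str  # "ML" | "REML"
    loglik: float
    aicc: float
    k_params: int
    n_obs: int
    n_groups: int
    fixed_effects: pd.DataFrame  # index term; estimate, se, t, df, p
    variance_components: dict
    per_whale: pd.DataFrame  # index whale_id; intercept, slope
    boundary_variance: bool
    converged: bool


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float
    r_squared: float
    p_two_tailed: float
    significant: bool  # at alpha = 0.05


def denominator_df(n_obs: int, n_groups: int, n_within_covariates: int) -> int:
    """Within-group denominator df: N - G - q."""
    df = n_obs - n_groups - n_within_covariates
    if df <= 0:
        raise ValueError("non-positive denominator df")
    return int(df)


def aicc(loglik: float, k_params: int, n_obs: int) -> float:
    """AICc = -2 logLik + 2k + 2k(k+1)/(n-k-1)."""
    if n_obs <= k_params + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    k = k_params
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n_obs - k - 1)


def _n_within_covariates(df: pd.DataFrame, has_age: bool) -> int:
    if not has_age:
        return 0
    varies = df.groupby("whale_id")["age"].nunique() > 1
    return int(varies.any())


def fit_lmm(
    observations: pd.DataFrame,
    variant: str,
    estimation: str = "ML",
    response: str = "response",
) -> LMMResult:
    """Fit one candidate model.

    ``observations`` needs columns whale_id, age, and the response.  Raises
    :class:`ConvergenceError` if no optimizer converges; a random-effect
    variance estimated at (numerically) zero sets ``boundary_variance``
    rather than raising.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    if estimation not in ("ML", "REML"):
        raise ValueError("estimation must be 'ML' or 'REML'")
    df = observations.sort_values(["whale_id", "age"]).reset_index(drop=True)
    groups = df["whale_id"].to_numpy()
    n_obs = len(df)
    n_groups = df["whale_id"].nunique()
    if n_groups < 2:
        raise ValueError("need at least 2 whales")
    y = df[response].to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)

    has_age = variant != "null"
    # the age covariate is standardized internally for optimizer
    # conditioning (ages span two orders of magnitude); every reported
    # quantity is transformed back to the natural scale, and the REML
    # log-likelihood is corrected by -log(sd) so it refers to the natural
    # parametrization (the ML log-likelihood is invariant)
    mu = float(age.mean())
    sd = float(age.std())
    standardize = has_age and sd > 0
    z = (age - mu) / sd if standardize else age
    exog = np.column_stack([np.ones(n_obs), z]) if has_age else np.ones((n_obs, 1))
    names = ["intercept", "age"] if has_age else ["intercept"]
    exog_re = exog if variant == "random_intercept_slope" else np.ones((n_obs, 1))

    model = MixedLM(y, exog, groups=groups, exog_re=exog_re)
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in (["lbfgs"], ["bfgs"], ["powell", "cg"], ["nm"]):
            try:
                cand = model.fit(
                    reml=(estimation == "REML"), method=method, maxiter=2000
                )
                # a fit whose fixed-effect covariance is singular (NaN SEs,
                # possibly only after back-transformation) is degenerate even
                # if the optimizer reports convergence
                if standardize:
                    T_chk = np.array([[1.0, -mu / sd], [0.0, 1.0 / sd]])
                    cov_chk = np.asarray(cand.cov_params(), dtype=float)[:2, :2]
                    with np.errstate(invalid="ignore"):
                        se_chk = np.sqrt(np.diag(T_chk @ cov_chk @ T_chk.T))
                else:
                    se_chk = np.asarray(cand.bse_fe, dtype=float)
                usable = (
                    cand.converged
                    and np.isfinite(cand.llf)
                    and np.all(np.isfinite(se_chk))
                )
            except Exception:
                continue
            if usable:
                result = cand
                break
    if result is None:
        raise ConvergenceError(
            f"{variant} ({estimation}) failed to converge on {n_obs} observations"
        )

    n_re_params = 1 if variant != "random_intercept_slope" else 3
    k = len(names) + n_re_params + 1
    q = _n_within_covariates(df, has_age)
    dof = denominator_df(n_obs, n_groups, q)

    est_z = np.asarray(result.fe_params, dtype=float)
    if standardize:
        # (intercept, slope)_natural = T (intercept, slope)_z
        T = np.array([[1.0, -mu / sd], [0.0, 1.0 / sd]])
        est = T @ est_z
        cov_fe = np.asarray(result.cov_params(), dtype=float)[:2, :2]
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(T @ cov_fe @ T.T))
    else:
        est = est_z
        se = np.asarray(result.bse_fe, dtype=float)
    tval = est / se
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    fixed = pd.DataFrame(
        {"estimate": est, "se": se, "t": tval, "df": dof, "p": pval}, index=names
    )

    resid_var = float(result.scale)
    cov_re = np.atleast_2d(np.asarray(result.cov_re, dtype=float))
    vc = {"residual_var": resid_var, "intercept_var": float(cov_re[0, 0])}
    if variant == "random_intercept_slope":
        v0, v1, c01 = float(cov_re[0, 0]), float(cov_re[1, 1]), float(cov_re[0, 1])
        if standardize:
            # u_int_nat = u0 - (mu/sd) u1 ; u_slope_nat = u1 / sd
            vc["intercept_var"] = v0 + (mu / sd) ** 2 * v1 - 2 * (mu / sd) * c01
            vc["slope_var"] = v1 / sd**2
            vc["intercept_slope_cov"] = c01 / sd - mu * v1 / sd**2
        else:
            vc["slope_var"] = v1
            vc["intercept_slope_cov"] = c01
    boundary = any(
        v < _BOUNDARY_FRAC * resid_var
        for k_, v in vc.items()
        if k_.endswith("_var") and k_ != "residual_var"
    )

    rows = {}
    re = result.random_effects
    for wid in sorted(df["whale_id"].unique()):
        u = np.asarray(re[wid], dtype=float)
        b0 = est_z[0] + u[0]
        b1 = (est_z[1] if has_age else 0.0) + (u[1] if len(u) > 1 else 0.0)
        if standardize:
            rows[wid] = {"intercept": b0 - b1 * mu / sd, "slope": b1 / sd}
        else:
            rows[wid] = {"intercept": b0, "slope": b1}
    per_whale = pd.DataFrame.from_dict(rows, orient="index")

    loglik = float(result.llf)
    if standardize and estimation == "REML":
        loglik -= np.log(sd)

    return LMMResult(
        variant=variant,
        estimation=estimation,
        loglik=loglik,
        aicc=aicc(loglik, k, n_obs),
        k_params=k,
        n_obs=n_obs,
        n_groups=n_groups,
        fixed_effects=fixed,
        variance_components=vc,
        per_whale=per_whale,
        boundary_variance=boundary,
        converged=bool(result.converged),
    )


@dataclass(frozen=True)
class ModelSelection:
    comparison: pd.DataFrame  # variant, loglik, k, aicc, converged (ML fits)
    best_variant: str
    best: LMMResult  # REML refit of the winner
    ml_fits: dict
    residual_normality_W: float
    residual_normality_p: float
    scale_location_slope: float


def _residual_diagnostics(res: LMMResult, observations: pd.DataFrame, response: str):
    """Shapiro-Wilk on conditional residuals plus a scale-location slope
    (automated stand-ins for visual residual inspection)."""
    df = observations.sort_values(["whale_id", "age"]).reset_index(drop=True)
    coef = res.per_whale
    fitted = np.array(
        [
            coef.loc[w, "intercept"] + coef.loc[w, "slope"] * a
            for w, a in zip(df["whale_id"], df["age"])
        ]
    )
    resid = df[response].to_numpy(dtype=float) - fitted
    w_stat, w_p = stats.shapiro(resid)
    z = np.abs(resid) / np.sqrt(res.variance_components["residual_var"])
    slope = np.polyfit(fitted, np.sqrt(z), 1)[0] if np.ptp(fitted) > 0 else 0.0
    return float(w_stat), float(w_p), float(slope)


def select_model(
    observations: pd.DataFrame, response: str = "response"
) -> ModelSelection:
    """Fit all three candidates by ML, pick the lowest AICc (ties go to the
    simpler variant), and refit the winner by REML."""
    ml_fits: dict[str, LMMResult] = {}
    rows = []
    for variant in VARIANTS:
        try:
            fit = fit_lmm(observations, variant, "ML", response)
            ml_fits[variant] = fit
            rows.append(
                {
                    "variant": variant,
                    "loglik": fit.loglik,
                    "k": fit.k_params,
                    "aicc": fit.aicc,
                    "converged": True,
                }
            )
        except (ConvergenceError, ValueError) as exc:
            rows.append(
                {
                    "variant": variant,
                    "loglik": np.nan,
                    "k": np.nan,
                    "aicc": np.inf,
                    "converged": False,
                    "error": str(exc),
                }
            )
    comparison = pd.DataFrame(rows)
    if not ml_fits:
        raise ConvergenceError("all candidate models failed")
    # ties toward the simpler variant: VARIANTS is ordered simple -> complex
    best_variant = min(
        ml_fits, key=lambda v: (ml_fits[v].aicc, VARIANTS.index(v))
    )
    best = fit_lmm(observations, best_variant, "REML", response)
    w, p, sl = _residual_diagnostics(best, observations, response)
    return ModelSelection(
        comparison=comparison,
        best_variant=best_variant,
        best=best,
        ml_fits=ml_fits,
        residual_normality_W=w,
        residual_normality_p=p,
        scale_location_slope=sl,
    )


def pearson_corr_test(x, y) -> CorrelationResult:
    """Two-tailed Pearson correlation test (t on n-2 df), alpha = 0.05."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no correlation")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(
        n=len(x),
        r=float(r),
        r_squared=float(r * r),
        p_two_tailed=float(p),
        significant=bool(p < 0.05),
    )
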