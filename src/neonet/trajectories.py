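"""Developmental-trajectory modelling with random-intercept mixed models.

Each network metric is regressed on age at scan (PMA, weeks) under
three fixed-effect forms — linear (1, age), quadratic (1, age-c,
(age-c)^2 with c the sample mean age) and logarithmic
(1, ln(age - 20)) — with a subject-level random intercept to absorb
repeated scans, and optionally a sex indicator.  The logarithmic form
is anchored 20 weeks post-conception: over the neonatal scan window
(23-44 wk PMA) ln(age) itself is almost perfectly linear, so an
unanchored log model would be indistinguishable from the linear one;
anchoring gives the log curve its characteristic steep-early/flat-late
shape on the ages actually observed.  The linear and quadratic model
spaces are invariant to such shifts.  Models are estimated by full maximum
likelihood (not REML) so that AIC = 2k - 2 logLik is comparable across
fixed-effect structures; k counts the fixed coefficients plus the two
variance parameters.  The form with the lowest AIC is selected, ties
going to the model with fewer parameters and then to the linear form.

When no subject has a repeated scan the random intercept is not
identifiable; the fit falls back to ordinary least squares with
k = fixed coefficients + 1 and a logged note.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

MODEL_FORMS = ("linear", "quadratic", "logarithmic")

#: post-conception anchor (weeks) subtracted from age inside the log form
LOG_AGE_OFFSET = 20.0

#: tie-break preference order when AICs are exactly equal and k ties
_FORM_PREFERENCE = {"linear": 0, "logarithmic": 1, "quadratic": 2}


@dataclass(frozen=True)
class TrajectoryFit:
    """One model form fitted to one response."""

    form: str
    coefficients: dict[str, float]
    random_intercept_var: float
    residual_var: float
    loglik: float
    k: int               # fixed coefficients + variance parameters
    aic: float
    nobs: int
    age_f: float         # joint Wald F for the age term(s)
    age_p: float
    method: str          # "mixed_ml" or "ols"


def _age_design(age: np.ndarray, form: str) -> tuple[np.ndarray, list[str], list[int]]:
    """Fixed-effect design columns for one form; returns (X, names, age column idx)."""
    if form == "linear":
        X = np.column_stack([np.ones_like(age), age])
        return X, ["intercept", "age"], [1]
    if form == "quadratic":
        c = age - age.mean()
        X = np.column_stack([np.ones_like(age), c, c * c])
        return X, ["intercept", "age_c", "age_c2"], [1, 2]
    if form == "logarithmic":
        if np.any(age <= LOG_AGE_OFFSET):
            raise ValueError(
                f"logarithmic form requires ages above {LOG_AGE_OFFSET} weeks"
            )
        X = np.column_stack([np.ones_like(age), np.log(age - LOG_AGE_OFFSET)])
        return X, ["intercept", "ln_age"], [1]
    raise ValueError(f"unknown form {form!r}; expected one of {MODEL_FORMS}")


def fit_mixed_trajectory(
    table: pd.DataFrame,
    response: str,
    form: str,
    sex_covariate: bool = True,
    age_col: str = "pma_scan",
    subject_col: str = "subject_id",
) -> TrajectoryFit:
    """Fit one fixed-effect form with a subject random intercept (ML)."""
    data = table.dropna(subset=[response]).copy()
    if len(data) < 10:
        raise ValueError(f"need >= 10 observations, got {len(data)}")
    age = data[age_col].to_numpy(float)
    if np.any(age <= 0):
        raise ValueError("age column must be positive")
    y = data[response].to_numpy(float)
    X, names, age_idx = _age_design(age, form)
    if sex_covariate:
        X = np.column_stack([X, (data["sex"] == "male").astype(float).to_numpy()])
        names = names + ["sex_male"]
    groups = data[subject_col].to_numpy()

    repeats = pd.Series(groups).value_counts().max() >= 2
    if repeats:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", UserWarning)
                model = sm.MixedLM(y, X, groups=groups)
                fit = model.fit(reml=False, method="lbfgs")
                if not np.isfinite(fit.llf):
                    raise np.linalg.LinAlgError("non-finite likelihood")
            return _package_mixed(fit, X, names, age_idx, form)
        except (np.linalg.LinAlgError, ValueError) as err:
            logger.info("mixed fit failed (%s); falling back to OLS for form=%s", err, form)
    else:
        logger.info(
            "no subject has repeated scans; random intercept unidentifiable, using OLS"
        )
    return _package_ols(sm.OLS(y, X).fit(), names, age_idx, form)


def _wald_f(params, cov, idx, df_resid):
    """Joint Wald test that the coefficients at ``idx`` are zero, as an F."""
    b = np.asarray(params, float)[idx]
    V = np.asarray(cov, float)[np.ix_(idx, idx)]
    try:
        chi2 = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError:
        return float("nan"), float("nan")
    f = max(chi2 / len(idx), 0.0)
    return f, float(stats.f.sf(f, len(idx), df_resid))


def _package_mixed(fit, X, names, age_idx, form) -> TrajectoryFit:
    p = X.shape[1]
    k = p + 2
    llf = float(fit.llf)
    re_var = float(np.asarray(fit.cov_re)[0, 0])
    resid_var = float(fit.scale)
    df_resid = X.shape[0] - p
    age_f, age_p = _wald_f(fit.fe_params, fit.cov_params()[:p, :p], age_idx, df_resid)
    return TrajectoryFit(
        form=form,
        coefficients=dict(zip(names, np.asarray(fit.fe_params, float))),
        random_intercept_var=re_var,
        residual_var=resid_var,
        loglik=llf,
        k=k,
        aic=2 * k - 2 * llf,
        nobs=X.shape[0],
        age_f=age_f,
        age_p=age_p,
        method="mixed_ml",
    )


def _package_ols(fit, names, age_idx, form) -> TrajectoryFit:
    p = len(names)
    k = p + 1
    llf = float(fit.llf)
    resid_var = float(fit.ssr / fit.nobs)  # ML variance estimate
    y = np.asarray(fit.model.endog, float)
    if resid_var <= 1e-14 * max(float(y.var()), 1e-300):
        # exact fit: the Gaussian likelihood diverges; such fits tie at the
        # top and the selection rule then prefers fewer parameters
        resid_var, llf = 0.0, float("inf")
    age_f, age_p = _wald_f(fit.params, fit.cov_params(), age_idx, fit.df_resid)
    return TrajectoryFit(
        form=form,
        coefficients=dict(zip(names, np.asarray(fit.params, float))),
        random_intercept_var=0.0,
        residual_var=resid_var,
        loglik=llf,
        k=k,
        aic=2 * k - 2 * llf,
        nobs=int(fit.nobs),
        age_f=age_f,
        age_p=age_p,
        method="ols",
    )


def fit_all_forms(
    table: pd.DataFrame,
    response: str,
    sex_covariate: bool = True,
    age_col: str = "pma_scan",
    subject_col: str = "subject_id",
) -> dict[str, TrajectoryFit]:
    """Fit the three candidate forms on identical data."""
    return {
        form: fit_mixed_trajectory(table, response, form, sex_covariate, age_col, subject_col)
        for form in MODEL_FORMS
    }


def select_best_model(fits) -> str:
    """Lowest-AIC form; ties go to fewer parameters, then to linear."""
    if isinstance(fits, dict):
        fits = list(fits.values())
    if len(fits) < 2:
        raise ValueError("need at least two fits to select among")
    nobs = {f.nobs for f in fits}
    if len(nobs) > 1:
        raise ValueError(f"fits use differing observation counts: {sorted(nobs)}")
    best = min(fits, key=lambda f: (f.aic, f.k, _FORM_PREFERENCE[f.form]))
    return best.form


def trajectory_table(fits: dict[str, TrajectoryFit]) -> pd.DataFrame:
    """Model-comparison table: one row per form with (F, p, AIC), best flagged."""
    best = select_best_model(fits)
    rows = [
        {"form": form, "f_value": f.age_f, "p_value": f.age_p, "aic": f.aic,
         "loglik": f.loglik, "k": f.k, "method": f.method, "best": form == best}
        for form, f in fits.items()
    ]
    return pd.DataFrame(rows)


def regional_trajectories(
    nodal_table: pd.DataFrame,
    metrics=("strength", "clustering", "local_efficiency"),
    sex_covariate: bool = True,
    q: float = 0.05,
    age_col: str = "pma_scan",
    subject_col: str = "subject_id",
) -> pd.DataFrame:
    """Best-fitting form per region and metric, with FDR on the age term.

    For each region x metric, all three forms are fitted and the lowest
    AIC wins; the winning form's age p value enters a BH-FDR correction
    across regions (separately per metric).  Returns a tidy frame with
    (region, metric, best_form, age_p, p_adjusted, reject).  Regions
    failing all fits are excluded and logged.
    """
    if nodal_table["cost"].nunique() > 1:
        raise ValueError("regional_trajectories expects a table at a single cost")
    rows = []
    for metric in metrics:
        regional = []
        for region, sub in nodal_table.groupby("region", sort=True, observed=True):
            try:
                fits = fit_all_forms(sub, metric, sex_covariate, age_col, subject_col)
                best = select_best_model(fits)
            except (ValueError, KeyError) as err:
                logger.warning("region %s/%s excluded from trajectories: %s",
                               region, metric, err)
                continue
            regional.append({"region": region, "metric": metric, "best_form": best,
                             "age_p": fits[best].age_p, "aic": fits[best].aic})
        if not regional:
            continue
        sub_df = pd.DataFrame(regional)
        pvals = sub_df["age_p"].fillna(1.0).to_numpy()
        if len(pvals) == 1:
            sub_df["p_adjusted"] = pvals
            sub_df["reject"] = pvals <= q
        else:
            rej, _, p_adj, _ = multipletests(pvals, alpha=q, method="fdr_bh")
            sub_df["p_adjusted"] = p_adj
            sub_df["reject"] = rej
        rows.append(sub_df)
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["region", "metric", "best_form", "age_p", "aic", "p_adjusted", "reject"]
    )
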