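"""Chained-equation imputation of covariates and pooling of Cox estimates.

Variables are visited in order of ascending missingness.  Conditional models
by type: logistic for binary, proportional-odds for ordered categorical, and
linear regression with predictive-mean matching for continuous.  The event
indicator and log follow-up time are always included as predictors, the
standard practice when imputing covariates for a survival model.  Parameter
draws from the asymptotic posterior of each conditional model make the
imputations proper.  Pooling follows the mean rule (pooled coefficient =
arithmetic mean over completed datasets); Rubin's total variance
(within + (1 + 1/m) * between) is also reported for interval construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .survival import CoxFit

logger = logging.getLogger(__name__)

__all__ = ["ImputationSet", "mice_impute", "pool_estimates", "PooledFit"]


@dataclass
class ImputationSet:
    completed: list[pd.DataFrame]
    visit_order: list[str]
    variable_types: dict[str, str]
    m: int
    seed: int


def _classify(series: pd.Series) -> str:
    if pd.api.types.is_numeric_dtype(series):
        return "continuous"
    levels = series.dropna().unique()
    return "binary" if len(levels) == 2 else "ordered"


def _design(df: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    """Numeric design matrix: dummies for categoricals, passthrough numerics."""
    parts = [np.ones((len(df), 1))]
    for col in predictors:
        s = df[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.to_numpy(dtype=float).reshape(-1, 1))
        else:
            d = pd.get_dummies(s, drop_first=True, dtype=float)
            if d.shape[1]:
                parts.append(d.to_numpy())
    x = np.column_stack(parts)
    # drop constant columns beyond the intercept to keep models identifiable
    keep = [0] + [j for j in range(1, x.shape[1]) if x[:, j].std() > 0]
    return x[:, keep]


def _draw_params(mean: np.ndarray, cov: np.ndarray, rng: np.random.Generator):
    try:
        return rng.multivariate_normal(mean, cov, method="cholesky")
    except np.linalg.LinAlgError:
        return rng.multivariate_normal(mean, cov + 1e-8 * np.eye(len(mean)))


def _impute_binary(y, x_obs, x_mis, rng):
    levels = sorted(pd.unique(y))
    y01 = (y == levels[1]).astype(float)
    try:
        res = sm.Logit(y01, x_obs).fit(disp=0, maxiter=100)
        beta = _draw_params(res.params, res.cov_params(), rng)
        p = 1.0 / (1.0 + np.exp(-(x_mis @ beta)))
    except Exception:  # separation etc.: fall back to observed prevalence
        logger.debug("logistic imputation model failed; marginal fallback")
        p = np.full(len(x_mis), y01.mean())
    draws = rng.random(len(x_mis)) < p
    return np.where(draws, levels[1], levels[0])


def _impute_ordered(y, x_obs, x_mis, rng):
    levels = sorted(pd.unique(y))
    codes = pd.Categorical(y, categories=levels, ordered=True).codes.astype(float)
    try:
        mod = OrderedModel(codes, x_obs[:, 1:], distr="logit")
        res = mod.fit(method="bfgs", disp=0, maxiter=200)
        params = _draw_params(res.params, res.cov_params(), rng)
        probs = mod.predict(params, exog=x_mis[:, 1:])
    except Exception:
        logger.debug("ordinal imputation model failed; marginal fallback")
        marg = np.bincount(codes.astype(int), minlength=len(levels)) / len(codes)
        probs = np.tile(marg, (len(x_mis), 1))
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum(axis=1, keepdims=True)
    cum = probs.cumsum(axis=1)
    u = rng.random((len(x_mis), 1))
    idx = (u > cum).sum(axis=1)
    return np.asarray(levels, dtype=object)[idx]


def _impute_continuous_pmm(y, x_obs, x_mis, rng, k_donors: int = 5):
    y = np.asarray(y, dtype=float)
    res = sm.OLS(y, x_obs).fit()
    beta = _draw_params(res.params, res.cov_params(), rng)
    pred_obs = x_obs @ res.params
    pred_mis = x_mis @ beta
    out = np.empty(len(x_mis))
    for i, pm in enumerate(pred_mis):
        nearest = np.argsort(np.abs(pred_obs - pm))[:k_donors]
        out[i] = y[nearest[rng.integers(0, len(nearest))]]
    return out


def mice_impute(
    records: pd.DataFrame,
    variables: list[str] | None = None,
    m: int = 10,
    iterations: int = 10,
    seed: int = 0,
    extra_predictors: list[str] | None = None,
) -> ImputationSet:
    """Multiple imputation by chained equations.

    ``variables`` defaults to every column with at least one missing value
    (object columns use the sentinel 'unknown' as missing).  Fully observed
    covariates plus the outcome columns act as predictors throughout; at
    least one fully observed variable is required.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    df = records.copy()

    # normalise the 'unknown' sentinel to NaN for object columns
    for col in df.columns:
        if df[col].dtype == object:
            df.loc[df[col] == "unknown", col] = np.nan

    if variables is None:
        variables = [c for c in df.columns if df[c].isna().any()]
        skipped = [v for v in variables if df[v].isna().all()]
        if skipped:
            logger.warning("skipping fully missing column(s): %s", skipped)
            variables = [v for v in variables if v not in skipped]
    fully_missing = [v for v in variables if df[v].isna().all()]
    if fully_missing:
        raise ValueError(f"variable(s) 100% missing: {fully_missing}")

    frac = {v: df[v].isna().mean() for v in variables}
    visit_order = sorted(variables, key=lambda v: (frac[v], v))
    var_types = {v: _classify(df[v]) for v in variables}

    default_predictors = [
        c
        for c in df.columns
        if c not in variables
        and not df[c].isna().any()
        and c not in {"subject_id", "family_id"}
        and df[c].nunique() > 1
    ]
    if extra_predictors:
        default_predictors = list(dict.fromkeys(default_predictors + extra_predictors))
    if not default_predictors:
        raise ValueError("need at least one fully observed predictor variable")

    masks = {v: df[v].isna().to_numpy() for v in variables}
    completed: list[pd.DataFrame] = []
    root = np.random.SeedSequence(seed)
    for chain_seed in root.spawn(m):
        rng = np.random.default_rng(chain_seed)
        work = df.copy()
        # initial fill: random draws from the observed distribution
        for v in visit_order:
            obs = work.loc[~masks[v], v].to_numpy()
            work.loc[masks[v], v] = rng.choice(obs, size=masks[v].sum(), replace=True)

        for _ in range(iterations):
            for v in visit_order:
                mask = masks[v]
                if not mask.any():
                    continue
                predictors = default_predictors + [u for u in variables if u != v]
                x = _design(work, predictors)
                y_obs = work.loc[~mask, v]
                x_obs, x_mis = x[~mask], x[mask]
                if var_types[v] == "binary":
                    imputed = _impute_binary(y_obs, x_obs, x_mis, rng)
                elif var_types[v] == "ordered":
                    imputed = _impute_ordered(y_obs, x_obs, x_mis, rng)
                else:
                    imputed = _impute_continuous_pmm(
                        y_obs.to_numpy(), x_obs, x_mis, rng
                    )
                work.loc[mask, v] = imputed
        completed.append(work)

    return ImputationSet(
        completed=completed,
        visit_order=visit_order,
        variable_types=var_types,
        m=m,
        seed=seed,
    )


@dataclass
class PooledFit:
    """Mean-pooled coefficients with Rubin variance decomposition."""

    coefficients: dict[str, float]
    within_var: dict[str, float]
    between_var: dict[str, float]
    total_se: dict[str, float]  # Rubin: sqrt(within + (1 + 1/m) * between)
    hr: dict[str, float]
    m: int

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "hr": self.hr,
            "total_se": self.total_se,
            "m": self.m,
        }


def pool_estimates(fits: list[CoxFit]) -> PooledFit:
    """Pool per-imputation Cox fits.

    The pooled point estimate is the arithmetic mean of the per-imputation
    coefficients; the reported SE uses Rubin's rules as an extension for
    interval construction.
    """
    if len(fits) < 2:
        raise ValueError("pooling needs at least two fits")
    terms = list(fits[0].coefficients)
    for f in fits[1:]:
        if list(f.coefficients) != terms:
            raise ValueError("model terms differ across imputations")
    m = len(fits)
    coefs = {t: np.array([f.coefficients[t] for f in fits]) for t in terms}
    ses = {t: np.array([f.robust_se[t] for f in fits]) for t in terms}
    pooled = {t: float(coefs[t].mean()) for t in terms}
    within = {t: float((ses[t] ** 2).mean()) for t in terms}
    between = {
        t: float(coefs[t].var(ddof=1)) if m > 1 else 0.0 for t in terms
    }
    total = {
        t: float(np.sqrt(within[t] + (1.0 + 1.0 / m) * between[t])) for t in terms
    }
    return PooledFit(
        coefficients=pooled,
        within_var=within,
        between_var=between,
        total_se=total,
        hr={t: float(np.exp(v)) for t, v in pooled.items()},
        m=m,
    )
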