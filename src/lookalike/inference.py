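"""Validation regressions and multiple-imputation pooling.

OLS, logistic, and NB2 negative-binomial fits over the shared
reference-coded design; Poisson-vs-negative-binomial selection on AIC/BIC;
and Rubin's-rules combination of per-imputation results with the
Barnard-Rubin small-sample degrees of freedom.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .design import check_full_rank, design_matrix, encode_binary
from .errors import (
    AlignmentError,
    ConvergenceError,
    ModelError,
    SeparationError,
)
from .schema import HarmonizedTable, Schema

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))

ALPHA_BOUNDARY = 1e-3  # below this the NB2 dispersion is at the Poisson boundary


def significance_stars(p: float) -> str:
    for threshold, marker in STAR_THRESHOLDS:
        if p < threshold:
            return marker
    return ""


@dataclass
class RegressionResult:
    """One fitted regression, aligned on named coefficients."""

    family: str
    coefficients: pd.Series
    standard_errors: pd.Series
    covariance: pd.DataFrame
    n: int
    df_resid: float
    loglik: float
    aic: float
    bic: float
    lnalpha: float | None = None
    lnalpha_se: float | None = None
    alpha_boundary: bool = False

    def __post_init__(self):
        if list(self.coefficients.index) != list(self.standard_errors.index):
            raise AlignmentError("coefficient and SE names must coincide")
        if self.n <= len(self.coefficients):
            raise ModelError("need more rows than coefficients")

    @property
    def pvalues(self) -> pd.Series:
        se = self.standard_errors.replace(0.0, np.nan)
        if self.family == "ols":
            t = self.coefficients / se
            p = 2.0 * stats.t.sf(np.abs(t), df=self.df_resid)
        else:
            z = self.coefficients / se
            p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.Series(p, index=self.coefficients.index).fillna(0.0)

    @property
    def stars(self) -> pd.Series:
        return self.pvalues.map(significance_stars)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.coefficients,
                "se": self.standard_errors,
                "p": self.pvalues,
                "stars": self.stars,
            }
        )

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "family": self.family,
            "coefficients": self.coefficients.to_dict(),
            "standard_errors": self.standard_errors.to_dict(),
            "covariance": self.covariance.to_numpy().tolist(),
            "names": list(self.coefficients.index),
            "n": self.n,
            "df_resid": self.df_resid,
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "lnalpha": self.lnalpha,
            "lnalpha_se": self.lnalpha_se,
            "alpha_boundary": self.alpha_boundary,
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(doc, fh, indent=2)
        return doc

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "RegressionResult":
        if not isinstance(source, dict):
            with open(source) as fh:
                source = json.load(fh)
        names = source["names"]
        return cls(
            family=source["family"],
            coefficients=pd.Series(source["coefficients"]).reindex(names),
            standard_errors=pd.Series(source["standard_errors"]).reindex(names),
            covariance=pd.DataFrame(source["covariance"], index=names, columns=names),
            n=source["n"],
            df_resid=source["df_resid"],
            loglik=source["loglik"],
            aic=source["aic"],
            bic=source["bic"],
            lnalpha=source.get("lnalpha"),
            lnalpha_se=source.get("lnalpha_se"),
            alpha_boundary=source.get("alpha_boundary", False),
        )


def _resolve(table, schema: Schema | None):
    if isinstance(table, HarmonizedTable):
        return table.data, table.schema
    if schema is None:
        raise ModelError("a Schema is required when passing a bare DataFrame")
    return table, schema


def fit_ols(table, outcome: str, predictors: Sequence[str], schema: Schema | None = None) -> RegressionResult:
    """Least squares with classical standard errors."""
    data, schema = _resolve(table, schema)
    X = design_matrix(data, list(predictors), schema)
    check_full_rank(X)
    y = pd.to_numeric(data[outcome]).to_numpy(dtype=float)
    res = sm.OLS(y, X.to_numpy(), hasconst=True).fit()
    names = list(X.columns)
    return RegressionResult(
        family="ols",
        coefficients=pd.Series(res.params, index=names),
        standard_errors=pd.Series(res.bse, index=names),
        covariance=pd.DataFrame(res.cov_params(), index=names, columns=names),
        n=int(res.nobs),
        df_resid=float(res.df_resid),
        loglik=float(res.llf),
        aic=float(res.aic),
        bic=float(res.bic),
    )


def fit_logistic(table, outcome: str, predictors: Sequence[str], schema: Schema | None = None) -> RegressionResult:
    """Binary logistic regression (MLE, inverse-Hessian SEs)."""
    data, schema = _resolve(table, schema)
    var = schema[outcome]
    if var.family == "binary":
        y = encode_binary(data[outcome], var)
    else:
        y = pd.to_numeric(data[outcome]).to_numpy(dtype=float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ModelError(f"outcome {outcome!r} is not binary")
    if len(np.unique(y)) < 2:
        raise SeparationError("outcome has a single observed class")
    X = design_matrix(data, list(predictors), schema)
    check_full_rank(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X.to_numpy()).fit(disp=0, maxiter=200)
        except PerfectSeparationError as exc:
            raise SeparationError(str(exc)) from exc
    if not res.mle_retvals.get("converged", True):
        raise ConvergenceError("logistic fit did not converge")
    names = list(X.columns)
    return RegressionResult(
        family="logistic",
        coefficients=pd.Series(np.asarray(res.params), index=names),
        standard_errors=pd.Series(np.asarray(res.bse), index=names),
        covariance=pd.DataFrame(np.asarray(res.cov_params()), index=names, columns=names),
        n=int(res.nobs),
        df_resid=float(res.df_resid),
        loglik=float(res.llf),
        aic=float(res.aic),
        bic=float(res.bic),
    )


def _validate_counts(y: np.ndarray, outcome: str) -> None:
    if np.any(y < 0) or np.any(np.abs(y - np.rint(y)) > 1e-9):
        raise ModelError(f"outcome {outcome!r} must hold non-negative integers")


def fit_negbin(table, outcome: str, predictors: Sequence[str], schema: Schema | None = None) -> RegressionResult:
    """NB2 negative-binomial regression; reports lnalpha with its SE."""
    data, schema = _resolve(table, schema)
    y = pd.to_numeric(data[outcome]).to_numpy(dtype=float)
    _validate_counts(y, outcome)
    X = design_matrix(data, list(predictors), schema)
    check_full_rank(X)
    names = list(X.columns)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start = sm.Poisson(y, X.to_numpy()).fit(disp=0, maxiter=200).params
        model = sm.NegativeBinomial(y, X.to_numpy(), loglike_method="nb2")
        try:
            res = model.fit(start_params=np.append(start, 0.5), disp=0, maxiter=500)
        except Exception:
            try:
                res = model.fit(
                    start_params=np.append(start, 0.5), method="nm", disp=0, maxiter=5000
                )
            except Exception as exc:  # pragma: no cover
                raise ConvergenceError(f"negative binomial fit failed: {exc}") from exc
    params = np.asarray(res.params)
    if not np.all(np.isfinite(params)):
        raise ConvergenceError("negative binomial fit diverged")
    cov = np.asarray(res.cov_params())
    alpha = float(params[-1])
    se_alpha = float(np.sqrt(max(cov[-1, -1], 0.0)))
    # at the Poisson limit alpha piles up on 0: flag when it is either tiny
    # or statistically indistinguishable from zero
    boundary = alpha < ALPHA_BOUNDARY or alpha <= 2.0 * se_alpha
    alpha_safe = max(alpha, 1e-12)
    lnalpha = float(np.log(alpha_safe))
    alpha_var = cov[-1, -1]
    lnalpha_se = float(np.sqrt(max(alpha_var, 0.0)) / alpha_safe)
    return RegressionResult(
        family="negbin",
        coefficients=pd.Series(params[:-1], index=names),
        standard_errors=pd.Series(np.sqrt(np.diag(cov))[:-1], index=names),
        covariance=pd.DataFrame(cov[:-1, :-1], index=names, columns=names),
        n=int(res.nobs),
        df_resid=float(res.nobs - len(names)),
        loglik=float(res.llf),
        aic=float(res.aic),
        bic=float(res.bic),
        lnalpha=lnalpha,
        lnalpha_se=lnalpha_se,
        alpha_boundary=boundary,
    )


def fit_poisson(table, outcome: str, predictors: Sequence[str], schema: Schema | None = None) -> RegressionResult:
    """Poisson regression (used for count-family selection)."""
    data, schema = _resolve(table, schema)
    y = pd.to_numeric(data[outcome]).to_numpy(dtype=float)
    _validate_counts(y, outcome)
    X = design_matrix(data, list(predictors), schema)
    check_full_rank(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Poisson(y, X.to_numpy()).fit(disp=0, maxiter=200)
    names = list(X.columns)
    return RegressionResult(
        family="poisson",
        coefficients=pd.Series(np.asarray(res.params), index=names),
        standard_errors=pd.Series(np.asarray(res.bse), index=names),
        covariance=pd.DataFrame(np.asarray(res.cov_params()), index=names, columns=names),
        n=int(res.nobs),
        df_resid=float(res.df_resid),
        loglik=float(res.llf),
        aic=float(res.aic),
        bic=float(res.bic),
    )


@dataclass
class CountFamilySelection:
    """AIC/BIC comparison of Poisson vs negative binomial."""

    recommended: str | None
    table: pd.DataFrame
    tie: bool
    poisson: RegressionResult
    negbin: RegressionResult


def select_count_family(table, outcome: str, predictors: Sequence[str], schema: Schema | None = None) -> CountFamilySelection:
    """Fit Poisson and NB2; recommend the family winning on both AIC and BIC."""
    pois = fit_poisson(table, outcome, predictors, schema)
    nb = fit_negbin(table, outcome, predictors, schema)
    crit = pd.DataFrame(
        {"aic": [pois.aic, nb.aic], "bic": [pois.bic, nb.bic]},
        index=["poisson", "negbin"],
    )
    aic_winner = crit["aic"].idxmin()
    bic_winner = crit["bic"].idxmin()
    tie = aic_winner != bic_winner
    return CountFamilySelection(
        recommended=None if tie else aic_winner,
        table=crit,
        tie=tie,
        poisson=pois,
        negbin=nb,
    )


@dataclass
class PooledResult:
    """Rubin-combined estimates across m imputations."""

    q_bar: pd.Series
    W: pd.Series
    B_var: pd.Series
    T_var: pd.Series
    df: pd.Series
    p: pd.Series
    m: int
    n: int
    family: str

    @property
    def standard_errors(self) -> pd.Series:
        return np.sqrt(self.T_var)

    # alias so pooled and single-fit results render interchangeably
    @property
    def coefficients(self) -> pd.Series:
        return self.q_bar

    @property
    def pvalues(self) -> pd.Series:
        return self.p

    @property
    def stars(self) -> pd.Series:
        return self.p.map(significance_stars)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.q_bar,
                "se": self.standard_errors,
                "W": self.W,
                "B": self.B_var,
                "T": self.T_var,
                "df": self.df,
                "p": self.p,
                "stars": self.stars,
            }
        )

    def to_json(self, path: str | Path | None = None) -> dict:
        doc = {
            "family": self.family,
            "m": self.m,
            "n": self.n,
            "names": list(self.q_bar.index),
            "q_bar": self.q_bar.to_dict(),
            "W": self.W.to_dict(),
            "B_var": self.B_var.to_dict(),
            "T_var": self.T_var.to_dict(),
            "df": self.df.to_dict(),
            "p": self.p.to_dict(),
        }
        if path is not None:
            with open(path, "w") as fh:
                json.dump(doc, fh, indent=2)
        return doc

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "PooledResult":
        if not isinstance(source, dict):
            with open(source) as fh:
                source = json.load(fh)
        names = source["names"]

        def s(key):
            return pd.Series(source[key]).reindex(names)

        return cls(
            q_bar=s("q_bar"), W=s("W"), B_var=s("B_var"), T_var=s("T_var"),
            df=s("df"), p=s("p"), m=source["m"], n=source["n"], family=source["family"],
        )


def pool_rubin(results: Sequence[RegressionResult]) -> PooledResult:
    """Combine per-imputation fits by Rubin's rules.

    T = W + (1 + 1/m) B with the Barnard-Rubin adjusted degrees of freedom;
    p-values are two-sided from the t reference.
    """
    m = len(results)
    if m < 2:
        raise ModelError("pooling needs at least 2 imputations")
    names = list(results[0].coefficients.index)
    for r in results[1:]:
        if list(r.coefficients.index) != names:
            raise AlignmentError("coefficient names differ across imputations")

    est = np.vstack([r.coefficients.to_numpy() for r in results])
    ses = np.vstack([r.standard_errors.to_numpy() for r in results])
    q_bar = est.mean(axis=0)
    W = (ses**2).mean(axis=0)
    B = est.var(axis=0, ddof=1)
    T = W + (1.0 + 1.0 / m) * B

    nu_com = min(float(r.df_resid) for r in results)
    lam = np.divide((1.0 + 1.0 / m) * B, T, out=np.zeros_like(T), where=T > 0)
    nu_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
    with np.errstate(divide="ignore"):
        nu_old = np.where(lam > 0, (m - 1) / np.square(lam), np.inf)
    df = 1.0 / (1.0 / nu_old + 1.0 / np.maximum(nu_obs, 1e-12))

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(T > 0, q_bar / np.sqrt(T), np.inf)
    p = 2.0 * stats.t.sf(np.abs(tstat), df=np.maximum(df, 1e-6))

    idx = pd.Index(names)
    return PooledResult(
        q_bar=pd.Series(q_bar, index=idx),
        W=pd.Series(W, index=idx),
        B_var=pd.Series(B, index=idx),
        T_var=pd.Series(T, index=idx),
        df=pd.Series(df, index=idx),
        p=pd.Series(p, index=idx),
        m=m,
        n=min(r.n for r in results),
        family=results[0].family,
    )


FITTERS = {
    "ols": fit_ols,
    "logistic": fit_logistic,
    "negbin": fit_negbin,
    "poisson": fit_poisson,
}
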