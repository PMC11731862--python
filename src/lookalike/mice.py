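"""Chained-equations multiple imputation with proper parameter draws.

Each incomplete variable gets a univariate conditional model (its family
matched to the variable's type); every iteration refits the conditional on
the currently-completed data, draws parameters from their approximate
posterior, and draws imputations from the conditional given those
parameters.  Gaussian conditionals use the exact normal-inverse-chi-square
draw; likelihood-based families use a large-sample normal draw around the
MLE.  Repeating the chain with independent sub-streams yields the m
completed datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import ConvergenceWarning, PerfectSeparationError

from .design import check_full_rank, decode_binary, design_matrix, encode_binary
from .errors import (
    ConvergenceError,
    DonorPoolError,
    ModelError,
    SchemaError,
    SeparationError,
)
from .schema import HarmonizedTable, Schema

CONDITIONAL_FAMILIES = ("bayes_linear", "logistic", "multinomial", "pmm", "negbin_draw")

_FAMILY_FOR_SCHEMA = {
    "continuous": ("bayes_linear", "pmm"),
    "count": ("negbin_draw", "pmm", "bayes_linear"),
    "binary": ("logistic",),
    "categorical": ("multinomial",),
}


@dataclass(frozen=True)
class ConditionalModelSpec:
    """Univariate imputation model for one variable."""

    variable: str
    family: str
    predictors: tuple[str, ...]
    pmm_k: int = 5

    def __post_init__(self):
        if self.family not in CONDITIONAL_FAMILIES:
            raise ModelError(f"unknown conditional family {self.family!r}")
        if self.variable in self.predictors:
            raise ModelError(f"{self.variable!r} cannot predict itself")
        if self.pmm_k < 1:
            raise ModelError("pmm_k must be >= 1")

    def validate_against(self, schema: Schema) -> None:
        fam = schema[self.variable].family
        if self.family not in _FAMILY_FOR_SCHEMA[fam]:
            raise ModelError(
                f"family {self.family!r} incompatible with {fam} variable {self.variable!r}"
            )


def default_family(schema_family: str) -> str:
    return _FAMILY_FOR_SCHEMA[schema_family][0]


@dataclass
class FittedConditional:
    """MLE (or least-squares) fit of one conditional, with covariance."""

    family: str
    params: np.ndarray
    cov: np.ndarray
    names: list[str]
    n: int
    # bayes_linear / pmm extras
    resid_var: float | None = None
    df_resid: int | None = None
    xtx_inv: np.ndarray | None = None
    # pmm donor info
    y_obs: np.ndarray | None = None
    yhat_obs: np.ndarray | None = None
    # multinomial: number of modelled classes and their original codes
    n_categories: int | None = None
    category_codes: np.ndarray | None = None


@dataclass
class Phi:
    """Drawn conditional-model parameters for one imputation step."""

    family: str
    beta: np.ndarray
    sigma2: float | None = None
    alpha: float | None = None
    fitted: FittedConditional | None = None
    pmm_k: int = 5


@dataclass
class ChainState:
    """State of one imputation chain."""

    completed: pd.DataFrame
    t: int
    T: int
    phi: dict = field(default_factory=dict)
    rng: np.random.Generator | None = None


@dataclass
class ImputedSet:
    """m completed datasets plus per-variable chain diagnostics."""

    datasets: list[pd.DataFrame]
    m: int
    T: int
    seed: int | None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.m < 1 or len(self.datasets) != self.m:
            raise ModelError("ImputedSet needs m >= 1 datasets")

    def write(self, outdir: str | Path, specs: Sequence[ConditionalModelSpec] = ()) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.datasets):
            df.to_csv(outdir / f"imputation_{i:03d}.csv", index=False)
        import json

        manifest = {
            "m": self.m,
            "T": self.T,
            "seed": self.seed,
            "specs": [
                {
                    "variable": s.variable,
                    "family": s.family,
                    "predictors": list(s.predictors),
                    "pmm_k": s.pmm_k,
                }
                for s in specs
            ],
            "diagnostics": self.diagnostics,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return outdir


# --------------------------------------------------------------------------
# fitting


def fit_conditional(
    y_observed: np.ndarray,
    X_observed: pd.DataFrame,
    family: str,
) -> FittedConditional:
    """Fit one conditional model on the observed rows.

    bayes_linear/pmm use the normal equations with residual variance and
    (X'X)^-1 retained for the posterior draw; likelihood families return the
    MLE with inverse-Hessian covariance.
    """
    y = np.asarray(y_observed, dtype=float)
    X = X_observed
    n, p = X.shape
    if n < p + 1:
        raise ModelError(f"need at least {p + 1} observed rows to fit {p} parameters, got {n}")
    check_full_rank(X)
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)

    if family in ("bayes_linear", "pmm"):
        xtx = Xa.T @ Xa
        xtx_inv = np.linalg.inv(xtx)
        beta = xtx_inv @ (Xa.T @ y)
        resid = y - Xa @ beta
        df = n - p
        rss = float(resid @ resid)
        resid_var = rss / df if df > 0 else 0.0
        if resid_var < 1e-12:
            resid_var = 0.0
        return FittedConditional(
            family=family,
            params=beta,
            cov=resid_var * xtx_inv,
            names=names,
            n=n,
            resid_var=resid_var,
            df_resid=df,
            xtx_inv=xtx_inv,
            y_obs=y.copy(),
            yhat_obs=Xa @ beta,
        )

    if family == "logistic":
        classes = np.unique(y)
        if len(classes) < 2:
            raise SeparationError("outcome has a single observed class")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, Xa).fit(disp=0, maxiter=200)
            except PerfectSeparationError as exc:
                raise SeparationError(str(exc)) from exc
        if not res.mle_retvals.get("converged", True):
            raise ConvergenceError("logistic fit did not converge")
        return FittedConditional(
            family=family, params=np.asarray(res.params), cov=np.asarray(res.cov_params()),
            names=names, n=n,
        )

    if family == "multinomial":
        codes = np.asarray(y, dtype=int)
        uniq = np.unique(codes)
        if len(uniq) < 2:
            raise SeparationError("outcome has a single observed class")
        recoded = np.searchsorted(uniq, codes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.MNLogit(recoded, Xa).fit(disp=0, maxiter=200)
            except PerfectSeparationError as exc:
                raise SeparationError(str(exc)) from exc
        if not res.mle_retvals.get("converged", True):
            raise ConvergenceError("multinomial fit did not converge")
        # params: (p, J-1); flatten column-major to match cov_params ordering
        params = np.asarray(res.params).flatten(order="F")
        return FittedConditional(
            family=family, params=params, cov=np.asarray(res.cov_params()),
            names=names, n=n, n_categories=len(uniq), category_codes=uniq,
        )

    if family == "negbin_draw":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            start = sm.Poisson(y, Xa).fit(disp=0, maxiter=200).params
            model = sm.NegativeBinomial(y, Xa, loglike_method="nb2")
            try:
                res = model.fit(start_params=np.append(start, 0.5), disp=0, maxiter=500)
            except Exception:
                res = model.fit(
                    start_params=np.append(start, 0.5), method="nm", disp=0, maxiter=2000
                )
        params = np.asarray(res.params)
        cov = np.asarray(res.cov_params())
        if not np.all(np.isfinite(params)):
            raise ConvergenceError("negative binomial fit diverged")
        return FittedConditional(
            family=family, params=params, cov=cov, names=names + ["alpha"], n=n,
        )

    raise ModelError(f"unknown conditional family {family!r}")


def _safe_cholesky(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh((cov + cov.T) / 2.0)
        w = np.clip(w, 0.0, None)
        if np.any(~np.isfinite(w)):
            raise ModelError("covariance matrix is not positive semidefinite")
        return v @ np.diag(np.sqrt(w))


def draw_parameters(fitted: FittedConditional, rng: np.random.Generator) -> Phi:
    """Draw phi from the approximate posterior of the fitted conditional."""
    if fitted.family in ("bayes_linear", "pmm"):
        df = fitted.df_resid
        if fitted.resid_var == 0.0 or df <= 0:
            return Phi(
                family=fitted.family, beta=fitted.params.copy(), sigma2=0.0, fitted=fitted
            )
        sigma2_star = fitted.resid_var * df / rng.chisquare(df)
        chol = _safe_cholesky(sigma2_star * fitted.xtx_inv)
        beta_star = fitted.params + chol @ rng.standard_normal(len(fitted.params))
        return Phi(
            family=fitted.family, beta=beta_star, sigma2=float(sigma2_star), fitted=fitted
        )

    if fitted.family == "negbin_draw":
        # draw on (beta, lnalpha): delta-method transform of the alpha block
        params = fitted.params.copy()
        cov = fitted.cov.copy()
        alpha_hat = max(params[-1], 1e-8)
        jac = np.ones(len(params))
        jac[-1] = 1.0 / alpha_hat
        cov_t = cov * np.outer(jac, jac)
        mean_t = params.copy()
        mean_t[-1] = np.log(alpha_hat)
        draw = mean_t + _safe_cholesky(cov_t) @ rng.standard_normal(len(params))
        return Phi(
            family=fitted.family,
            beta=draw[:-1],
            alpha=float(np.exp(draw[-1])),
            fitted=fitted,
        )

    draw = fitted.params + _safe_cholesky(fitted.cov) @ rng.standard_normal(len(fitted.params))
    return Phi(family=fitted.family, beta=draw, fitted=fitted)


def impute_from_conditional(
    phi: Phi,
    X_missing: pd.DataFrame,
    family: str | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw imputed values for the missing rows given drawn parameters."""
    family = family or phi.family
    rng = rng if rng is not None else np.random.default_rng()
    Xa = X_missing.to_numpy(dtype=float)
    n_mis = Xa.shape[0]
    if n_mis == 0:
        return np.empty(0)

    if family == "bayes_linear":
        mu = Xa @ phi.beta
        sd = np.sqrt(phi.sigma2 or 0.0)
        return mu + sd * rng.standard_normal(n_mis)

    if family == "logistic":
        p = 1.0 / (1.0 + np.exp(-(Xa @ phi.beta)))
        return (rng.random(n_mis) < p).astype(float)

    if family == "multinomial":
        fitted = phi.fitted
        J = fitted.n_categories
        p = Xa.shape[1]
        B = phi.beta.reshape(p, J - 1, order="F")
        eta = np.column_stack([np.zeros(n_mis), Xa @ B])
        eta -= eta.max(axis=1, keepdims=True)
        probs = np.exp(eta)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n_mis)
        idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        idx = np.minimum(idx, J - 1)
        return fitted.category_codes[idx].astype(float)

    if family == "pmm":
        fitted = phi.fitted
        k = phi.pmm_k
        if fitted is None or fitted.y_obs is None or len(fitted.y_obs) < k:
            raise DonorPoolError(
                f"predictive mean matching needs at least {k} observed rows"
            )
        yhat_mis = Xa @ phi.beta
        out = np.empty(n_mis)
        for i, pred in enumerate(yhat_mis):
            dist = np.abs(fitted.yhat_obs - pred)
            donors = np.argpartition(dist, k - 1)[:k]
            out[i] = fitted.y_obs[donors[rng.integers(k)]]
        return out

    if family == "negbin_draw":
        mu = np.exp(np.clip(Xa @ phi.beta, -30, 30))
        alpha = max(phi.alpha or 1e-8, 1e-8)
        r = 1.0 / alpha
        p = r / (r + mu)
        return rng.negative_binomial(r, p).astype(float)

    raise ModelError(f"unknown conditional family {family!r}")


# --------------------------------------------------------------------------
# the chained-equations driver


def _encode_y(values: pd.Series, var, family: str) -> np.ndarray:
    if family == "logistic":
        return encode_binary(values, var)
    if family == "multinomial":
        return pd.Categorical(values, categories=list(var.categories)).codes.astype(float)
    return pd.to_numeric(values).to_numpy(dtype=float)


def _decode_y(draws: np.ndarray, var, family: str):
    if family == "logistic":
        return decode_binary(draws, var)
    if family == "multinomial":
        cats = np.array(var.categories, dtype=object)
        return cats[draws.astype(int)]
    return draws


def run_mice(
    data: HarmonizedTable,
    specs: Sequence[ConditionalModelSpec],
    m: int = 10,
    T: int = 10,
    seed: int | None = None,
) -> ImputedSet:
    """Run chained-equations multiple imputation.

    Visits incomplete variables in schema order each of T iterations,
    refitting on the currently-completed data, drawing parameters, and
    imputing; repeated with independent RNG sub-streams for each of the m
    datasets.
    """
    if m < 1 or T < 1:
        raise ModelError("m and T must both be >= 1")
    schema = data.schema
    spec_by_var = {}
    for spec in specs:
        if spec.variable not in schema:
            raise SchemaError(f"spec targets unknown variable {spec.variable!r}")
        spec.validate_against(schema)
        spec_by_var[spec.variable] = spec

    incomplete = data.missing_variables()
    unspecified = [v for v in incomplete if v not in spec_by_var]
    if unspecified:
        raise ModelError(f"incomplete variables without a conditional spec: {unspecified}")
    visit = [v for v in schema.names if v in spec_by_var and v in incomplete]

    obs_mask = {v: data.mask[v].to_numpy(dtype=bool) for v in visit}
    for v in visit:
        if obs_mask[v].sum() == 0:
            raise ModelError(f"variable {v!r} has no observed values anywhere")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(m)
    datasets: list[pd.DataFrame] = []
    diagnostics: dict[str, dict[str, list]] = {
        v: {"mean": [], "sd": []} for v in visit
    }

    for child in children:
        rng = np.random.default_rng(child)
        completed = data.data.copy()
        # t = 0: initialize missing cells from observed marginals
        for v in visit:
            obs = obs_mask[v]
            pool = completed.loc[obs, v].to_numpy()
            completed.loc[~obs, v] = rng.choice(pool, size=int((~obs).sum()), replace=True)
        state = ChainState(completed=completed, t=0, T=T, rng=rng)
        trace = {v: {"mean": [], "sd": []} for v in visit}

        for t in range(1, T + 1):
            for v in visit:
                spec = spec_by_var[v]
                var = schema[v]
                obs = obs_mask[v]
                X = design_matrix(state.completed, list(spec.predictors), schema)
                y_obs = _encode_y(state.completed.loc[obs, v], var, spec.family)
                try:
                    fitted = fit_conditional(y_obs, X.loc[obs], spec.family)
                except ModelError as exc:
                    exc.add_note(f"while imputing variable {v!r}, iteration {t}")
                    raise
                phi = draw_parameters(fitted, rng)
                phi.pmm_k = spec.pmm_k
                state.phi[v] = phi
                draws = impute_from_conditional(phi, X.loc[~obs], spec.family, rng)
                state.completed.loc[~obs, v] = _decode_y(draws, var, spec.family)
                numeric = _encode_y(state.completed.loc[~obs, v], var, spec.family)
                trace[v]["mean"].append(float(np.mean(numeric)))
                trace[v]["sd"].append(float(np.std(numeric)))
            state.t = t

        for v in visit:
            diagnostics[v]["mean"].append(trace[v]["mean"])
            diagnostics[v]["sd"].append(trace[v]["sd"])
        datasets.append(state.completed)

    return ImputedSet(datasets=datasets, m=m, T=T, seed=seed, diagnostics=diagnostics)


def plot_traces(imputed: ImputedSet, outfile: str | Path) -> Path:
    """Chain-trace diagnostic plot (mean and sd of imputed values by iteration)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    variables = list(imputed.diagnostics)
    fig, axes = plt.subplots(
        max(len(variables), 1), 2, figsize=(8, 2.5 * max(len(variables), 1)), squeeze=False
    )
    for i, v in enumerate(variables):
        for stat, ax in zip(("mean", "sd"), axes[i]):
            for chain in imputed.diagnostics[v][stat]:
                ax.plot(range(1, len(chain) + 1), chain, alpha=0.6)
            ax.set_title(f"{v}: imputed {stat}")
            ax.set_xlabel("iteration")
    fig.tight_layout()
    fig.savefig(outfile)
    plt.close(fig)
    return Path(outfile)
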