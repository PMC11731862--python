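"""Seeded generators for survey-like and service-like populations.

Profiles hold published marginals (category percentages, age mean/SD,
dependant-count mean/SD); covariates are drawn independently per variable
unless a dependence hook is supplied.  Outcomes are generated from an
additive linear predictor over the reference-coded design, per family:
gaussian (normal error), bernoulli (logistic link), overdispersed count
(NB2 with log link).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .design import design_matrix
from .errors import ModelError, SchemaError
from .harmonization import default_schema
from .schema import HarmonizedTable, Schema, VariableSchema, empty_table

OUTCOME_FAMILIES = ("gaussian", "bernoulli", "count_negbin")


def truncated_normal_params(mean: float, sd: float, lower: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a lower-truncated normal with given realized moments.

    Published age summaries describe the truncated (age >= lower) scale, so
    the parent normal is calibrated by inverting the truncated-moment map.
    """

    def moments(x):
        mu, log_sigma = x
        sigma = math.exp(log_sigma)
        a = (lower - mu) / sigma
        lam = stats.norm.pdf(a) / stats.norm.sf(a)
        m = mu + sigma * lam
        v = sigma**2 * (1.0 + a * lam - lam**2)
        return [m - mean, math.sqrt(max(v, 1e-12)) - sd]

    sol = optimize.root(moments, x0=[mean, math.log(sd)], method="hybr")
    if not sol.success:  # pragma: no cover - well-behaved for realistic inputs
        raise ModelError(f"truncated-normal calibration failed: {sol.message}")
    mu, log_sigma = sol.x
    return float(mu), float(math.exp(log_sigma))


def _negbin_from_moments(mean: float, sd: float) -> float | None:
    """NB2 dispersion alpha matching (mean, sd); None means equidispersed."""
    var = sd**2
    if var <= mean:
        return None
    return (var - mean) / mean**2


@dataclass
class PopulationProfile:
    """Marginal specification of one source population."""

    name: str
    n_default: int
    categorical: dict[str, dict[str, float]]
    continuous: dict[str, dict] = field(default_factory=dict)
    count: dict[str, dict] = field(default_factory=dict)
    cluster_rate: float = 0.0
    dependence: Callable[[pd.DataFrame, np.random.Generator], pd.DataFrame] | None = None

    def __post_init__(self):
        normalized = {}
        for var, probs in self.categorical.items():
            total = float(sum(probs.values()))
            if total <= 0:
                raise SchemaError(f"non-positive marginal mass for {var!r}")
            normalized[var] = {k: v / total for k, v in probs.items()}
            assert abs(sum(normalized[var].values()) - 1.0) < 1e-9
        self.categorical = normalized
        for var, spec in self.continuous.items():
            if spec["sd"] <= 0:
                raise SchemaError(f"sd must be positive for {var!r}")
        for var, spec in self.count.items():
            if spec["sd"] <= 0:
                raise SchemaError(f"sd must be positive for {var!r}")
        if not 0.0 <= self.cluster_rate < 1.0:
            raise SchemaError("cluster_rate must be in [0, 1)")


def load_profiles(path: str | Path | None = None) -> dict[str, PopulationProfile]:
    """Load profiles from YAML; defaults to the packaged csew/rcew file."""
    if path is None:
        source = resources.files("lookalike.config") / "profiles.yaml"
        doc = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    profiles = {}
    for name, p in doc["profiles"].items():
        profiles[name] = PopulationProfile(
            name=name,
            n_default=int(p.get("n_default", 0)),
            categorical={k: dict(v) for k, v in p.get("categorical", {}).items()},
            continuous={k: dict(v) for k, v in p.get("continuous", {}).items()},
            count={k: dict(v) for k, v in p.get("count", {}).items()},
            cluster_rate=float(p.get("cluster_rate", 0.0)),
        )
    return profiles


def builtin_profile(name: str) -> PopulationProfile:
    profiles = load_profiles()
    if name not in profiles:
        raise SchemaError(f"unknown builtin profile {name!r}; have {sorted(profiles)}")
    return profiles[name]


@dataclass
class OutcomeModel:
    """Generative regression model for one outcome variable.

    ``beta`` maps design-column names (``Intercept``, ``var[category]``,
    continuous names) to coefficients; unmentioned columns get zero.
    ``gamma`` maps cluster-level covariate columns to coefficients.
    """

    outcome: str
    family: str
    predictors: list[str]
    beta: Mapping[str, float]
    gamma: Mapping[str, float] = field(default_factory=dict)
    sigma2: float = 1.0
    dispersion: float = 1.0

    def __post_init__(self):
        if self.family not in OUTCOME_FAMILIES:
            raise ModelError(f"unknown outcome family {self.family!r}")
        if self.family == "gaussian" and self.sigma2 <= 0:
            raise ModelError("sigma2 must be positive")
        if self.family == "count_negbin" and self.dispersion <= 0:
            raise ModelError("dispersion must be positive")

    @property
    def schema_variable(self) -> VariableSchema:
        if self.family == "gaussian":
            return VariableSchema(self.outcome, "continuous", role="target")
        if self.family == "bernoulli":
            return VariableSchema(
                self.outcome, "binary", categories=("no", "yes"), reference="no", role="target"
            )
        return VariableSchema(self.outcome, "count", role="target")


@dataclass
class FusionScenario:
    """Two populations sharing one generative outcome model."""

    profile_A: PopulationProfile
    profile_B: PopulationProfile
    shared_outcome: OutcomeModel
    n_A: int
    n_B: int
    seed: int


def generate_covariates(
    profile: PopulationProfile,
    n: int,
    seed: int | np.random.SeedSequence,
    schema: Schema | None = None,
) -> HarmonizedTable:
    """Draw ``n`` records from the profile marginals; fully deterministic in seed."""
    if n < 0:
        raise SchemaError("n must be non-negative")
    schema = schema if schema is not None else default_schema()
    for var in list(profile.categorical) + list(profile.continuous) + list(profile.count):
        if var not in schema:
            raise SchemaError(f"profile variable {var!r} not in schema")
    if n == 0:
        return empty_table(schema)

    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for var in schema:
        name = var.name
        if name in profile.categorical:
            probs = profile.categorical[name]
            cats = [c for c in var.categories if c in probs]
            missing = set(probs) - set(var.categories)
            if missing or len(cats) != len(probs):
                raise SchemaError(f"marginal categories for {name!r} do not match schema")
            p = np.array([probs[c] for c in cats])
            cols[name] = rng.choice(np.array(cats, dtype=object), size=n, p=p)
        elif name in profile.continuous:
            spec = profile.continuous[name]
            lower = spec.get("lower")
            if lower is None:
                draws = rng.normal(spec["mean"], spec["sd"], size=n)
            else:
                mu, sigma = truncated_normal_params(spec["mean"], spec["sd"], lower)
                a = (lower - mu) / sigma
                draws = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)
            if spec.get("integer"):
                draws = np.rint(draws)
            cols[name] = draws
        elif name in profile.count:
            spec = profile.count[name]
            mean = spec["mean"]
            alpha = _negbin_from_moments(mean, spec["sd"])
            if alpha is None:
                cols[name] = rng.poisson(mean, size=n).astype(float)
            else:
                r = 1.0 / alpha
                p = r / (r + mean)
                cols[name] = rng.negative_binomial(r, p, size=n).astype(float)

    data = pd.DataFrame(cols)[[v.name for v in schema if v.name in cols]]
    if profile.dependence is not None:
        data = profile.dependence(data, rng)
    if profile.cluster_rate > 0:
        data["cluster_id"] = _draw_clusters(n, profile.cluster_rate, rng)
    sub = schema.subset([v.name for v in schema if v.name in data.columns])
    return HarmonizedTable(data=data, schema=sub)


def _draw_clusters(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    ids = np.empty(n, dtype=int)
    next_id = 0
    for i in range(n):
        if i > 0 and rng.random() < rate:
            ids[i] = ids[rng.integers(i)]
        else:
            ids[i] = next_id
            next_id += 1
    return ids


def generate_outcome(
    covariates: HarmonizedTable,
    model: OutcomeModel,
    seed: int | np.random.SeedSequence,
) -> pd.Series:
    """Draw the outcome column implied by ``model`` given the covariates."""
    X = design_matrix(covariates.data, model.predictors, covariates.schema)
    unknown = set(model.beta) - set(X.columns)
    if unknown:
        raise ModelError(f"beta names {sorted(unknown)} not in design columns {list(X.columns)}")
    beta = np.array([model.beta.get(c, 0.0) for c in X.columns])
    eta = X.to_numpy() @ beta
    for col, g in model.gamma.items():
        if col not in covariates.data.columns:
            raise ModelError(f"cluster covariate {col!r} missing from data")
        eta = eta + g * pd.to_numeric(covariates.data[col]).to_numpy()

    rng = np.random.default_rng(seed)
    if model.family == "gaussian":
        values = eta + rng.normal(0.0, math.sqrt(model.sigma2), size=len(eta))
        return pd.Series(values, index=covariates.data.index, name=model.outcome)
    if model.family == "bernoulli":
        p = 1.0 / (1.0 + np.exp(-eta))
        draws = rng.random(len(eta)) < p
        labels = np.where(draws, "yes", "no")
        return pd.Series(labels, index=covariates.data.index, name=model.outcome, dtype=object)
    mu = np.exp(eta)
    r = 1.0 / model.dispersion
    p = r / (r + mu)
    values = rng.negative_binomial(r, p).astype(float)
    return pd.Series(values, index=covariates.data.index, name=model.outcome)


def make_fusion_scenario(
    scenario: FusionScenario,
) -> tuple[HarmonizedTable, HarmonizedTable, dict]:
    """Build recipient A (outcome fully masked) and donor B (fully observed).

    Returns ``(A, B, truth)`` where ``truth`` records the masked outcome
    values and the generative parameters for recovery testing.
    """
    ss = np.random.SeedSequence(scenario.seed)
    seed_cov_a, seed_cov_b, seed_out_a, seed_out_b = ss.spawn(4)
    model = scenario.shared_outcome

    def build(profile, n, seed_cov, seed_out):
        cov = generate_covariates(profile, n, seed_cov)
        schema = Schema(list(cov.schema) + [model.schema_variable])
        data = cov.data.copy()
        if n > 0:
            data[model.outcome] = generate_outcome(cov, model, seed_out)
        else:
            data[model.outcome] = pd.Series(dtype=object if model.family == "bernoulli" else float)
        return HarmonizedTable(data=data, schema=schema)

    A = build(scenario.profile_A, scenario.n_A, seed_cov_a, seed_out_a)
    B = build(scenario.profile_B, scenario.n_B, seed_cov_b, seed_out_b)

    truth = {
        "target": model.outcome,
        "family": model.family,
        "predictors": list(model.predictors),
        "beta": dict(model.beta),
        "gamma": dict(model.gamma),
        "sigma2": model.sigma2,
        "dispersion": model.dispersion,
        "seed": scenario.seed,
        "masked_values": A.data[model.outcome].tolist(),
    }
    A.data[model.outcome] = pd.Series(
        [None] * len(A), index=A.data.index, dtype=object if model.family == "bernoulli" else float
    )
    A.mask[model.outcome] = False
    A.source_label = pd.Series(["A"] * len(A), index=A.data.index)
    B.source_label = pd.Series(["B"] * len(B), index=B.data.index)
    return A, B, truth
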