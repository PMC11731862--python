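"""End-to-end orchestration: generate/load -> mask -> fuse -> fit -> pool -> report.

A pipeline run is fully described by its config (YAML or dict); the manifest
written next to the outputs re-runs the pipeline bit-identically.
"""

from __future__ import annotations

import json
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .fusion import FusionSpec, fuse, mask_variable
from .harmonization import default_schema
from .inference import FITTERS, pool_rubin
from .mice import plot_traces
from .reporting import build_comparison, concordance
from .schema import HarmonizedTable, Schema
from .synthetic import (
    OutcomeModel,
    builtin_profile,
    generate_covariates,
    generate_outcome,
    load_profiles,
)

ALL_VARIABLES = [
    "sv_type",
    "perpetrator",
    "health_impact",
    "gender",
    "relationship_status",
    "ethnicity",
    "employment",
    "tenure",
    "dependants",
    "age",
]

# Comparison-vector configurations used in the published validation exercises.
COMPARISON_VECTORS = {
    "age": [v for v in ALL_VARIABLES if v != "age"],
    "gender": [v for v in ALL_VARIABLES if v != "gender"],
    "health_impact": [v for v in ALL_VARIABLES if v != "health_impact"],
    "frequency": list(ALL_VARIABLES),
}

# Published count-model coefficients, reused as generator inputs for the
# donor-only count target exercise.
FREQUENCY_MODEL = {
    "outcome": "frequency",
    "family": "count_negbin",
    "predictors": ALL_VARIABLES,
    "beta": {
        "Intercept": 1.135,
        "sv_type[rape]": -0.585,
        "perpetrator[acquaintance]": -1.560,
        "perpetrator[stranger_unknown]": -2.764,
        "gender[male]": -0.539,
        "health_impact[injury]": 0.313,
        "relationship_status[single_widowed]": -0.531,
        "relationship_status[separated_divorced]": 0.046,
        "ethnicity[non_white]": -0.869,
        "employment[unemployed]": 0.129,
        "employment[outside_labour_force]": 0.148,
        "employment[student]": 0.593,
        "tenure[renter]": 0.086,
        "tenure[other]": 0.083,
        "dependants": -0.041,
        "age": 0.017,
    },
    "dispersion": 8.723,  # exp(2.166)
}


def replication_config(
    target: str = "age",
    seed: int = 0,
    n_A: int = 6102,
    n_B: int = 1232,
    m: int = 10,
    T: int = 5,
    direction_swapped: bool = False,
) -> dict:
    """Config for one of the four built-in validation exercises."""
    if target not in COMPARISON_VECTORS:
        raise SchemaError(f"unknown replication target {target!r}")
    family = {"age": "ols", "gender": "logistic", "health_impact": "logistic", "frequency": "negbin"}[target]
    config = {
        "data": {
            "mode": "synthetic",
            "profile_A": "rcew",
            "profile_B": "csew",
            "n_A": n_A,
            "n_B": n_B,
        },
        "target": target,
        "family": family,
        "comparison_vector": COMPARISON_VECTORS[target],
        "m": m,
        "T": T,
        "seed": seed,
        "direction_swapped": direction_swapped,
    }
    if target == "frequency":
        config["outcome_model"] = dict(FREQUENCY_MODEL)
        config["fit_A"] = False
    return config


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def _profile(name: str, profile_file: str | None):
    if profile_file:
        return load_profiles(profile_file)[name]
    return builtin_profile(name)


def _build_outcome_model(doc: Mapping) -> OutcomeModel:
    return OutcomeModel(
        outcome=doc["outcome"],
        family=doc["family"],
        predictors=list(doc["predictors"]),
        beta=dict(doc["beta"]),
        gamma=dict(doc.get("gamma", {})),
        sigma2=float(doc.get("sigma2", 1.0)),
        dispersion=float(doc.get("dispersion", 1.0)),
    )


def run_pipeline(config, out_dir: str | Path) -> Path:
    """Execute a full fusion-and-validation run; returns the output directory."""
    config = _load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    data_cfg = dict(config["data"])
    target = config["target"]
    family = config["family"]
    cv = list(config["comparison_vector"])
    if target in cv:
        raise SchemaError("target cannot be part of the comparison vector")
    m = int(config.get("m", 10))
    T = int(config.get("T", 10))
    seed = config.get("seed", 0)
    swapped = bool(config.get("direction_swapped", False))
    fit_A = bool(config.get("fit_A", True))
    outcome_model = (
        _build_outcome_model(config["outcome_model"]) if config.get("outcome_model") else None
    )

    ss = np.random.SeedSequence(seed)
    s_cov_a, s_cov_b, s_out_a, s_out_b, s_fuse = ss.spawn(5)

    mode = data_cfg.get("mode", "synthetic")
    if mode == "synthetic":
        name_a, name_b = data_cfg["profile_A"], data_cfg["profile_B"]
        n_a, n_b = int(data_cfg["n_A"]), int(data_cfg["n_B"])
        if swapped:
            name_a, name_b = name_b, name_a
            n_a, n_b = n_b, n_a
        prof_a = _profile(name_a, data_cfg.get("profile_file"))
        prof_b = _profile(name_b, data_cfg.get("profile_file"))
        A = generate_covariates(prof_a, n_a, s_cov_a)
        B = generate_covariates(prof_b, n_b, s_cov_b)
        log.append(f"generated recipient from profile {name_a!r} (n={n_a})")
        log.append(f"generated donor from profile {name_b!r} (n={n_b})")
    elif mode == "files":
        A = HarmonizedTable.read(data_cfg["recipient_prefix"])
        B = HarmonizedTable.read(data_cfg["donor_prefix"])
        if swapped:
            A, B = B, A
        log.append(f"loaded recipient ({len(A)}) and donor ({len(B)}) from files")
    else:
        raise SchemaError(f"unknown data mode {mode!r}")

    if outcome_model is not None:
        # donor-only target generated from the shared model in both tables
        for tab, s_out in ((A, s_out_a), (B, s_out_b)):
            tab.data[outcome_model.outcome] = generate_outcome(tab, outcome_model, s_out)
            tab.mask[outcome_model.outcome] = True
            new_var = outcome_model.schema_variable
            if new_var.name not in tab.schema:
                tab.schema = Schema(list(tab.schema) + [new_var])
        log.append(f"generated shared outcome {outcome_model.outcome!r} ({outcome_model.family})")

    fitter = FITTERS[family]
    res_A = fitter(A, target, cv) if fit_A else None
    res_B = fitter(B, target, cv)
    log.append(f"fitted {family} on donor (n={res_B.n})"
               + (f" and recipient original (n={res_A.n})" if res_A else ""))

    A_masked, truth_col = mask_variable(A, target)
    spec = FusionSpec(
        targets=[target],
        comparison_vector=cv,
        m=m,
        T=T,
        seed=int(s_fuse.generate_state(1)[0]),
        direction_swapped=swapped,
    )
    fused = fuse(A_masked, B, spec)
    log.append(f"fused {m} imputations over {fused.n} recipient rows (T={T})")

    per_imp = [fitter(df, target, cv, fused.schema) for df in fused.datasets]
    pooled = pool_rubin(per_imp)
    log.append("pooled per-imputation fits by Rubin's rules")

    truth_beta = dict(outcome_model.beta) if outcome_model is not None else None
    table = build_comparison(res_A, res_B, pooled, schema=fused.schema)
    report = concordance(res_B, pooled, truth=truth_beta)

    # ------------------------------------------------------------- artifacts
    if res_A is not None:
        res_A.to_json(out_dir / "a_original.json")
    res_B.to_json(out_dir / "b_donor.json")
    pooled.to_json(out_dir / "pooled_synthetic.json")
    table.to_csv(out_dir / "comparison.csv")
    (out_dir / "comparison.txt").write_text(table.render_text() + "\n")
    with open(out_dir / "concordance.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    with open(out_dir / "diagnostics.json", "w") as fh:
        json.dump(fused.imputed.diagnostics, fh, indent=2)
    truth_col.to_frame(target).to_csv(out_dir / "masked_truth.csv", index=False)
    if config.get("plots"):
        plot_traces(fused.imputed, out_dir / "traces.png")
    try:
        pkg_version = _pkg_version("lookalike")
    except Exception:  # pragma: no cover
        pkg_version = "unknown"
    manifest = {"config": config, "package_version": pkg_version}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    (out_dir / "log.txt").write_text("\n".join(log) + "\n")
    return out_dir


def run_pipeline_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> Path:
    """Re-run a pipeline from a previously written manifest."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    return run_pipeline(manifest["config"], out_dir)
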