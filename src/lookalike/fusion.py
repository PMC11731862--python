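"""Mass imputation of donor-only variables into a recipient dataset.

The recipient (A) and donor (B) are stacked on their shared comparison
vector; the target variables — observed only in the donor — form a block of
unit missingness in the recipient, which the chained-equations engine fills.
The fused result is the recipient's rows with imputed targets, one copy per
imputation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AlignmentError, ExtrapolationWarning, ModelError, SchemaError
from .mice import ConditionalModelSpec, ImputedSet, default_family, run_mice
from .schema import HarmonizedTable, Schema


@dataclass
class FusionSpec:
    """Configuration of one fusion run."""

    targets: list[str]
    comparison_vector: list[str]
    recipient: str = "A"
    donor: str = "B"
    m: int = 10
    T: int = 10
    seed: int | None = None
    direction_swapped: bool = False
    families: dict = field(default_factory=dict)
    pmm_k: int = 5

    def __post_init__(self):
        overlap = set(self.targets) & set(self.comparison_vector)
        if overlap:
            raise SchemaError(f"targets also listed in comparison vector: {sorted(overlap)}")
        if not self.targets:
            raise SchemaError("at least one target variable is required")


@dataclass
class FusedResult:
    """m synthetic copies of the recipient with imputed targets."""

    datasets: list[pd.DataFrame]
    n: int
    spec: FusionSpec
    schema: Schema
    imputed: ImputedSet

    def __post_init__(self):
        for df in self.datasets:
            if len(df) != self.n:
                raise ModelError("every fused dataset must have exactly n recipient rows")

    def write(self, outdir: str | Path) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for i, df in enumerate(self.datasets):
            df.to_csv(outdir / f"fused_{i:03d}.csv", index=False)
        manifest = {
            "n": self.n,
            "m": self.spec.m,
            "T": self.spec.T,
            "seed": self.spec.seed,
            "targets": list(self.spec.targets),
            "comparison_vector": list(self.spec.comparison_vector),
            "recipient": self.spec.recipient,
            "donor": self.spec.donor,
            "direction_swapped": self.spec.direction_swapped,
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        return outdir


def _check_alignment(A: HarmonizedTable, B: HarmonizedTable, names: list[str]) -> None:
    discordant = []
    for name in names:
        in_a, in_b = name in A.schema, name in B.schema
        if not (in_a and in_b):
            discordant.append(name)
            continue
        if A.schema[name] != B.schema[name]:
            discordant.append(name)
    if discordant:
        raise AlignmentError(f"schemas disagree on variables: {discordant}")


def stack_datasets(
    A: HarmonizedTable, B: HarmonizedTable, spec: FusionSpec
) -> HarmonizedTable:
    """Stack recipient on donor; targets masked in all recipient rows."""
    if len(B) == 0:
        raise ModelError("donor dataset is empty: no information to impute from")
    _check_alignment(A, B, list(spec.comparison_vector))
    for t in spec.targets:
        if t not in B.schema:
            raise AlignmentError(f"target {t!r} missing from donor schema")

    for name in spec.comparison_vector:
        for label, tab in ((spec.recipient, A), (spec.donor, B)):
            if tab.mask[name].sum() < len(tab):
                raise ModelError(
                    f"comparison-vector variable {name!r} has missing cells in dataset "
                    f"{label}; run complete-case selection first"
                )

    columns = list(spec.comparison_vector) + list(spec.targets)
    schema_vars = [B.schema[c] if c in B.schema else A.schema[c] for c in columns]
    schema = Schema(schema_vars)

    a_data = A.data.reindex(columns=columns).copy()
    b_data = B.data.reindex(columns=columns).copy()
    data = pd.concat([a_data, b_data], ignore_index=True)
    mask = pd.concat(
        [
            A.mask.reindex(columns=columns, fill_value=False),
            B.mask.reindex(columns=columns, fill_value=False),
        ],
        ignore_index=True,
    )
    n_A = len(A)
    for t in spec.targets:
        tcol = data.columns.get_loc(t)
        data.iloc[:n_A, tcol] = np.nan if not schema[t].is_categorical else None
        mask.iloc[:n_A, mask.columns.get_loc(t)] = False
        if mask.iloc[n_A:, mask.columns.get_loc(t)].sum() < len(B):
            raise ModelError(f"target {t!r} must be fully observed in the donor")
    data = data.where(mask)

    source = pd.Series(
        [spec.recipient] * n_A + [spec.donor] * len(B), index=data.index
    )
    return HarmonizedTable(data=data, schema=schema, mask=mask, source_label=source)


def mask_variable(
    table: HarmonizedTable, name: str
) -> tuple[HarmonizedTable, pd.Series]:
    """Return a copy with ``name`` fully masked, plus the pre-mask truth column."""
    if name not in table.schema:
        raise SchemaError(f"unknown variable {name!r}")
    truth = table.data[name].copy()
    out = table.copy()
    out.data[name] = (
        pd.Series([None] * len(out), index=out.data.index, dtype=object)
        if table.schema[name].is_categorical
        else np.nan
    )
    out.mask[name] = False
    return out, truth


def _donor_support_check(A: HarmonizedTable, B: HarmonizedTable, spec: FusionSpec) -> None:
    for name in spec.comparison_vector:
        var = A.schema[name]
        if not var.is_categorical:
            continue
        a_cats = set(A.data.loc[A.mask[name], name].dropna())
        b_cats = set(B.data.loc[B.mask[name], name].dropna())
        unsupported = sorted(a_cats - b_cats)
        if unsupported:
            warnings.warn(
                f"categories {unsupported} of {name!r} present in recipient but "
                "absent from donor; imputations extrapolate",
                ExtrapolationWarning,
                stacklevel=3,
            )


def fuse(A: HarmonizedTable, B: HarmonizedTable, spec: FusionSpec) -> FusedResult:
    """Impute the donor-only targets into the recipient.

    Stacks the datasets, runs chained-equations imputation with each target
    predicted from the comparison vector, and restricts every completed
    dataset to the recipient rows.
    """
    _donor_support_check(A, B, spec)
    stacked = stack_datasets(A, B, spec)
    specs = []
    for t in spec.targets:
        family = spec.families.get(t, default_family(stacked.schema[t].family))
        specs.append(
            ConditionalModelSpec(
                variable=t,
                family=family,
                predictors=tuple(spec.comparison_vector),
                pmm_k=spec.pmm_k,
            )
        )
    imputed = run_mice(stacked, specs, m=spec.m, T=spec.T, seed=spec.seed)
    n_A = len(A)
    datasets = [df.iloc[:n_A].reset_index(drop=True) for df in imputed.datasets]
    return FusedResult(datasets=datasets, n=n_A, spec=spec, schema=stacked.schema, imputed=imputed)
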