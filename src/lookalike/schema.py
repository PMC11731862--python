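"""Typed variable schemas and the masked rectangular table they describe.

A :class:`HarmonizedTable` couples a :class:`pandas.DataFrame` with a boolean
observedness mask of the same shape and a :class:`Schema` describing each
column (family, categories, reference level, role).  All downstream stages —
generation, imputation, fusion, regression — speak this type.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError

FAMILIES = ("binary", "categorical", "continuous", "count")
ROLES = ("comparison_vector", "target", "id", "cluster")


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of one harmonized variable.

    Parameters
    ----------
    name
        Column name, unique within a schema.
    family
        One of ``binary``, ``categorical``, ``continuous``, ``count``.
    categories
        Ordered category labels; the first is the reference level unless
        ``reference`` overrides it.  Empty for continuous/count variables.
    reference
        Reference category for dummy coding.
    role
        One of ``comparison_vector``, ``target``, ``id``, ``cluster``.
    """

    name: str
    family: str
    categories: tuple[str, ...] = ()
    reference: str | None = None
    role: str = "comparison_vector"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise SchemaError(f"unknown family {self.family!r} for variable {self.name!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.family == "binary" and len(self.categories) != 2:
            raise SchemaError(f"binary variable {self.name!r} must have exactly 2 categories")
        if self.family == "categorical" and len(self.categories) < 2:
            raise SchemaError(f"categorical variable {self.name!r} needs >= 2 categories")
        if self.family in ("continuous", "count") and self.categories:
            raise SchemaError(f"{self.family} variable {self.name!r} cannot carry categories")
        if self.categories:
            if len(set(self.categories)) != len(self.categories):
                raise SchemaError(f"duplicate categories in variable {self.name!r}")
            ref = self.reference if self.reference is not None else self.categories[0]
            if ref not in self.categories:
                raise SchemaError(
                    f"reference {ref!r} is not a category of variable {self.name!r}"
                )
            object.__setattr__(self, "reference", ref)

    @property
    def is_categorical(self) -> bool:
        return self.family in ("binary", "categorical")

    @property
    def nonreference(self) -> tuple[str, ...]:
        return tuple(c for c in self.categories if c != self.reference)


class Schema:
    """Ordered collection of :class:`VariableSchema` with name lookup."""

    def __init__(self, variables: Iterable[VariableSchema]):
        self._vars = list(variables)
        names = [v.name for v in self._vars]
        if len(set(names)) != len(names):
            raise SchemaError("variable names must be unique within a schema")
        self._by_name = {v.name: v for v in self._vars}

    def __iter__(self) -> Iterator[VariableSchema]:
        return iter(self._vars)

    def __len__(self) -> int:
        return len(self._vars)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> VariableSchema:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"unknown variable {name!r}") from None

    def __eq__(self, other) -> bool:
        return isinstance(other, Schema) and self._vars == other._vars

    @property
    def names(self) -> list[str]:
        return [v.name for v in self._vars]

    def subset(self, names: Sequence[str]) -> "Schema":
        return Schema([self[n] for n in names])

    def to_dict(self) -> list[dict]:
        return [
            {
                "name": v.name,
                "family": v.family,
                "categories": list(v.categories),
                "reference": v.reference,
                "role": v.role,
            }
            for v in self._vars
        ]

    @classmethod
    def from_dict(cls, entries: Sequence[Mapping]) -> "Schema":
        return cls(
            VariableSchema(
                name=e["name"],
                family=e["family"],
                categories=tuple(e.get("categories") or ()),
                reference=e.get("reference"),
                role=e.get("role", "comparison_vector"),
            )
            for e in entries
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Schema":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc["variables"] if "variables" in doc else doc)


@dataclass
class HarmonizedTable:
    """Rectangular data plus observedness mask plus schema.

    ``mask`` is boolean with True marking an observed cell; its index and
    columns mirror ``data`` for every schema variable present.
    """

    data: pd.DataFrame
    schema: Schema
    mask: pd.DataFrame = None
    source_label: pd.Series | None = None

    def __post_init__(self):
        if self.mask is None:
            self.mask = self.data.notna()
        if list(self.mask.columns) != list(self.data.columns):
            raise SchemaError("mask columns must equal data columns")
        if self.mask.shape != self.data.shape:
            raise SchemaError("mask shape must equal data shape")
        for var in self.schema:
            if var.name not in self.data.columns:
                raise SchemaError(f"schema variable {var.name!r} missing from data")
        self._validate_cells()

    def _validate_cells(self):
        for var in self.schema:
            if not var.is_categorical:
                continue
            col = self.data[var.name]
            observed = col[self.mask[var.name]]
            bad = set(observed.dropna()) - set(var.categories)
            if bad:
                raise SchemaError(
                    f"values {sorted(bad)!r} in {var.name!r} outside categories {var.categories}"
                )

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n(self) -> int:
        return len(self.data)

    def copy(self) -> "HarmonizedTable":
        return HarmonizedTable(
            data=self.data.copy(),
            schema=self.schema,
            mask=self.mask.copy(),
            source_label=None if self.source_label is None else self.source_label.copy(),
        )

    def observed_count(self, name: str) -> int:
        return int(self.mask[name].sum())

    def missing_variables(self) -> list[str]:
        return [v.name for v in self.schema if self.mask[v.name].sum() < len(self)]

    # ---------------------------------------------------------------- I/O

    def write(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.csv`` plus a JSON sidecar with schema and mask."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        csv_path = prefix.with_suffix(".csv")
        sidecar_path = prefix.with_suffix(".sidecar.json")
        self.data.to_csv(csv_path, index=False)
        sidecar = {
            "schema": self.schema.to_dict(),
            "mask": {c: self.mask[c].astype(bool).tolist() for c in self.mask.columns},
            "source_label": None
            if self.source_label is None
            else self.source_label.astype(str).tolist(),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh)
        return csv_path, sidecar_path

    @classmethod
    def read(cls, prefix: str | Path) -> "HarmonizedTable":
        prefix = Path(prefix)
        data = pd.read_csv(prefix.with_suffix(".csv"))
        with open(prefix.with_suffix(".sidecar.json")) as fh:
            sidecar = json.load(fh)
        schema = Schema.from_dict(sidecar["schema"])
        mask = pd.DataFrame(
            {c: np.asarray(v, dtype=bool) for c, v in sidecar["mask"].items()},
            index=data.index,
        )[data.columns]
        data = data.where(mask)
        source = sidecar.get("source_label")
        return cls(
            data=data,
            schema=schema,
            mask=mask,
            source_label=None if source is None else pd.Series(source, index=data.index),
        )


def empty_table(schema: Schema) -> HarmonizedTable:
    """Zero-row table carrying the full schema."""
    data = pd.DataFrame({v.name: pd.Series(dtype=object if v.is_categorical else float) for v in schema})
    return HarmonizedTable(data=data, schema=schema)
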