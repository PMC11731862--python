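"""Declarative recoding of heterogeneous source tables into a shared schema.

Source variables are mapped many-to-one onto harmonized categories through
:class:`RecodeRule` objects; conflicts between multiple raw codes on one
record are resolved through a stated priority order (closest relationship
first for perpetrators, most severe first for violence type).  Eligibility
filters (minimum age, excluded raw codes) and complete-case selection live
here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, SchemaError
from .schema import HarmonizedTable, Schema


class _Excluded:
    """Sentinel returned when every raw code on a record is a drop code."""

    def __repr__(self) -> str:  # pragma: no cover
        return "EXCLUDED"


EXCLUDED = _Excluded()


@dataclass(frozen=True)
class RecodeRule:
    """Many-to-one recode of one source column onto one harmonized variable."""

    target: str
    source: str
    mapping: Mapping[str, str]
    priority: tuple[str, ...] | None = None
    drop: frozenset = frozenset()
    delimiter: str = ";"

    def validate(self, schema: Schema) -> None:
        var = schema[self.target]
        if not var.is_categorical:
            raise SchemaError(f"recode rule targets non-categorical variable {self.target!r}")
        bad = set(self.mapping.values()) - set(var.categories)
        if bad:
            raise SchemaError(
                f"rule for {self.target!r} maps onto unknown categories {sorted(bad)}"
            )
        if self.priority is not None and sorted(self.priority) != sorted(var.categories):
            raise SchemaError(
                f"priority order for {self.target!r} must be a permutation of its categories"
            )


def recode_categorical(raw_codes: Sequence[str], rule: RecodeRule):
    """Map raw codes to a single harmonized category.

    Multiple codes mapping to different categories resolve to the category
    earliest in ``rule.priority``.  Returns :data:`EXCLUDED` when every code
    is a drop code.
    """
    if not raw_codes:
        raise SchemaError(f"no raw codes supplied for variable {rule.target!r}")
    hits: set[str] = set()
    for code in raw_codes:
        code = str(code).strip()
        if code in rule.drop:
            continue
        if code not in rule.mapping:
            raise SchemaError(f"unknown raw code {code!r} for variable {rule.target!r}")
        hits.add(rule.mapping[code])
    if not hits:
        return EXCLUDED
    if len(hits) == 1:
        return next(iter(hits))
    if rule.priority is None:
        raise SchemaError(
            f"codes {list(raw_codes)!r} map to {sorted(hits)} for {rule.target!r} "
            "but the rule has no priority order"
        )
    for cat in rule.priority:
        if cat in hits:
            return cat
    raise SchemaError(f"priority order for {rule.target!r} covers none of {sorted(hits)}")


def load_rules(path: str | Path | None = None) -> tuple[list[RecodeRule], dict]:
    """Load recode rules + filters from YAML; defaults to the packaged file."""
    if path is None:
        source = resources.files("lookalike.config") / "harmonization_default.yaml"
        doc = yaml.safe_load(source.read_text())
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    rules = [
        RecodeRule(
            target=r["target"],
            source=r.get("source", r["target"]),
            mapping={str(k): str(v) for k, v in r["mapping"].items()},
            priority=tuple(r["priority"]) if r.get("priority") else None,
            drop=frozenset(str(c) for c in r.get("drop", ())),
            delimiter=r.get("delimiter", ";"),
        )
        for r in doc.get("rules", [])
    ]
    return rules, doc.get("filters", {})


def harmonize_dataset(
    raw_table: pd.DataFrame,
    rules: Sequence[RecodeRule],
    schema: Schema,
    filters: Mapping | None = None,
) -> HarmonizedTable:
    """Recode a raw table onto ``schema``, applying drop codes and the age filter.

    Rows whose raw codes are all drop codes for any rule are excluded, as are
    rows failing the minimum-age filter.  Missing raw cells stay missing.
    The returned table carries an ``exclusions`` attribute with per-rule and
    age-filter drop counts.
    """
    filters = dict(filters or {})
    age_column = filters.get("age_column", "age")
    min_age = filters.get("min_age", 16)

    for rule in rules:
        rule.validate(schema)
        if rule.source not in raw_table.columns:
            raise SchemaError(f"source column {rule.source!r} missing from raw table")

    n = len(raw_table)
    out: dict[str, pd.Series] = {}
    drop_row = np.zeros(n, dtype=bool)
    exclusions: dict[str, int] = {}

    for rule in rules:
        raw = raw_table[rule.source]
        values = np.full(n, None, dtype=object)
        excluded_here = np.zeros(n, dtype=bool)
        for i, cell in enumerate(raw):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue  # stays missing
            codes = [c.strip() for c in str(cell).split(rule.delimiter) if c.strip()]
            cat = recode_categorical(codes, rule)
            if cat is EXCLUDED:
                excluded_here[i] = True
            else:
                values[i] = cat
        exclusions[rule.target] = int(excluded_here.sum())
        drop_row |= excluded_here
        out[rule.target] = pd.Series(values, index=raw_table.index, dtype=object)

    # passthrough for schema variables without a rule (continuous/count, or
    # columns already harmonized upstream)
    ruled = {r.target for r in rules}
    for var in schema:
        if var.name in ruled:
            continue
        if var.name not in raw_table.columns:
            raise SchemaError(f"schema variable {var.name!r} missing from raw table")
        col = raw_table[var.name]
        if var.is_categorical:
            out[var.name] = col.astype(object)
        else:
            try:
                out[var.name] = pd.to_numeric(col)
            except (ValueError, TypeError) as exc:
                raise ParseError(f"non-numeric value in {var.name!r}: {exc}") from exc

    # age eligibility filter
    if age_column in out and min_age is not None:
        age = out[age_column]
        underage = (age < min_age).fillna(False).to_numpy(dtype=bool)
        exclusions["age_filter"] = int((underage & ~drop_row).sum())
        drop_row |= underage

    data = pd.DataFrame(out)[schema.names]
    data = data.loc[~drop_row].reset_index(drop=True)
    table = HarmonizedTable(data=data, schema=schema)
    table.exclusions = exclusions
    return table


def select_complete_cases(table: HarmonizedTable, variables: Sequence[str]) -> HarmonizedTable:
    """Keep rows fully observed on ``variables``; order preserved.

    The returned table carries a ``dropped_per_variable`` attribute counting,
    for each listed variable, how many dropped rows were missing it.
    """
    for name in variables:
        if name not in table.schema:
            raise SchemaError(f"unknown variable {name!r}")
    if not len(variables):
        result = table.copy()
        result.dropped_per_variable = {}
        return result
    keep = table.mask[list(variables)].all(axis=1)
    dropped = {
        name: int((~table.mask[name] & ~keep).sum()) for name in variables
    }
    result = HarmonizedTable(
        data=table.data.loc[keep].reset_index(drop=True),
        schema=table.schema,
        mask=table.mask.loc[keep].reset_index(drop=True),
        source_label=None
        if table.source_label is None
        else table.source_label.loc[keep].reset_index(drop=True),
    )
    result.dropped_per_variable = dropped
    return result


def default_schema() -> Schema:
    """The packaged comparison-vector schema."""
    source = resources.files("lookalike.config") / "schema.yaml"
    return Schema.from_dict(yaml.safe_load(source.read_text())["variables"])
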