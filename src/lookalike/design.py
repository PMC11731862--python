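"""Reference-coded design matrices shared by the generator, imputer and regressions.

One coding convention everywhere: continuous/count predictors enter as-is,
binary/categorical predictors as one indicator per non-reference category,
named ``var[category]``, with an optional leading ``Intercept`` column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import SchemaError, SingularDesignError
from .schema import Schema

INTERCEPT = "Intercept"


def design_columns(predictors: list[str], schema: Schema, intercept: bool = True) -> list[str]:
    """Column names of the design matrix implied by ``predictors``."""
    cols = [INTERCEPT] if intercept else []
    for name in predictors:
        var = schema[name]
        if var.is_categorical:
            cols.extend(f"{name}[{cat}]" for cat in var.nonreference)
        else:
            cols.append(name)
    return cols


def design_matrix(
    data: pd.DataFrame,
    predictors: list[str],
    schema: Schema,
    intercept: bool = True,
) -> pd.DataFrame:
    """Build the numeric design matrix for ``predictors`` from ``data``."""
    parts: dict[str, np.ndarray] = {}
    if intercept:
        parts[INTERCEPT] = np.ones(len(data))
    for name in predictors:
        var = schema[name]
        if name not in data.columns:
            raise SchemaError(f"predictor {name!r} missing from data")
        col = data[name]
        if var.is_categorical:
            for cat in var.nonreference:
                parts[f"{name}[{cat}]"] = (col == cat).to_numpy(dtype=float)
        else:
            parts[name] = pd.to_numeric(col).to_numpy(dtype=float)
    return pd.DataFrame(parts, index=data.index)


def encode_binary(values: pd.Series, var) -> np.ndarray:
    """Encode a binary column as 0 (reference) / 1 (non-reference)."""
    return (values == var.nonreference[0]).to_numpy(dtype=float)


def decode_binary(draws: np.ndarray, var) -> np.ndarray:
    """Map 0/1 draws back to category labels."""
    return np.where(draws > 0.5, var.nonreference[0], var.reference)


def encode_categorical(values: pd.Series, var) -> np.ndarray:
    """Encode categories as integer codes in schema order."""
    codes = pd.Categorical(values, categories=list(var.categories)).codes
    return codes.astype(float)


def check_full_rank(X: pd.DataFrame) -> None:
    """Raise :class:`SingularDesignError` naming near-collinear columns."""
    arr = X.to_numpy(dtype=float)
    if arr.shape[0] == 0:
        raise SingularDesignError(X.columns, "empty design matrix")
    rank = np.linalg.matrix_rank(arr)
    if rank >= arr.shape[1]:
        return
    # identify columns whose removal restores full rank among the rest
    offenders = []
    for j, name in enumerate(X.columns):
        rest = np.delete(arr, j, axis=1)
        if np.linalg.matrix_rank(rest) == rank:
            offenders.append(name)
    raise SingularDesignError(offenders or list(X.columns))
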