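"""Three-column comparison tables and donor-vs-synthetic concordance metrics."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .design import INTERCEPT
from .errors import AlignmentError
from .schema import Schema

REL_DIFF_EPS = 1e-8

COLUMN_LABELS = ("A_original", "B_donor", "synthetic")


def _term_labels(term: str, schema: Schema | None) -> tuple[str, str]:
    """(group header, row label) for one design column."""
    if term == INTERCEPT:
        return "", "Constant"
    if "[" in term and term.endswith("]"):
        var, cat = term[:-1].split("[", 1)
        if schema is not None and var in schema:
            ref = schema[var].reference
            return f"{var} (Ref: {ref})", cat
        return var, cat
    return "", term


@dataclass
class ComparisonTable:
    """Estimate/(SE)/stars grid over the analysis columns.

    ``frame`` is tidy: one row per (term, column) with estimate, se, stars.
    """

    frame: pd.DataFrame
    footer: dict[str, int]
    columns: tuple[str, ...] = COLUMN_LABELS

    def cell(self, term: str, column: str) -> tuple[float, float, str]:
        row = self.frame[(self.frame["term"] == term) & (self.frame["column"] == column)]
        if row.empty:
            raise AlignmentError(f"no cell for ({term!r}, {column!r})")
        r = row.iloc[0]
        return float(r["estimate"]), float(r["se"]), str(r["stars"]) if r["stars"] else ""

    def render_text(self) -> str:
        lines = []
        width = 16
        header = f"{'':38s}" + "".join(f"{c:>{width + 4}s}" for c in self.columns)
        lines.append(header)
        lines.append("-" * len(header))
        last_group = None
        for term in self.frame["term"].unique():
            sub = self.frame[self.frame["term"] == term]
            group = sub.iloc[0]["group"]
            if group and group != last_group:
                lines.append(group)
            last_group = group or last_group
            label = sub.iloc[0]["label"]
            est_cells, se_cells = [], []
            for c in self.columns:
                row = sub[sub["column"] == c].iloc[0]
                est_cells.append(f"{row['estimate']:.3f}{row['stars']:<3s}".rjust(width + 4))
                se_cells.append(f"({row['se']:.3f})".rjust(width + 4))
            lines.append(f"  {label:36s}" + "".join(est_cells))
            lines.append(f"  {'':36s}" + "".join(se_cells))
        footer = "Observations (N)".ljust(38) + "".join(
            f"{self.footer[c]:>{width + 4}d}" for c in self.columns
        )
        lines.append("-" * len(header))
        lines.append(footer)
        lines.append("*** p<0.001, ** p<0.01, * p<0.05. SE in brackets.")
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> Path:
        out = self.frame.copy()
        out["n"] = out["column"].map(self.footer)
        out.to_csv(path, index=False)
        return Path(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ComparisonTable":
        frame = pd.read_csv(path, keep_default_na=False, na_values=[])
        frame["estimate"] = frame["estimate"].astype(float)
        frame["se"] = frame["se"].astype(float)
        footer = {
            c: int(frame.loc[frame["column"] == c, "n"].iloc[0])
            for c in frame["column"].unique()
        }
        columns = tuple(frame["column"].unique())
        return cls(frame=frame.drop(columns=["n"]), footer=footer, columns=columns)


def build_comparison(res_A, res_B, pooled_syn, schema: Schema | None = None) -> ComparisonTable:
    """Assemble the (A original, B donor, synthetic) comparison grid.

    ``res_A`` may be None when the target is genuinely unobserved in the
    recipient, yielding a two-column table.
    """
    sources = {}
    if res_A is not None:
        sources["A_original"] = res_A
    sources["B_donor"] = res_B
    sources["synthetic"] = pooled_syn

    ref = None
    for label, res in sources.items():
        names = list(res.coefficients.index)
        if ref is None:
            ref = names
        elif names != ref:
            raise AlignmentError(
                f"predictor set of column {label!r} differs from the others"
            )

    rows = []
    for term in ref:
        group, label = _term_labels(term, schema)
        for col, res in sources.items():
            rows.append(
                {
                    "group": group,
                    "term": term,
                    "label": label,
                    "column": col,
                    "estimate": float(res.coefficients[term]),
                    "se": float(res.standard_errors[term]),
                    "stars": str(res.stars[term]),
                }
            )
    frame = pd.DataFrame(rows)
    footer = {label: int(res.n) for label, res in sources.items()}
    return ComparisonTable(frame=frame, footer=footer, columns=tuple(sources))


@dataclass
class ConcordanceReport:
    """How closely the synthetic column mimics the donor column."""

    sign_agreement: float
    significance_agreement: float
    mean_abs_relative_diff: float
    flips: list[dict] = field(default_factory=list)
    bias: float | None = None
    rmse: float | None = None

    def __post_init__(self):
        assert 0.0 <= self.sign_agreement <= 1.0
        assert 0.0 <= self.significance_agreement <= 1.0

    def to_dict(self) -> dict:
        return {
            "sign_agreement": self.sign_agreement,
            "significance_agreement": self.significance_agreement,
            "mean_abs_relative_diff": self.mean_abs_relative_diff,
            "flips": self.flips,
            "bias": self.bias,
            "rmse": self.rmse,
        }


def concordance(res_B, pooled_syn, truth: Mapping[str, float] | None = None) -> ConcordanceReport:
    """Sign / significance agreement between donor and synthetic coefficients.

    ``truth`` maps design-column names to generative coefficients; when
    given, bias and RMSE of the synthetic estimates are reported too.
    """
    names = list(res_B.coefficients.index)
    if list(pooled_syn.coefficients.index) != names:
        raise AlignmentError("donor and synthetic coefficient names differ")

    b = res_B.coefficients.to_numpy(dtype=float)
    s = pooled_syn.coefficients.to_numpy(dtype=float)
    sign_agreement = float(np.mean(np.sign(b) == np.sign(s)))

    stars_b = res_B.stars
    stars_s = pooled_syn.stars
    matches = stars_b.to_numpy() == stars_s.to_numpy()
    significance_agreement = float(np.mean(matches))
    flips = [
        {"term": t, "donor": str(stars_b[t]), "synthetic": str(stars_s[t])}
        for t, ok in zip(names, matches)
        if not ok
    ]

    rel = np.abs(s - b) / np.maximum(np.abs(b), REL_DIFF_EPS)
    report = ConcordanceReport(
        sign_agreement=sign_agreement,
        significance_agreement=significance_agreement,
        mean_abs_relative_diff=float(np.mean(rel)),
        flips=flips,
    )
    if truth is not None:
        true_vec = np.array([float(truth.get(t, 0.0)) for t in names])
        err = s - true_vec
        report.bias = float(np.mean(err))
        report.rmse = float(np.sqrt(np.mean(err**2)))
    return report
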