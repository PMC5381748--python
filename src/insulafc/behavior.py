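"""Behavioral and demographic statistics: Elo expected scores, group-matching
tests on phenotype tables, and contingency-table chi-square tests."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .group import two_sample_t

__all__ = [
    "elo_expected",
    "chi_square_independence",
    "phenotype_summary",
]


def elo_expected(diff: float) -> float:
    """Expected score of the stronger player from an Elo rating difference.

    E(d) = 1 / (1 + 10^(-d/400)).  A 100-point advantage gives 64%, a
    200-point advantage 76% (to the nearest percent); E(d) + E(-d) = 1 and
    E(400) = 10/11 exactly.
    """
    diff = float(diff)
    if not np.isfinite(diff):
        raise ValueError(f"rating difference must be finite, got {diff}")
    return 1.0 / (1.0 + 10.0 ** (-diff / 400.0))


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    Expected counts come from the row/column margins; df = (r-1)(c-1).
    Rows or columns with a zero margin are dropped with a warning.  No
    continuity correction is applied.
    """
    if isinstance(table, pd.DataFrame):
        counts = table.to_numpy(dtype=float)
    else:
        counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError(f"contingency table must be at least 2x2, got shape {counts.shape}")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    if counts.sum() == 0:
        raise ValueError("degenerate table: total count is zero")
    row_ok = counts.sum(axis=1) > 0
    col_ok = counts.sum(axis=0) > 0
    if not (row_ok.all() and col_ok.all()):
        warnings.warn("dropping zero-margin rows/columns from contingency table",
                      stacklevel=2)
        counts = counts[np.ix_(row_ok, col_ok)]
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("degenerate table after dropping zero margins")
    chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(chi2), int(df), float(p)


_CONTINUOUS_VARS = ["at_hours_per_week", "elo_points", "ds_seconds"]


def phenotype_summary(records) -> dict:
    """Group summary (mean +/- SE) and matching tests for a phenotype table.

    ``records`` is a list of :class:`~insulafc.cohort.PhenotypeRecord` or a
    DataFrame with at least ``group`` and the continuous variables.  Returns
    a dict with a per-group summary DataFrame and a test table (pooled
    two-sample t per continuous variable; chi-square for ``game_type`` if
    present).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    if "group" not in df.columns:
        raise ValueError("phenotype table needs a 'group' column")
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    counts = df["group"].value_counts()
    if counts.min() < 2:
        raise ValueError("each group needs at least 2 records")

    variables = [v for v in _CONTINUOUS_VARS if v in df.columns]
    summary_rows = []
    for g in groups:
        sub = df[df["group"] == g]
        row = {"group": g, "n": len(sub)}
        for v in variables:
            vals = sub[v].to_numpy(dtype=float)
            row[f"{v}_mean"] = vals.mean()
            row[f"{v}_se"] = vals.std(ddof=1) / np.sqrt(len(vals))
        summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    test_rows = []
    a = df[df["group"] == groups[0]]
    b = df[df["group"] == groups[1]]
    for v in variables:
        res = two_sample_t(a[v], b[v], contrast=f"{v}: {groups[0]} vs {groups[1]}")
        test_rows.append({"variable": v, "test": "t", "statistic": res.t,
                          "df": res.df, "p": res.p})
    if "game_type" in df.columns:
        ct = pd.crosstab(df["group"], df["game_type"])
        chi2, dof, p = chi_square_independence(ct)
        test_rows.append({"variable": "game_type", "test": "chi2",
                          "statistic": chi2, "df": dof, "p": p})
    return {"summary": summary, "tests": pd.DataFrame(test_rows)}
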