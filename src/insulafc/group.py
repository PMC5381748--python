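"""Population-level inference: spatial-consistency maps, two-sample tests,
brain-behavior correlations, and edgewise FC comparisons.

Group comparisons of correlations operate on Fisher-z values, whose sampling
distribution is approximately normal, so the pooled two-sample t test
(df = n1 + n2 - 2) applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectivity import FcMatrix

__all__ = [
    "ConsistencyMap",
    "GroupTestResult",
    "CorrelationResult",
    "consistency_map",
    "two_sample_t",
    "pearson_with_p",
    "edgewise_group_test",
]


@dataclass
class ConsistencyMap:
    """Per-voxel percentage of subjects whose significance mask covers the voxel."""

    group: str
    roi_id: tuple[str, int]
    values: np.ndarray  # percentages in [0, 100]
    n_subjects: int


@dataclass(frozen=True)
class GroupTestResult:
    """Pooled-variance independent two-sample t test."""

    contrast: str
    t: float
    df: int
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    q: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with a t-based two-sided p value (df = n - 2)."""

    pair: str
    r: float
    n: int
    p: float


def consistency_map(masks, n_subjects: int, group: str = "", roi_id=("", 0)) -> ConsistencyMap:
    """Population spatial-consistency (probability) map.

    value = 100 * (number of subjects significant at the voxel) / n_subjects,
    e.g. 12 of 30 subjects -> 40%.
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if len(masks) != n_subjects:
        raise ValueError(f"{len(masks)} masks for n_subjects={n_subjects}")
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError(f"masks on mismatched grids: {sorted(shapes)}")
    counts = np.sum(masks, axis=0)
    return ConsistencyMap(
        group=group,
        roi_id=roi_id,
        values=100.0 * counts / n_subjects,
        n_subjects=n_subjects,
    )


def two_sample_t(values_a, values_b, contrast: str = "",
                 equal_var: bool = True) -> GroupTestResult:
    """Independent two-sample t test.

    Pooled variance by default (df = n1 + n2 - 2); ``equal_var=False``
    switches to Welch's test with Satterthwaite df (rounded down).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in group data")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0 and a.mean() == b.mean():
        # identical constant groups: define t = 0, p = 1 rather than 0/0
        return GroupTestResult(contrast, 0.0, a.size + b.size - 2, 1.0,
                               float(a.mean()), float(b.mean()), 0.0, 0.0,
                               a.size, b.size)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance: degenerate data")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2
    else:
        va, vb = np.var(a, ddof=1) / a.size, np.var(b, ddof=1) / b.size
        df = int((va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1)))
    return GroupTestResult(
        contrast=contrast,
        t=float(t),
        df=df,
        p=float(p),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        n_a=int(a.size),
        n_b=int(b.size),
    )


def pearson_with_p(x, y, pair: str = "") -> CorrelationResult:
    """Pearson r with p from t = r sqrt((n-2) / (1-r^2)) on df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    if x.size < 3:
        raise ValueError("need n >= 3 for a correlation p value")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(pair=pair, r=float(res.statistic), n=int(x.size),
                             p=float(res.pvalue))


def edgewise_group_test(fc_a: list[FcMatrix], fc_b: list[FcMatrix],
                        alpha: float = 0.05) -> pd.DataFrame:
    """Per-edge two-sample t on Fisher-z FC, BH-FDR corrected across edges.

    Returns one row per unordered ROI pair (190 edges for 20 ROIs) with the
    pooled t, p, BH-adjusted q, and a significance flag at ``alpha``.
    """
    if len(fc_a) < 2 or len(fc_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    roi_ids = fc_a[0].roi_ids
    for fc in (*fc_a, *fc_b):
        if fc.roi_ids != roi_ids:
            raise ValueError("FC matrices have inconsistent ROI ordering")
    za = np.array([fc.z for fc in fc_a])
    zb = np.array([fc.z for fc in fc_b])
    iu, ju = np.triu_indices(len(roi_ids), k=1)
    rows = []
    for i, j in zip(iu, ju):
        res = two_sample_t(za[:, i, j], zb[:, i, j],
                           contrast=f"{roi_ids[i][0]}{roi_ids[i][1]}-{roi_ids[j][0]}{roi_ids[j][1]}")
        rows.append({
            "roi_a": f"{roi_ids[i][0]}{roi_ids[i][1]}",
            "roi_b": f"{roi_ids[j][0]}{roi_ids[j][1]}",
            "t": res.t, "df": res.df, "p": res.p,
            "mean_z_a": res.mean_a, "mean_z_b": res.mean_b,
        })
    table = pd.DataFrame(rows)
    reject, qvals, *_ = multipletests(table["p"], alpha=alpha, method="fdr_bh")
    table["q"] = qvals
    table["significant"] = reject
    return table
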