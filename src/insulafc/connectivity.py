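"""Functional connectivity statistics: ROI pairwise FC, the anterior-posterior
insular integration score, voxel-wise seed maps, and significance thresholding.

The integration score is the Pearson correlation between the average signal
of the anterior ROIs {1, 2, 4, 5, 8} and the average signal of the posterior
ROIs {3, 7, 10} of one hemisphere; transitional ROIs {6, 9} are excluded.
Seed maps are partial correlations between the seed time course and every
voxel, controlling the nuisance regressors through a per-voxel GLM, then
thresholded with Benjamini-Hochberg FDR plus a cluster-extent rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .atlas import ANTERIOR_INDICES, POSTERIOR_INDICES, RoiDefinition, RoiSignalSet
from .grid import GridSpec

__all__ = [
    "FcMatrix",
    "IntegrationScore",
    "SeedMap",
    "ConnectivityError",
    "fisher_z",
    "pairwise_fc",
    "integration_score",
    "seed_map",
    "threshold_map",
]


class ConnectivityError(ValueError):
    """Degenerate input to a connectivity statistic (zero variance, missing ROI)."""


ROI_ORDER: tuple[tuple[str, int], ...] = tuple(
    (h, i) for h in ("L", "R") for i in range(1, 11)
)


def fisher_z(r) -> np.ndarray:
    """Variance-stabilizing Fisher transform z = atanh(r)."""
    return np.arctanh(r)


@dataclass
class FcMatrix:
    """20x20 ROI-by-ROI Pearson correlation matrix for one subject.

    ``r`` is exactly symmetric with unit diagonal; ``z`` holds Fisher-
    transformed off-diagonal values with NaN on the (undefined) diagonal.
    """

    subject_id: str
    roi_ids: tuple[tuple[str, int], ...]
    r: np.ndarray
    z: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.shape != (len(self.roi_ids),) * 2:
            raise ValueError(f"FC matrix shape {r.shape} does not match ROI list")
        if not np.array_equal(r, r.T):
            raise ValueError("FC matrix must be exactly symmetric")
        if not np.allclose(np.diag(r), 1.0):
            raise ValueError("FC matrix diagonal must be 1")
        off = ~np.eye(len(r), dtype=bool)
        if np.any(np.abs(r[off]) > 1):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        self.r = r
        z = np.full_like(r, np.nan)
        z[off] = np.arctanh(np.clip(r[off], -1 + 1e-15, 1 - 1e-15))
        self.z = z


@dataclass(frozen=True)
class IntegrationScore:
    """Anterior-posterior insular functional integration for one hemisphere."""

    subject_id: str
    hemisphere: str
    r_value: float
    z_value: float


@dataclass
class SeedMap:
    """Voxel-wise seed connectivity for one (subject, ROI) pair.

    ``r_map``/``p_map`` are partial correlation and two-sided p volumes;
    ``seed_mask`` marks the seed's own voxels, which are excluded from
    thresholding and network statistics; ``sig_mask`` is filled in by
    :func:`threshold_map`.
    """

    subject_id: str
    roi_id: tuple[str, int]
    r_map: np.ndarray
    p_map: np.ndarray
    df: int
    seed_mask: np.ndarray
    sig_mask: np.ndarray | None = None


def pairwise_fc(signals: RoiSignalSet) -> FcMatrix:
    """Pearson correlation between every pair of ROI mean time courses."""
    missing = [rid for rid in ROI_ORDER if rid not in signals.signals]
    if missing:
        raise ConnectivityError(f"signal set missing ROIs {missing}")
    x = np.array([signals.signals[rid] for rid in ROI_ORDER])
    if x.shape[1] < 3:
        raise ConnectivityError("need at least 3 time points for correlation")
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = [ROI_ORDER[i] for i in np.flatnonzero(sd == 0)]
        raise ConnectivityError(f"zero-variance signal for ROIs {bad}")
    r = np.corrcoef(x)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return FcMatrix(subject_id=signals.subject_id, roi_ids=ROI_ORDER, r=r)


def integration_score(signals: RoiSignalSet, hemisphere: str) -> IntegrationScore:
    """Correlation of the averaged anterior signal with the averaged posterior signal."""
    if hemisphere not in ("L", "R"):
        raise ValueError(f"hemisphere must be 'L' or 'R', got {hemisphere!r}")
    needed = [(hemisphere, i) for i in (*ANTERIOR_INDICES, *POSTERIOR_INDICES)]
    missing = [rid for rid in needed if rid not in signals.signals]
    if missing:
        raise ConnectivityError(f"incomplete atlas: missing ROIs {missing}")
    ant = signals.mean_signal([(hemisphere, i) for i in ANTERIOR_INDICES])
    post = signals.mean_signal([(hemisphere, i) for i in POSTERIOR_INDICES])
    if ant.std() == 0 or post.std() == 0:
        raise ConnectivityError("zero-variance averaged signal")
    r = float(np.corrcoef(ant, post)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    return IntegrationScore(
        subject_id=signals.subject_id,
        hemisphere=hemisphere,
        r_value=r,
        z_value=float(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))),
    )


def seed_map(run, seed_signal: np.ndarray, confounds, roi: RoiDefinition | None = None,
             brain_mask: np.ndarray | None = None) -> SeedMap:
    """Partial correlation between a seed time course and every voxel.

    Fits, per voxel, the GLM  y = b0 + b_s * seed + B * confounds + e  and
    converts the seed coefficient's t statistic into a partial correlation
    r = t / sqrt(t^2 + df) with df = T - p (p regressors including the
    intercept); two-sided p values come from the t distribution.  By the
    Frisch-Waugh theorem this equals correlating the seed and voxel series
    after residualizing both on the confounds.
    """
    import pandas as pd

    data = run.data
    dims = data.shape[:3]
    n_t = data.shape[3]
    seed_signal = np.asarray(seed_signal, dtype=float)
    if seed_signal.shape != (n_t,):
        raise ValueError(f"seed signal length {seed_signal.shape} != run length {n_t}")
    conf = confounds.to_numpy(dtype=float) if isinstance(confounds, pd.DataFrame) else np.asarray(confounds, dtype=float)
    if conf.ndim == 1:
        conf = conf[:, None]
    if conf.shape[0] != n_t:
        raise ValueError("confound rows do not align with run length")

    from .preprocess import _full_rank_columns

    design = np.column_stack([np.ones(n_t), seed_signal, conf])
    keep = _full_rank_columns(design)
    if 1 not in keep:
        raise ConnectivityError("seed signal is collinear with the nuisance regressors")
    design = design[:, keep]
    seed_col = keep.index(1)
    p = design.shape[1]
    df = n_t - p
    if df <= 0:
        raise ConnectivityError(f"not enough time points ({n_t}) for {p} regressors")

    y = data.reshape(-1, n_t).T  # T x V
    pinv = np.linalg.pinv(design)
    beta = pinv @ y
    resid = y - design @ beta
    sigma2 = np.einsum("tv,tv->v", resid, resid) / df
    xtx_inv = pinv @ pinv.T
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[seed_col, seed_col], 1e-300))
    t = beta[seed_col] / se
    r = t / np.sqrt(t**2 + df)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)

    r_map = r.reshape(dims)
    p_map = pvals.reshape(dims)
    seed_mask = np.zeros(dims, dtype=bool)
    if roi is not None:
        vox = np.array(roi.voxels)
        seed_mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        p_map = p_map.copy()
        p_map[seed_mask] = 1.0  # seed voxels never enter network statistics
        r_map = r_map.copy()
        r_map[seed_mask] = 0.0
    if brain_mask is not None:
        outside = ~np.asarray(brain_mask, dtype=bool)
        p_map = p_map.copy()
        p_map[outside] = 1.0
    return SeedMap(
        subject_id=run.subject_id,
        roi_id=roi.roi_id if roi is not None else ("", 0),
        r_map=r_map,
        p_map=p_map,
        df=df,
        seed_mask=seed_mask,
    )


_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


def threshold_map(p_map: np.ndarray, alpha: float = 0.05, k: int = 20,
                  connectivity_rule: int = 26, brain_mask: np.ndarray | None = None,
                  extent_op: str = ">") -> np.ndarray:
    """Benjamini-Hochberg FDR then cluster-extent filtering.

    BH step-up is applied over in-mask p values at level ``alpha``; connected
    components of the surviving voxels (neighborhood per
    ``connectivity_rule`` in {6, 18, 26}) are kept only if their size
    satisfies ``size > k`` (strict, the default) or ``size >= k``.
    """
    p_map = np.asarray(p_map, dtype=float)
    if np.any((p_map < 0) | (p_map > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if connectivity_rule not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity_rule must be one of {sorted(_CONNECTIVITY_RANK)}")
    if extent_op not in (">", ">="):
        raise ValueError("extent_op must be '>' or '>='")
    if brain_mask is None:
        brain_mask = np.ones(p_map.shape, dtype=bool)
    else:
        brain_mask = np.asarray(brain_mask, dtype=bool)
        if brain_mask.shape != p_map.shape:
            raise ValueError("brain mask shape does not match p map")
    if not brain_mask.any():
        raise ValueError("empty brain mask")

    rejected = np.zeros(p_map.shape, dtype=bool)
    in_mask = p_map[brain_mask]
    rejected[brain_mask] = multipletests(in_mask, alpha=alpha, method="fdr_bh")[0]

    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity_rule])
    labels, n_comp = ndimage.label(rejected, structure=structure)
    if n_comp == 0:
        return rejected
    sizes = np.bincount(labels.ravel())[1:]
    if extent_op == ">":
        keep = np.flatnonzero(sizes > k) + 1
    else:
        keep = np.flatnonzero(sizes >= k) + 1
    return np.isin(labels, keep)
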