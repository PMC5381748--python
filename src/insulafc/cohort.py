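"""Synthetic two-group resting-state cohort generator.

Emulates the statistical structure the downstream analysis assumes, on a
small synthetic grid rather than an anatomical template:

* two groups (default 27 "expert" / 30 "amateur" subjects) of 4D BOLD runs
  (default 255 volumes at TR = 2 s, 3 mm isotropic voxels);
* an anterior (attentional, "A") and a posterior (sensorimotor, "P")
  latent network signal per subject, band-limited to 0.01-0.08 Hz,
  correlated at the subject's planted anterior-posterior coupling rho;
* signal sites at the 20 insular ROIs (anterior ROIs follow the A latent,
  posterior ROIs the P latent, transitional ROIs an equal mixture) and at
  extra-insular A-/P-network nodes;
* per-subject coupling drawn around the group value (rho_ap_expert /
  rho_ap_amateur) with spread rho_sd, returned as ground truth;
* voxel-wise AR(1) noise plus low-frequency drift, and additive leakage of
  the 15 nuisance regressors (6 motion + 9 physiological) with random
  per-voxel loadings, so band-pass filtering and nuisance regression have
  real work to do;
* phenotypes calibrated to the study groups: weekly play time (AT) coupled
  to the planted rho in experts only, Elo ratings (experts 1900-2600,
  amateurs uniform below 1200), a reaction-game score, and optional
  grey-matter volumes with a planted left-hemisphere effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from . import atlas as atlas_mod
from .grid import GridSpec

__all__ = [
    "MOTION_COLUMNS",
    "PHYSIO_COLUMNS",
    "CONFOUND_COLUMNS",
    "GMV_SUBREGIONS",
    "CohortConfigError",
    "PhenotypeRecord",
    "BOLDRun",
    "ConfoundTable",
    "CohortConfig",
    "Cohort",
    "default_network_nodes",
    "generate_cohort",
    "write_cohort",
]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
PHYSIO_COLUMNS = [f"physio_{i}" for i in range(1, 10)]
CONFOUND_COLUMNS = MOTION_COLUMNS + PHYSIO_COLUMNS

#: insular subregion names used for tabular grey-matter volumes
GMV_SUBREGIONS = [
    "short_insular_gyri",
    "circular_sulcus_anterior",
    "long_insular_gyrus_central_sulcus",
    "circular_sulcus_superior",
    "circular_sulcus_inferior",
]

# Group phenotype calibration: AT and reaction-game values reproduce the
# study groups' mean +/- SE (SE * sqrt(n) = SD); Elo ranges follow the
# stated expert range, with amateurs uniform below 1200.
_PHENO_CAL = {
    "expert": {"n_ref": 27, "at_mean": 46.67, "at_se": 2.1,
               "ds_mean": 25.2, "ds_se": 3.2, "elo": (1900.0, 2600.0)},
    "amateur": {"n_ref": 30, "at_mean": 14.2, "at_se": 1.1,
                "ds_mean": 15.4, "ds_se": 3.5, "elo": (800.0, 1200.0)},
}
_GAME_TYPE_P = {"expert": {"AVG": 1.0}, "amateur": {"AVG": 14 / 30, "RPG": 4 / 30, "Both": 12 / 30}}


class CohortConfigError(ValueError):
    """Invalid cohort configuration (ranges, covariance, or node placement)."""


@dataclass
class PhenotypeRecord:
    subject_id: str
    group: str  # "expert" | "amateur"
    at_hours_per_week: float
    elo_points: float
    ds_seconds: float
    game_type: str = "AVG"
    gmv_mm3: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.group not in ("expert", "amateur"):
            raise ValueError(f"group must be expert/amateur, got {self.group!r}")
        if not np.isfinite(self.at_hours_per_week) or self.at_hours_per_week < 0:
            raise ValueError("at_hours_per_week must be finite and nonnegative")


@dataclass
class BOLDRun:
    """One subject's 4D time series on a fixed grid."""

    subject_id: str
    data: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape != self.grid.shape4d:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape4d}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in run {self.subject_id}")


@dataclass
class ConfoundTable:
    """15 nuisance time series (6 motion + 9 physiological) for one run."""

    subject_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.data.columns) != CONFOUND_COLUMNS:
            raise ValueError(
                f"confound table must have exactly the 15 columns {CONFOUND_COLUMNS}"
            )
        if self.data.isna().any().any():
            raise ValueError(f"missing values in confound table {self.subject_id}")


def default_network_nodes() -> pd.DataFrame:
    """Extra-insular A-/P-network node centers (synthetic layout, mm)."""
    rows = [
        ("A_frontal_L", "A", -18.0, 12.0, 9.0),
        ("A_frontal_R", "A", 18.0, 12.0, 9.0),
        ("A_parietal_L", "A", -18.0, 12.0, -9.0),
        ("A_parietal_R", "A", 18.0, 12.0, -9.0),
        ("P_sensorimotor_L", "P", -18.0, -12.0, 9.0),
        ("P_sensorimotor_R", "P", 18.0, -12.0, 9.0),
        ("P_temporal_L", "P", -18.0, -12.0, -9.0),
        ("P_temporal_R", "P", 18.0, -12.0, -9.0),
    ]
    return pd.DataFrame(rows, columns=["label", "network", "x_mm", "y_mm", "z_mm"])


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    rho_ap_expert / rho_ap_amateur are the group-level planted
    anterior-posterior couplings; each subject's own coupling is drawn
    N(group rho, rho_sd^2), truncated to (-0.95, 0.95), and returned as
    ground truth.  rho_within is the coupling of each node's latent to its
    network latent.  at_effect is the slope (hours/week per unit rho)
    linking a subject's planted coupling to simulated weekly play time in
    the expert group only.
    """

    n_expert: int = 27
    n_amateur: int = 30
    grid: GridSpec = field(default_factory=GridSpec)
    roi_table: pd.DataFrame = field(default_factory=atlas_mod.default_roi_table)
    network_nodes: pd.DataFrame = field(default_factory=default_network_nodes)
    rho_within: float = 0.9
    rho_ap_expert: float = 0.6
    rho_ap_amateur: float = 0.3
    rho_sd: float = 0.12
    confound_sd: float = 0.3
    noise_sd: float = 1.0
    ar_phi: float = 0.3
    drift_sd: float = 1.0
    at_effect: float = 40.0
    signal_band_hz: tuple[float, float] = (0.01, 0.08)
    include_gmv: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_expert < 0 or self.n_amateur < 0:
            raise CohortConfigError("group sizes must be nonnegative")
        if not 0 <= self.rho_within < 1:
            raise CohortConfigError(f"rho_within must lie in [0, 1), got {self.rho_within}")
        for name in ("rho_ap_expert", "rho_ap_amateur"):
            v = getattr(self, name)
            if not -1 < v < 1:
                raise CohortConfigError(f"{name} must lie in (-1, 1), got {v}")
        if self.rho_sd < 0 or self.confound_sd < 0 or self.drift_sd < 0:
            raise CohortConfigError("spread parameters must be nonnegative")
        if self.noise_sd <= 0:
            raise CohortConfigError("noise_sd must be positive")
        if not 0 <= self.ar_phi < 1:
            raise CohortConfigError("ar_phi must lie in [0, 1)")
        if self.grid.n_volumes < 20:
            raise CohortConfigError(
                f"simulated runs need >= 20 volumes, got {self.grid.n_volumes}"
            )
        for group, rho in (("expert", self.rho_ap_expert), ("amateur", self.rho_ap_amateur)):
            cov = self.latent_covariance(rho)
            eigmin = float(np.linalg.eigvalsh(cov).min())
            if eigmin < -1e-10:
                raise CohortConfigError(
                    f"latent covariance for the {group} anterior-posterior block is not "
                    f"positive semi-definite (min eigenvalue {eigmin:.3g})"
                )

    @property
    def n_subjects(self) -> int:
        return self.n_expert + self.n_amateur

    def latent_covariance(self, rho_ap: float) -> np.ndarray:
        """Implied covariance of the insular node latents (anterior block
        first, then posterior): within-network covariance rho_within, cross
        covariance rho_within * rho_ap, unit variances."""
        m_a, m_p = len(atlas_mod.ANTERIOR_INDICES), len(atlas_mod.POSTERIOR_INDICES)
        w = self.rho_within
        cov = np.empty((m_a + m_p, m_a + m_p))
        cov[:m_a, :m_a] = w
        cov[m_a:, m_a:] = w
        cov[:m_a, m_a:] = cov[m_a:, :m_a] = w * rho_ap
        np.fill_diagonal(cov, 1.0)
        return cov

    def implied_integration(self, rho_ap: float) -> float:
        """Population correlation between the averaged anterior and averaged
        posterior ROI signals implied by the latent model (noiseless limit)."""
        m_a, m_p = len(atlas_mod.ANTERIOR_INDICES), len(atlas_mod.POSTERIOR_INDICES)
        w = self.rho_within
        var_a = (1 + (m_a - 1) * w) / m_a
        var_p = (1 + (m_p - 1) * w) / m_p
        return w * rho_ap / np.sqrt(var_a * var_p)


@dataclass
class Cohort:
    """Generated cohort bundle: runs, confounds, phenotypes, ground truth."""

    runs: list[BOLDRun]
    confounds: list[ConfoundTable]
    phenotypes: list[PhenotypeRecord]
    ground_truth: pd.DataFrame
    config: CohortConfig

    def __iter__(self):
        return iter((self.runs, self.confounds, self.phenotypes, self.ground_truth))


def _band_limited_noise(rng: np.random.Generator, shape: tuple, sos: np.ndarray) -> np.ndarray:
    """White noise band-pass filtered along the last axis, standardized per row."""
    x = sp_signal.sosfiltfilt(sos, rng.standard_normal(shape), axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _make_confounds(rng: np.random.Generator, n_t: int) -> pd.DataFrame:
    """6 slow random-walk motion parameters + 9 AR(1) physiological series."""
    motion = np.cumsum(rng.normal(0.0, [0.02] * 3 + [0.005] * 3, size=(n_t, 6)), axis=0)
    white = rng.standard_normal((9, n_t))
    physio = sp_signal.lfilter([1.0], [1.0, -0.5], white, axis=-1).T
    return pd.DataFrame(np.column_stack([motion, physio]), columns=CONFOUND_COLUMNS)


def _signal_sites(config: CohortConfig) -> list[tuple[str, np.ndarray]]:
    """(latent kind, voxel array) per signal site; kinds 'A', 'P', 'M' (mixed)."""
    rois = atlas_mod.build_atlas(config.roi_table, config.grid)
    kind_of = {"anterior": "A", "posterior": "P", "transitional": "M"}
    sites = [(kind_of[roi.subregion], np.array(roi.voxels)) for roi in rois]
    grid = config.grid
    for row in config.network_nodes.itertuples(index=False):
        if row.network not in ("A", "P"):
            raise CohortConfigError(f"network node {row.label!r} must be in network A or P")
        center = grid.mm_to_voxel([row.x_mm, row.y_mm, row.z_mm])
        voxels = atlas_mod._ball_voxels(np.asarray(center))
        if not grid.in_bounds(voxels):
            raise CohortConfigError(f"network node {row.label!r} leaves the grid")
        sites.append((row.network, voxels))
    return sites


def _draw_latents(rng: np.random.Generator, rho: float, n_t: int, sos) -> dict[str, np.ndarray]:
    """Anterior/posterior network latents correlated at rho, plus their mixture."""
    x = _band_limited_noise(rng, (2, n_t), sos)
    lat_a = x[0]
    lat_p = rho * x[0] + np.sqrt(1.0 - rho**2) * x[1]
    lat_m = (lat_a + lat_p) / np.sqrt(2.0 * (1.0 + rho))
    return {"A": lat_a, "P": lat_p, "M": lat_m}


def _subject_run(rng: np.random.Generator, subject_id: str, rho: float,
                 config: CohortConfig, sites, sos) -> tuple[BOLDRun, ConfoundTable]:
    grid = config.grid
    n_t = grid.n_volumes
    n_v = grid.n_voxels

    latents = _draw_latents(rng, rho, n_t, sos)

    # AR(1) voxel noise with unit marginal variance, scaled to noise_sd
    white = rng.standard_normal((n_v, n_t))
    noise = sp_signal.lfilter([1.0], [1.0, -config.ar_phi], white, axis=-1)
    data = noise * (config.noise_sd * np.sqrt(1.0 - config.ar_phi**2))

    # low-frequency drift: linear trend + slow cosine, random per-voxel amplitude
    t = np.arange(n_t)
    lin = (t - t.mean()) / n_t
    period_s = 160.0  # 0.00625 Hz, below the pass band
    cos = np.cos(2 * np.pi * grid.tr_seconds * t / period_s + rng.uniform(0, 2 * np.pi))
    data += config.drift_sd * (
        rng.standard_normal((n_v, 1)) * lin + rng.standard_normal((n_v, 1)) * cos
    )

    # confound leakage with random per-voxel loadings
    conf = _make_confounds(rng, n_t)
    conf_std = (conf - conf.mean()) / conf.std(ddof=0)
    data += (rng.normal(0.0, config.confound_sd, size=(n_v, 15))
             @ conf_std.to_numpy().T)

    # plant the network node signals
    data = data.reshape(*grid.dims, n_t)
    w = config.rho_within
    for kind, voxels in sites:
        u = np.sqrt(w) * latents[kind] + np.sqrt(1.0 - w) * _band_limited_noise(rng, (n_t,), sos)
        data[voxels[:, 0], voxels[:, 1], voxels[:, 2], :] += u

    run = BOLDRun(subject_id=subject_id, data=data.astype(np.float32), grid=grid)
    return run, ConfoundTable(subject_id=subject_id, data=conf)


def _phenotype(rng: np.random.Generator, subject_id: str, group: str, rho: float,
               config: CohortConfig) -> PhenotypeRecord:
    cal = _PHENO_CAL[group]
    at_sd = cal["at_se"] * np.sqrt(cal["n_ref"])
    if group == "expert":
        coupled = config.at_effect * (rho - config.rho_ap_expert)
        resid_sd = np.sqrt(max(at_sd**2 - (config.at_effect * config.rho_sd) ** 2, 1.0))
        at = cal["at_mean"] + coupled + rng.normal(0.0, resid_sd)
    else:
        at = rng.normal(cal["at_mean"], at_sd)
    ds_sd = cal["ds_se"] * np.sqrt(cal["n_ref"])
    ds = rng.normal(cal["ds_mean"], ds_sd)
    elo = rng.uniform(*cal["elo"])
    gtypes, gprobs = zip(*_GAME_TYPE_P[group].items())
    game_type = str(rng.choice(gtypes, p=gprobs))
    gmv = None
    if config.include_gmv:
        gmv = {}
        for name in GMV_SUBREGIONS:
            for hemi in ("L", "R"):
                base = 2500.0
                if name == "long_insular_gyrus_central_sulcus" and hemi == "L":
                    group_rho = config.rho_ap_expert if group == "expert" else config.rho_ap_amateur
                    base += (200.0 if group == "expert" else 0.0) + 600.0 * (rho - group_rho)
                gmv[f"{name}_{hemi}"] = max(float(rng.normal(base, 150.0)), 0.0)
    return PhenotypeRecord(
        subject_id=subject_id,
        group=group,
        at_hours_per_week=max(float(at), 0.0),
        elo_points=float(elo),
        ds_seconds=max(float(ds), 0.0),
        game_type=game_type,
        gmv_mm3=gmv,
    )


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full two-group cohort.

    Deterministic given (config, config.seed): subject streams derive from
    the master seed and the subject index, so cohorts are reproducible and
    individual subjects can be regenerated independently.
    """
    sites = _signal_sites(config)
    low, high = config.signal_band_hz
    sos = sp_signal.butter(2, [low, high], btype="bandpass",
                           fs=1.0 / config.grid.tr_seconds, output="sos")
    runs, confounds, phenotypes, truth_rows = [], [], [], []
    groups = ["expert"] * config.n_expert + ["amateur"] * config.n_amateur
    for idx, group in enumerate(groups):
        rng = np.random.default_rng([config.seed, idx])
        subject_id = f"sub-{idx + 1:03d}"
        group_rho = config.rho_ap_expert if group == "expert" else config.rho_ap_amateur
        rho = float(np.clip(rng.normal(group_rho, config.rho_sd), -0.95, 0.95))
        run, conf = _subject_run(rng, subject_id, rho, config, sites, sos)
        runs.append(run)
        confounds.append(conf)
        phenotypes.append(_phenotype(rng, subject_id, group, rho, config))
        truth_rows.append({
            "subject_id": subject_id,
            "group": group,
            "rho_latent": rho,
            "rho_implied": config.implied_integration(rho),
        })
    return Cohort(
        runs=runs,
        confounds=confounds,
        phenotypes=phenotypes,
        ground_truth=pd.DataFrame(truth_rows),
        config=config,
    )


def write_cohort(cohort: Cohort, directory) -> dict:
    """Write the cohort to disk (NIfTI runs, TSV tables, JSON manifest).

    Returns the manifest dict; the same data round-trip through
    :func:`insulafc.io.read_cohort`.
    """
    from . import io as io_mod

    return io_mod.write_cohort(cohort, directory)
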