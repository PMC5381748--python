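"""Insular ROI atlas: twenty 7-voxel near-spherical seeds and their signals.

Ten ROIs per hemisphere are laid out in three horizontal planes with
left-right mirrored coordinates.  Each ROI is the unique 7-voxel digital
ball of radius 1 (a center voxel plus its six face neighbors), so at 3 mm
isotropic resolution every ROI occupies 7 x 27 = 189 mm^3.

Subregion classes follow the fixed index convention:
anterior {1, 2, 4, 5, 8}, posterior {3, 7, 10}, transitional {6, 9}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec

__all__ = [
    "ANTERIOR_INDICES",
    "POSTERIOR_INDICES",
    "TRANSITIONAL_INDICES",
    "SUBREGION_OF_INDEX",
    "RoiDefinition",
    "RoiSignalSet",
    "AtlasError",
    "default_roi_table",
    "build_atlas",
    "extract_signals",
    "atlas_to_labels",
    "read_roi_table",
    "write_roi_table",
]

ANTERIOR_INDICES = (1, 2, 4, 5, 8)
POSTERIOR_INDICES = (3, 7, 10)
TRANSITIONAL_INDICES = (6, 9)

SUBREGION_OF_INDEX = {
    **{i: "anterior" for i in ANTERIOR_INDICES},
    **{i: "posterior" for i in POSTERIOR_INDICES},
    **{i: "transitional" for i in TRANSITIONAL_INDICES},
}

#: face-neighbor offsets defining the 7-voxel digital ball
_BALL_OFFSETS = np.array(
    [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
)

ROI_TABLE_COLUMNS = ["roi_index", "hemisphere", "subregion", "x_mm", "y_mm", "z_mm"]


class AtlasError(ValueError):
    """ROI placement problem: out-of-bounds center, overlap, or broken mirror."""


@dataclass(frozen=True)
class RoiDefinition:
    """One labeled 7-voxel seed region."""

    hemisphere: str  # "L" or "R"
    index: int  # 1..10
    subregion: str  # anterior / transitional / posterior
    center_mm: tuple[float, float, float]
    center_voxel: tuple[int, int, int]
    voxels: tuple[tuple[int, int, int], ...]  # 7 voxel coordinates

    @property
    def roi_id(self) -> tuple[str, int]:
        return (self.hemisphere, self.index)

    @property
    def label(self) -> str:
        return f"{self.hemisphere}{self.index}"

    def volume_mm3(self, grid: GridSpec) -> float:
        return len(self.voxels) * float(np.prod(grid.voxel_size_mm))


@dataclass
class RoiSignalSet:
    """Mean time course of every ROI for one subject."""

    subject_id: str
    signals: dict[tuple[str, int], np.ndarray]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.signals.values()}
        if len(lengths) > 1:
            raise ValueError(f"ROI signals have mixed lengths {sorted(lengths)}")
        for roi_id, s in self.signals.items():
            if not np.all(np.isfinite(s)):
                raise ValueError(f"non-finite signal for ROI {roi_id}")

    @property
    def n_timepoints(self) -> int:
        return len(next(iter(self.signals.values())))

    def mean_signal(self, roi_ids) -> np.ndarray:
        """Unweighted average of the named ROI time courses."""
        return np.mean([self.signals[r] for r in roi_ids], axis=0)


def default_roi_table() -> pd.DataFrame:
    """Synthetic default ROI layout (not anatomical coordinates).

    Three z-planes (+9, 0, -9 mm), anterior ROIs at larger y, mirrored at
    x = +/-9 mm.  Ships for testing on the default synthetic grid; real
    coordinate tables can be supplied in the same format.
    """
    layout = {  # index -> (y_mm, z_mm); >= 9 mm in-plane spacing keeps balls disjoint
        1: (15.0, 9.0),
        2: (6.0, 9.0),
        3: (-12.0, 9.0),
        4: (15.0, 0.0),
        5: (6.0, 0.0),
        6: (-3.0, 0.0),
        7: (-12.0, 0.0),
        8: (12.0, -9.0),
        9: (0.0, -9.0),
        10: (-12.0, -9.0),
    }
    rows = []
    for hemi, x in (("L", -9.0), ("R", 9.0)):
        for idx, (y, z) in layout.items():
            rows.append(
                {
                    "roi_index": idx,
                    "hemisphere": hemi,
                    "subregion": SUBREGION_OF_INDEX[idx],
                    "x_mm": x,
                    "y_mm": y,
                    "z_mm": z,
                }
            )
    return pd.DataFrame(rows, columns=ROI_TABLE_COLUMNS)


def _ball_voxels(center: np.ndarray) -> np.ndarray:
    return center[None, :] + _BALL_OFFSETS


def build_atlas(table: pd.DataFrame, grid: GridSpec) -> list[RoiDefinition]:
    """Construct the 20 ROI definitions from a coordinate table.

    Validates bounds (every ROI voxel inside the grid), pairwise
    disjointness, the subregion-class convention, and exact left/right
    voxel mirroring through the grid affine.
    """
    missing = [c for c in ROI_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise AtlasError(f"ROI table missing columns: {missing}")
    if len(table) != 20:
        raise AtlasError(f"expected 20 ROIs, table has {len(table)}")

    rois: dict[tuple[str, int], RoiDefinition] = {}
    occupied: dict[tuple[int, int, int], str] = {}
    for row in table.itertuples(index=False):
        idx = int(row.roi_index)
        hemi = str(row.hemisphere)
        if hemi not in ("L", "R") or idx not in SUBREGION_OF_INDEX:
            raise AtlasError(f"bad ROI id ({hemi}, {idx})")
        expected = SUBREGION_OF_INDEX[idx]
        if str(row.subregion) != expected:
            raise AtlasError(
                f"ROI {hemi}{idx} labeled '{row.subregion}' but index {idx} "
                f"is {expected} by convention"
            )
        center_mm = (float(row.x_mm), float(row.y_mm), float(row.z_mm))
        cvox = grid.mm_to_voxel(center_mm)
        voxels = _ball_voxels(np.asarray(cvox))
        if not grid.in_bounds(voxels):
            raise AtlasError(
                f"ROI {hemi}{idx} at {center_mm} mm maps to voxel {tuple(cvox)}; "
                "its 7-voxel ball leaves the grid"
            )
        vox_tuples = tuple(map(tuple, voxels.tolist()))
        for v in vox_tuples:
            if v in occupied:
                raise AtlasError(f"ROI {hemi}{idx} overlaps ROI {occupied[v]} at voxel {v}")
            occupied[v] = f"{hemi}{idx}"
        rois[(hemi, idx)] = RoiDefinition(
            hemisphere=hemi,
            index=idx,
            subregion=expected,
            center_mm=center_mm,
            center_voxel=tuple(int(i) for i in cvox),
            voxels=vox_tuples,
        )

    for idx in range(1, 11):
        left = rois.get(("L", idx))
        right = rois.get(("R", idx))
        if left is None or right is None:
            raise AtlasError(f"ROI pair {idx} incomplete (need both hemispheres)")
        mirrored = {tuple(v) for v in np.atleast_2d(grid.mirror_voxel(np.array(left.voxels)))}
        if mirrored != set(right.voxels):
            raise AtlasError(f"ROI pair {idx} does not mirror across the midline")

    return [rois[(h, i)] for h in ("L", "R") for i in range(1, 11)]


def extract_signals(data_or_run, atlas: list[RoiDefinition], subject_id: str | None = None) -> RoiSignalSet:
    """Average the 7 voxel time courses of each ROI.

    Accepts a :class:`~insulafc.cohort.BOLDRun` or a bare 4D array.
    """
    if hasattr(data_or_run, "grid"):  # a BOLDRun-like object
        data = np.asarray(data_or_run.data)
        subject_id = subject_id or data_or_run.subject_id
    else:
        data = np.asarray(data_or_run)
        subject_id = subject_id or "unknown"
    if data.ndim != 4:
        raise ValueError(f"expected 4D data, got shape {data.shape}")
    signals = {}
    for roi in atlas:
        vox = np.array(roi.voxels)
        if np.any(vox < 0) or np.any(vox >= np.array(data.shape[:3])):
            raise AtlasError(f"ROI {roi.label} lies outside the run grid {data.shape[:3]}")
        signals[roi.roi_id] = data[vox[:, 0], vox[:, 1], vox[:, 2], :].mean(axis=0)
    return RoiSignalSet(subject_id=subject_id, signals=signals)


def atlas_to_labels(atlas: list[RoiDefinition], grid: GridSpec) -> np.ndarray:
    """Integer-labeled volume: L1..L10 -> 1..10, R1..R10 -> 11..20, 0 elsewhere."""
    labels = np.zeros(grid.dims, dtype=np.int16)
    for roi in atlas:
        value = roi.index + (10 if roi.hemisphere == "R" else 0)
        for v in roi.voxels:
            labels[v] = value
    return labels


def write_roi_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_roi_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ROI_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise AtlasError(f"ROI table {path} missing columns: {missing}")
    return table
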