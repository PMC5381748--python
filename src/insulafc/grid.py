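"""Sampling grid for 4D BOLD runs and the mm <-> voxel coordinate mapping.

The grid is a small synthetic acquisition volume, not an anatomical template
space: world (mm) coordinates are defined by an axis-aligned affine whose
origin sits at the central voxel, so that x = 0 mm is the midline plane and
left/right hemispheres mirror as x -> -x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "GridError"]


class GridError(ValueError):
    """Invalid grid specification (dims, voxel size, or memory cap)."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry and timing of a 4D acquisition.

    Parameters
    ----------
    dims : tuple of int
        Voxels along (x, y, z). Each axis must have at least 8 voxels.
    voxel_size_mm : tuple of float
        Voxel edge lengths in mm; default 3 mm isotropic.
    tr_seconds : float
        Repetition time (sampling interval) in seconds; default 2 s.
    n_volumes : int
        Number of time points; default 255 (a 510 s scan at TR = 2 s).
    memory_cap_bytes : int
        Upper bound on the float64 footprint of one run; guards against
        accidentally huge simulation requests.
    """

    dims: tuple[int, int, int] = (20, 24, 20)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_seconds: float = 2.0
    n_volumes: int = 255
    memory_cap_bytes: int = field(default=2**31, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(
            self, "voxel_size_mm", tuple(float(v) for v in self.voxel_size_mm)
        )
        if len(self.dims) != 3 or any(d < 8 for d in self.dims):
            raise GridError(f"grid dims must be 3 axes of >= 8 voxels, got {self.dims}")
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise GridError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        if self.tr_seconds <= 0:
            raise GridError(f"TR must be positive, got {self.tr_seconds}")
        if self.n_volumes < 1:
            raise GridError(f"n_volumes must be >= 1, got {self.n_volumes}")
        nbytes = 8 * self.n_voxels * self.n_volumes
        if nbytes > self.memory_cap_bytes:
            raise GridError(
                f"run of {self.dims} x {self.n_volumes} volumes needs {nbytes} bytes, "
                f"over the {self.memory_cap_bytes}-byte cap"
            )

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def shape4d(self) -> tuple[int, int, int, int]:
        return (*self.dims, self.n_volumes)

    @property
    def origin_voxel(self) -> np.ndarray:
        """Voxel index lying at world coordinate (0, 0, 0) mm."""
        return np.array([d // 2 for d in self.dims])

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel -> mm affine (axis-aligned, origin at the central voxel)."""
        aff = np.eye(4)
        vs = np.asarray(self.voxel_size_mm)
        aff[:3, :3] = np.diag(vs)
        aff[:3, 3] = -vs * self.origin_voxel
        return aff

    def voxel_to_mm(self, ijk) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        mm = ijk * np.asarray(self.voxel_size_mm) + self.affine[:3, 3]
        return mm.squeeze()

    def mm_to_voxel(self, mm) -> np.ndarray:
        """Map mm coordinates to voxel indices.

        Rounds to the nearest voxel with ties broken toward -inf
        (ceil(x - 0.5)), so the mapping is deterministic for coordinates
        falling exactly between voxel centers.
        """
        mm = np.atleast_2d(np.asarray(mm, dtype=float))
        frac = (mm - self.affine[:3, 3]) / np.asarray(self.voxel_size_mm)
        ijk = np.ceil(frac - 0.5).astype(int)
        return ijk.squeeze()

    def in_bounds(self, ijk) -> bool:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=int))
        return bool(np.all(ijk >= 0) and np.all(ijk < np.asarray(self.dims)))

    def mirror_voxel(self, ijk) -> np.ndarray:
        """Reflect voxel indices across the midline (x -> -x in mm)."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=int)).copy()
        ijk[:, 0] = 2 * self.origin_voxel[0] - ijk[:, 0]
        return ijk.squeeze()

    def with_volumes(self, n_volumes: int) -> "GridSpec":
        return GridSpec(
            dims=self.dims,
            voxel_size_mm=self.voxel_size_mm,
            tr_seconds=self.tr_seconds,
            n_volumes=n_volumes,
            memory_cap_bytes=self.memory_cap_bytes,
        )
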