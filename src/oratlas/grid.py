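"""Voxel grids and the package-wide coordinate convention.

All spatial data in this package live in RAS+ world millimetres (+X right,
+Y anterior, +Z superior).  Voxel indices are 0-based; the grid affine maps
the *center* of voxel ``(i, j, k)`` to world mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class VolumeGrid:
    """A regular 3-D voxel grid with a voxel-to-world affine.

    Parameters
    ----------
    shape
        Number of voxels along each axis, three positive integers.
    affine
        4x4 matrix mapping 0-based voxel indices (voxel centers) to RAS+
        world mm.  Must be invertible with strictly positive voxel sizes.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"grid shape must be three positive ints, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("grid affine is singular")
        if np.any(np.linalg.norm(affine[:3, :3], axis=0) <= 0):
            raise ValueError("voxel sizes must be strictly positive")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def from_extent(
        cls,
        low: tuple[float, float, float],
        high: tuple[float, float, float],
        voxel_mm: float,
    ) -> "VolumeGrid":
        """Axis-aligned grid whose voxel centers cover ``[low, high]`` mm."""
        low_a = np.asarray(low, float)
        high_a = np.asarray(high, float)
        if np.any(high_a <= low_a):
            raise ValueError("extent high must exceed low on every axis")
        shape = tuple(int(np.floor((h - l) / voxel_mm)) + 1 for l, h in zip(low_a, high_a))
        affine = np.eye(4)
        affine[:3, :3] *= voxel_mm
        affine[:3, 3] = low_a
        return cls(shape=shape, affine=affine)

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_diagonal(self) -> float:
        """Length of the voxel body diagonal in mm."""
        return float(np.linalg.norm(self.voxel_sizes))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to world mm, shape (..., 3)."""
        ijk = np.asarray(ijk, float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm to fractional voxel indices, shape (..., 3)."""
        xyz = np.asarray(xyz, float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def round_to_indices(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest-voxel integer indices for world points (may be out of bounds)."""
        return np.rint(self.world_to_voxel(xyz)).astype(int)

    def inside(self, ijk: np.ndarray) -> np.ndarray:
        """Boolean mask of index rows lying inside the grid."""
        ijk = np.asarray(ijk)
        return np.all((ijk >= 0) & (ijk < np.asarray(self.shape)), axis=-1)

    def voxel_center_mesh(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``shape + (3,)``."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return self.voxel_to_world(idx).reshape(self.shape + (3,))

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)
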