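"""Spatial transforms: affine plus optional dense displacement fields.

A :class:`SpatialTransform` maps world mm to world mm as

    T(p) = A p + D(A p)

where ``A`` is an invertible 4x4 affine and ``D`` an optional displacement
field stored on a :class:`~oratlas.grid.VolumeGrid` and interpolated
trilinearly (zero outside its grid).  This is the package's stand-in for the
inverse-normalization warps that carry a template-space atlas into an
individual's anatomical space.

Label resampling uses the *pull-back* convention: the transform handed to
:func:`resample_labels` must map target-space points to source-space points;
each target voxel center is pulled through the transform and assigned the
nearest-neighbor source label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import VolumeGrid


@dataclass
class SpatialTransform:
    """World->world transform ``p -> affine @ p + displacement(affine @ p)``."""

    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    displacement: np.ndarray | None = None  # (nx, ny, nz, 3) mm, on displacement_grid
    displacement_grid: VolumeGrid | None = None
    metadata: str = ""

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.displacement is not None:
            if self.displacement_grid is None:
                raise ValueError("displacement field requires a displacement_grid")
            disp = np.asarray(self.displacement, dtype=float)
            if disp.shape != tuple(self.displacement_grid.shape) + (3,):
                raise ValueError(
                    f"displacement shape {disp.shape} does not match grid "
                    f"{self.displacement_grid.shape}"
                )
            if not np.all(np.isfinite(disp)):
                raise ValueError("displacement field must be finite everywhere")
            self.displacement = disp

    # ------------------------------------------------------------------ helpers
    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls(metadata="identity")

    @classmethod
    def from_translation(cls, shift_mm) -> "SpatialTransform":
        aff = np.eye(4)
        aff[:3, 3] = np.asarray(shift_mm, float)
        return cls(affine=aff, metadata=f"translation {tuple(np.asarray(shift_mm, float))}")

    @property
    def has_field(self) -> bool:
        return self.displacement is not None

    def sample_displacement(self, points: np.ndarray, warn_outside: bool = True) -> np.ndarray:
        """Trilinearly interpolate the displacement at world points (mm).

        Points outside the field grid get zero displacement (with a warning).
        """
        points = np.atleast_2d(np.asarray(points, float))
        if self.displacement is None:
            return np.zeros_like(points)
        grid = self.displacement_grid
        ijk = grid.world_to_voxel(points)
        if warn_outside:
            pad = 1e-9
            out = np.any((ijk < -pad) | (ijk > np.asarray(grid.shape) - 1 + pad), axis=1)
            if np.any(out):
                warnings.warn(
                    f"{int(out.sum())} point(s) outside the displacement grid; "
                    "zero displacement used there",
                    stacklevel=2,
                )
        coords = ijk.T  # (3, N)
        out_disp = np.empty_like(points)
        for c in range(3):
            out_disp[:, c] = ndimage.map_coordinates(
                self.displacement[..., c], coords, order=1, mode="constant", cval=0.0
            )
        return out_disp

    # --------------------------------------------------------------- operations
    def apply_to_points(self, points: np.ndarray) -> np.ndarray:
        """Map world points through the transform; shape preserved."""
        pts = np.asarray(points, float)
        single = pts.ndim == 1
        pts2 = np.atleast_2d(pts)
        if not np.all(np.isfinite(pts2)):
            raise ValueError("points must be finite")
        moved = pts2 @ self.affine[:3, :3].T + self.affine[:3, 3]
        if self.has_field:
            moved = moved + self.sample_displacement(moved)
        return moved[0] if single else moved.reshape(pts.shape)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self.apply_to_points(points)

    def compose(self, inner: "SpatialTransform",
                field_grid: VolumeGrid | None = None) -> "SpatialTransform":
        """Transform equal to ``self`` after ``inner``: ``T(p) = self(inner(p))``.

        Affine-only composition is exact.  When a displacement field is
        involved, the residual non-affine part is sampled on ``field_grid``
        (default: whichever field grid the operands carry) and interpolated
        thereafter, accurate to interpolation tolerance.
        """
        affine = self.affine @ inner.affine
        if not self.has_field and not inner.has_field:
            return SpatialTransform(affine=affine,
                                    metadata=f"({self.metadata})o({inner.metadata})")
        grid = field_grid or self.displacement_grid or inner.displacement_grid
        centers = grid.voxel_center_mesh().reshape(-1, 3)  # y = A_c p samples
        inv_ac = np.linalg.inv(affine)
        p = centers @ inv_ac[:3, :3].T + inv_ac[:3, 3]
        mapped = self.apply_to_points(inner.apply_to_points(p))
        disp = (mapped - centers).reshape(tuple(grid.shape) + (3,))
        return SpatialTransform(
            affine=affine, displacement=disp, displacement_grid=grid,
            metadata=f"({self.metadata})o({inner.metadata})",
        )

    def invert(self, tol_mm: float = 0.005, max_iter: int = 50,
               refine: int = 2) -> "SpatialTransform":
        """Inverse transform.

        The affine part is inverted exactly.  A displacement field is
        inverted by fixed-point iteration: solve ``E(z) = -D(z + E(z))``
        until the max update falls below ``tol_mm``.  The inverse field is
        sampled on a grid ``refine`` times finer than the forward field's to
        keep its own interpolation error below the round-trip tolerance.
        Raises on non-convergence (non-diffeomorphic fields).
        """
        inv_aff = np.linalg.inv(self.affine)
        if not self.has_field:
            return SpatialTransform(affine=inv_aff, metadata=f"inv({self.metadata})")
        src = self.displacement_grid
        if refine > 1:
            fine_affine = src.affine.copy()
            fine_affine[:3, :3] /= refine
            shape = tuple((np.asarray(src.shape) - 1) * refine + 1)
            grid = VolumeGrid(shape=shape, affine=fine_affine)
        else:
            grid = src
        z = grid.voxel_center_mesh().reshape(-1, 3)
        e = np.zeros_like(z)
        residual = np.inf
        for _ in range(max_iter):
            e_new = -self.sample_displacement(z + e, warn_outside=False)
            residual = float(np.max(np.linalg.norm(e_new - e, axis=1)))
            e = e_new
            if residual < tol_mm:
                break
        else:
            raise RuntimeError(
                f"displacement inversion did not converge: residual {residual:.4f} mm "
                f"after {max_iter} iterations (field may not be diffeomorphic)"
            )
        # T^{-1}(z) = A^{-1}(z + E(z)); in the package's post-affine form the
        # inverse field lives on the grid carried into A^{-1} space.
        rinv = inv_aff[:3, :3]
        disp = (e @ rinv.T).reshape(tuple(grid.shape) + (3,))
        out_grid = VolumeGrid(shape=grid.shape, affine=inv_aff @ grid.affine)
        return SpatialTransform(
            affine=inv_aff, displacement=disp, displacement_grid=out_grid,
            metadata=f"inv({self.metadata})",
        )

    def min_jacobian_det(self) -> float:
        """Minimum Jacobian determinant of the warp ``y -> y + D(y)`` over voxels.

        Positive everywhere means the non-affine part is locally invertible;
        the affine factor has constant determinant and is checked separately.
        """
        if not self.has_field:
            return 1.0
        spacing = self.displacement_grid.voxel_sizes
        jac = np.empty(tuple(self.displacement_grid.shape) + (3, 3))
        for c in range(3):
            grads = np.gradient(self.displacement[..., c], *spacing)
            for ax in range(3):
                jac[..., c, ax] = grads[ax]
        jac += np.eye(3)
        return float(np.min(np.linalg.det(jac)))

    def round_trip_error_mm(self, points: np.ndarray) -> float:
        """Max ``|T^{-1}(T(p)) - p|`` over the given points."""
        inv = self.invert()
        pts = np.atleast_2d(np.asarray(points, float))
        back = inv.apply_to_points(self.apply_to_points(pts))
        return float(np.max(np.linalg.norm(back - pts, axis=1)))


def compose(outer: SpatialTransform, inner: SpatialTransform,
            field_grid: VolumeGrid | None = None) -> SpatialTransform:
    """Functional alias: ``compose(a, b)(p) == a(b(p))``."""
    return outer.compose(inner, field_grid=field_grid)


def invert(t: SpatialTransform) -> SpatialTransform:
    return t.invert()


def apply_to_points(t: SpatialTransform, points: np.ndarray) -> np.ndarray:
    return t.apply_to_points(points)


def resample_labels(labels, t: SpatialTransform, target_grid: VolumeGrid):
    """Pull a label volume onto ``target_grid`` through ``t`` (target->source).

    Every target voxel center is mapped through ``t`` into the source space
    and assigned the nearest-neighbor source label; labels are never
    interpolated, so the output value set is a subset of the input's.
    """
    from .atlas import LabelVolume  # local import to avoid a cycle

    if abs(np.linalg.det(np.asarray(target_grid.affine)[:3, :3])) < 1e-12:
        raise ValueError("target grid affine is not invertible")
    centers = target_grid.voxel_center_mesh().reshape(-1, 3)
    src_pts = t.apply_to_points(centers)
    ijk = labels.grid.round_to_indices(src_pts)
    inside = labels.grid.inside(ijk)
    out = np.zeros(int(np.prod(target_grid.shape)), dtype=labels.labels.dtype)
    idx = ijk[inside]
    out[inside] = labels.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
    return LabelVolume(grid=target_grid, labels=out.reshape(target_grid.shape))
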