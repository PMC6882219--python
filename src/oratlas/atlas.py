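"""Group-atlas construction: merged streamlines, tract-density images and
integer label volumes, plus rigid mask-to-mask registration.

The label legend is fixed across the package: 1 = left ORu, 2 = right ORu,
3 = left ORl, 4 = right ORl, 0 = background (ORu/ORl = upper/lower division
of the optic radiation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .grid import VolumeGrid
from .streamlines import StreamlineSet
from .transforms import SpatialTransform

#: label value -> (side, division)
LABEL_LEGEND: dict[int, tuple[str, str]] = {
    1: ("left", "ORu"),
    2: ("right", "ORu"),
    3: ("left", "ORl"),
    4: ("right", "ORl"),
}
#: (side, division) -> label value
DIVISION_LABELS = {v: k for k, v in LABEL_LEGEND.items()}


def side_labels(side: str) -> tuple[int, ...]:
    """Label values belonging to one side (e.g. ``"left"`` -> (1, 3))."""
    vals = tuple(k for k, (s, _) in LABEL_LEGEND.items() if s == side)
    if not vals:
        raise ValueError(f"unknown side {side!r}; expected 'left' or 'right'")
    return vals


@dataclass
class LabelVolume:
    """Integer-coded atlas regions on a grid; values restricted to 0-4."""

    grid: VolumeGrid
    labels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.allclose(lab, np.round(lab)):
                raise ValueError(f"labels must be integers, got dtype {lab.dtype}")
            lab = np.round(lab).astype(np.int16)
        if lab.shape != tuple(self.grid.shape):
            raise ValueError(f"labels shape {lab.shape} != grid shape {self.grid.shape}")
        bad = set(np.unique(lab)) - {0, 1, 2, 3, 4}
        if bad:
            raise ValueError(f"labels outside legend {{0..4}}: {sorted(bad)}")
        self.labels = lab.astype(np.int16)

    def mask(self, side: str | None = None) -> np.ndarray:
        """Boolean mask of labeled voxels, optionally restricted to one side."""
        if side is None:
            return self.labels > 0
        return np.isin(self.labels, side_labels(side))


@dataclass
class TDIVolume:
    """Tract-density image: per-voxel count of traversing streamlines."""

    grid: VolumeGrid
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        cts = np.asarray(self.counts)
        if cts.shape != tuple(self.grid.shape):
            raise ValueError(f"counts shape {cts.shape} != grid shape {self.grid.shape}")
        if np.any(cts < 0):
            raise ValueError("TDI counts must be non-negative")
        self.counts = cts.astype(np.int32)


# --------------------------------------------------------------------- voxels
def traversal_intervals(sl: np.ndarray, grid: VolumeGrid):
    """Exact voxel walk of a polyline: one entry per (segment, voxel) interval.

    Every segment is sliced at its half-integer plane crossings in voxel
    coordinates; each interval's midpoint identifies the voxel the segment
    occupies there.  Returns ``(ijk, seg_ids, inside)`` where ``ijk`` is the
    per-interval voxel index (possibly out of bounds), ``seg_ids`` the
    segment index and ``inside`` the in-bounds mask.
    """
    vox = grid.world_to_voxel(sl)
    a, b = vox[:-1], vox[1:]
    d = b - a
    n_seg = len(a)
    ts = [np.zeros(n_seg), np.ones(n_seg)]
    seg_ids = [np.arange(n_seg), np.arange(n_seg)]
    for ax in range(3):
        lo = np.minimum(a[:, ax], b[:, ax])
        hi = np.maximum(a[:, ax], b[:, ax])
        # half-integer planes strictly inside (lo, hi)
        first = np.floor(lo + 0.5) + 0.5
        count = np.maximum(np.floor(hi - 0.5) - first + 1.5, 0.0).astype(int)
        count[np.abs(d[:, ax]) < 1e-15] = 0
        total = int(count.sum())
        if total == 0:
            continue
        seg = np.repeat(np.arange(n_seg), count)
        offs = np.arange(total) - np.repeat(np.cumsum(count) - count, count)
        planes = first[seg] + offs
        ts.append((planes - a[seg, ax]) / d[seg, ax])
        seg_ids.append(seg)
    t_all = np.concatenate(ts)
    s_all = np.concatenate(seg_ids)
    order = np.lexsort((t_all, s_all))
    t_all, s_all = t_all[order], s_all[order]
    same_seg = s_all[:-1] == s_all[1:]
    t_mid = 0.5 * (t_all[:-1] + t_all[1:])[same_seg]
    s_mid = s_all[:-1][same_seg]
    pts = a[s_mid] + t_mid[:, None] * d[s_mid]
    ijk = np.floor(pts + 0.5).astype(int)
    inside = np.all((ijk >= 0) & (ijk < np.asarray(grid.shape)), axis=1)
    return ijk, s_mid, inside


def streamline_voxels(sl: np.ndarray, grid: VolumeGrid, clip: bool = True) -> np.ndarray:
    """Unique voxel indices traversed by one streamline (exact).

    A voxel is traversed when any point of any segment lies in it (voxel
    cells are the nearest-neighbor regions around voxel centers); re-entering
    a voxel does not duplicate it (set semantics per streamline).
    """
    ijk, _, inside = traversal_intervals(sl, grid)
    if clip and not np.all(inside):
        ijk = ijk[inside]
    return np.unique(ijk, axis=0)


# ----------------------------------------------------------------- operations
def merge_groups(groups: list[StreamlineSet]) -> StreamlineSet:
    """Concatenate per-subject streamline groups sharing one space.

    Per-streamline subject/division tags are preserved; the output count is
    the sum of the group counts ("merged the 30 groups of fibers" step).
    """
    streamlines: list[np.ndarray] = []
    tags: list[dict] = []
    for g in groups:
        streamlines.extend(sl.copy() for sl in g.streamlines)
        tags.extend(dict(t) for t in g.tags)
    if not streamlines:
        return StreamlineSet([], [])
    return StreamlineSet(streamlines, tags)


def compute_tdi(tracks: StreamlineSet, grid: VolumeGrid) -> TDIVolume:
    """Tract density image: each streamline adds 1 to every voxel it traverses."""
    counts = np.zeros(grid.shape, dtype=np.int32)
    clipped = 0
    for sl in tracks:
        ijk_all = grid.round_to_indices(sl)
        if not np.all(grid.inside(ijk_all)):
            clipped += 1
        vox = streamline_voxels(sl, grid, clip=True)
        if len(vox):
            counts[vox[:, 0], vox[:, 1], vox[:, 2]] += 1
    if clipped:
        warnings.warn(f"{clipped} streamline(s) extend outside the grid; clipped",
                      stacklevel=2)
    return TDIVolume(grid=grid, counts=counts)


def _normalize_division_key(key) -> int:
    if isinstance(key, (int, np.integer)):
        if int(key) not in LABEL_LEGEND:
            raise ValueError(f"unknown division label {key}; legend is {LABEL_LEGEND}")
        return int(key)
    if isinstance(key, tuple) and tuple(key) in DIVISION_LABELS:
        return DIVISION_LABELS[tuple(key)]
    if isinstance(key, str):
        for (side, div), lab in DIVISION_LABELS.items():
            if key in (f"{side}_{div}", f"{side}-{div}"):
                return lab
    raise ValueError(
        f"unknown division key {key!r}; use a label 1-4, a (side, division) "
        f"tuple, or 'side_division' such as 'left_ORu'"
    )


def build_label_volume(
    division_tracks: dict,
    grid: VolumeGrid,
    min_subject_support: int = 1,
) -> LabelVolume:
    """Assign each voxel the label of the division whose streamlines cover it.

    A voxel receives a division's label iff streamlines of that division from
    at least ``min_subject_support`` distinct subjects traverse it.  Where
    divisions overlap, the one with the larger subject support wins; exact
    ties go to the lower label value (ORu over ORl).
    """
    support = np.zeros((4,) + tuple(grid.shape), dtype=np.int32)
    for key, tracks in division_tracks.items():
        lab = _normalize_division_key(key)
        by_subject: dict = {}
        for sl, tag in zip(tracks.streamlines, tracks.tags):
            by_subject.setdefault(tag.get("subject", 0), []).append(sl)
        for _, sls in by_subject.items():
            seen = np.zeros(grid.shape, dtype=bool)
            for sl in sls:
                vox = streamline_voxels(sl, grid, clip=True)
                if len(vox):
                    seen[vox[:, 0], vox[:, 1], vox[:, 2]] = True
            support[lab - 1][seen] += 1
    support[support < min_subject_support] = 0
    best = np.argmax(support, axis=0)  # first max wins -> lower label on ties
    labels = np.where(support.max(axis=0) > 0, best + 1, 0).astype(np.int16)
    return LabelVolume(grid=grid, labels=labels)


# --------------------------------------------------- rigid mask registration
def _euler_rotation(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation matrix from extrinsic XYZ Euler angles in radians."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    rx_m = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry_m = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz_m = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz_m @ ry_m @ rx_m


def _mask_moments(vol: LabelVolume) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = np.argwhere(vol.labels > 0)
    if len(idx) <= 3:
        raise ValueError(
            f"degenerate mask with {len(idx)} voxel(s); rigid registration "
            "needs a larger mask"
        )
    pts = vol.grid.voxel_to_world(idx)
    centroid = pts.mean(axis=0)
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] < 1e-9 or np.min(np.abs(np.diff(evals)) / evals[0]) < 1e-3:
        raise ValueError(
            "mask inertia is (near-)isotropic; principal axes are ambiguous — "
            "use larger or less symmetric masks"
        )
    return pts, centroid, evecs


def rigid_register_masks(moving: LabelVolume, fixed: LabelVolume) -> SpatialTransform:
    """Estimate the rigid transform carrying ``moving`` mask onto ``fixed``.

    Initialization aligns binary-mask centroids and principal inertia axes
    (trying the four proper-rotation sign choices), then a local Nelder-Mead
    search over small rotations and translations maximizes soft overlap with
    the fixed mask.  Returns the world->world transform moving->fixed.
    """
    from scipy.ndimage import map_coordinates

    from scipy.ndimage import gaussian_filter

    mov_pts, c_m, ax_m = _mask_moments(moving)
    _, c_f, ax_f = _mask_moments(fixed)
    # a lightly blurred target turns the piecewise-constant overlap into a
    # smooth objective so the simplex search can polish sub-voxel alignment
    fixed_soft = gaussian_filter((fixed.labels > 0).astype(float), sigma=1.0)

    def soft_overlap(rot: np.ndarray, shift: np.ndarray) -> float:
        mapped = (mov_pts - c_m) @ rot.T + c_f + shift
        ijk = fixed.grid.world_to_voxel(mapped)
        vals = map_coordinates(fixed_soft, ijk.T, order=1, mode="constant", cval=0.0)
        return float(vals.mean())

    best_rot, best_score = None, -np.inf
    for sx in (1.0, -1.0):
        for sy in (1.0, -1.0):
            axes = ax_f * np.array([sx, sy, sx * sy])  # keep det positive
            rot = axes @ ax_m.T
            if np.linalg.det(rot) < 0:
                continue
            score = soft_overlap(rot, np.zeros(3))
            if score > best_score:
                best_rot, best_score = rot, score

    def objective(params: np.ndarray) -> float:
        rot = _euler_rotation(*params[:3]) @ best_rot
        return -soft_overlap(rot, params[3:])

    res = optimize.minimize(
        objective, np.zeros(6), method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 2000},
    )
    rot = _euler_rotation(*res.x[:3]) @ best_rot
    shift = res.x[3:]
    affine = np.eye(4)
    affine[:3, :3] = rot
    affine[:3, 3] = c_f + shift - rot @ c_m
    return SpatialTransform(affine=affine, metadata="rigid mask registration")
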