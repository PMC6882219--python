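"""Deterministic streamline tracking on per-voxel orientation fields.

The tracker follows a single principal fiber direction per voxel with
trilinear interpolation, direction smoothing and a turn-angle gate — the
"streamlined" deterministic algorithm with the stock parameter set
(angular threshold 90 deg, step 0.5 mm, smoothing 0.8, length bounds
30-300 mm, 50,000 seeds).  Quantitative anisotropy (QA) plays the role of
the tracking mask: a branch stops where interpolated QA falls below the
threshold.

Vector interpolation handles the antipodal symmetry of fiber orientations:
each corner vector is sign-aligned to the incoming direction before the
trilinear weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import VolumeGrid
from .streamlines import StreamlineSet

_CORNERS = np.array(
    [[i, j, k] for i in (0, 1) for j in (0, 1) for k in (0, 1)], dtype=int
)


@dataclass
class OrientationField:
    """Per-voxel principal fiber direction and QA scalar on a grid.

    ``direction`` has shape ``grid.shape + (3,)`` with unit vectors wherever
    ``qa > 0`` and zeros elsewhere; ``qa`` is non-negative.
    """

    grid: VolumeGrid
    direction: np.ndarray = field(repr=False)
    qa: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        q = np.asarray(self.qa, float)
        if d.shape != tuple(self.grid.shape) + (3,):
            raise ValueError(f"direction shape {d.shape} != grid shape + (3,)")
        if q.shape != tuple(self.grid.shape):
            raise ValueError(f"qa shape {q.shape} != grid shape")
        if np.any(q < 0):
            raise ValueError("qa must be non-negative")
        norms = np.linalg.norm(d, axis=-1)
        bad = (q > 0) & ~np.isclose(norms, 1.0, atol=1e-6)
        if np.any(bad):
            raise ValueError(f"{int(bad.sum())} voxel(s) with qa>0 lack unit direction")
        self.direction = d
        self.qa = q


@dataclass
class TrackingParams:
    """Streamline tracking parameters (defaults follow the stock protocol)."""

    qa_threshold: float = 0.0
    angular_threshold_deg: float = 90.0
    step_mm: float = 0.5
    # direction update: next = normalize((1-smoothing)*previous +
    # smoothing*interpolated).  The previous direction acts as inertia; with
    # the weight on the *previous* direction instead, a tracker provably
    # spirals out of any curved bundle (outward drift ~ step*sin(lag) per
    # step), so the smoothing weight applies to the interpolated field.
    smoothing: float = 0.8
    min_length_mm: float = 30.0
    max_length_mm: float = 300.0
    seed_count: int = 50_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.smoothing <= 1.0):
            raise ValueError("smoothing must be in [0, 1]")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if not (0 < self.min_length_mm <= self.max_length_mm):
            raise ValueError("need 0 < min_length_mm <= max_length_mm")
        if self.seed_count < 1:
            raise ValueError("seed_count must be >= 1")
        if self.qa_threshold < 0:
            raise ValueError("qa_threshold must be >= 0")


def auto_qa_threshold(field_: OrientationField, tissue_mask: np.ndarray,
                      inside_fraction: float = 0.99) -> float:
    """Heuristic stand-in for the visual QA-threshold choice.

    Returns the smallest threshold (scanned over the QA value range) at which
    at least ``inside_fraction`` of the suprathreshold QA mass lies inside
    ``tissue_mask`` — emulating the manual "signal stays within brain tissue"
    criterion on phantom data.
    """
    qa = field_.qa
    candidates = np.unique(np.round(qa[qa > 0], 6))
    for thr in np.concatenate([[0.0], candidates]):
        supra = qa > thr
        total = qa[supra].sum()
        if total == 0:
            break
        if qa[supra & tissue_mask].sum() / total >= inside_fraction:
            return float(thr)
    return float(candidates[-1]) if len(candidates) else 0.0


def _interpolate(field_: OrientationField, pos_vox: np.ndarray,
                 ref_dir: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear QA and sign-aligned direction at fractional voxel positions.

    Out-of-grid corners contribute zero QA and zero vector.  Each corner
    vector is flipped to the hemisphere of ``ref_dir`` before weighting.
    """
    shape = np.asarray(field_.grid.shape)
    base = np.floor(pos_vox).astype(int)
    frac = pos_vox - base
    qa_acc = np.zeros(len(pos_vox))
    vec_acc = np.zeros((len(pos_vox), 3))
    for corner in _CORNERS:
        idx = base + corner
        valid = np.all((idx >= 0) & (idx < shape), axis=1)
        idx_c = np.clip(idx, 0, shape - 1)
        w = np.prod(np.where(corner, frac, 1.0 - frac), axis=1) * valid
        q = field_.qa[idx_c[:, 0], idx_c[:, 1], idx_c[:, 2]]
        v = field_.direction[idx_c[:, 0], idx_c[:, 1], idx_c[:, 2]]
        sign = np.where(np.einsum("ij,ij->i", v, ref_dir) < 0, -1.0, 1.0)
        qa_acc += w * q
        vec_acc += (w * sign)[:, None] * v
    return vec_acc, qa_acc


def _track_branch(field_: OrientationField, start: np.ndarray, start_dir: np.ndarray,
                  budget_mm: np.ndarray, params: TrackingParams) -> list[np.ndarray]:
    """March one branch for a batch of seeds; returns per-seed point lists.

    ``start_dir`` must be unit vectors; seeds with zero budget yield empty
    branches (the start point itself is owned by the caller).
    """
    n = len(start)
    inv_affine = np.linalg.inv(field_.grid.affine)

    def to_vox(p):
        return p @ inv_affine[:3, :3].T + inv_affine[:3, 3]

    cos_gate = np.cos(np.radians(params.angular_threshold_deg))
    pos = start.copy()
    prev = start_dir.copy()
    remaining = budget_mm.copy()
    active = remaining >= params.step_mm - 1e-12
    out: list[list[np.ndarray]] = [[] for _ in range(n)]
    max_steps = int(np.ceil(params.max_length_mm / params.step_mm)) + 1
    for _ in range(max_steps):
        if not np.any(active):
            break
        ia = np.flatnonzero(active)
        vec, qa = _interpolate(field_, to_vox(pos[ia]), prev[ia])
        norms = np.linalg.norm(vec, axis=1)
        ok = (qa >= params.qa_threshold) & (qa > 0) & (norms > 1e-8)
        new_dir = np.zeros_like(vec)
        new_dir[ok] = vec[ok] / norms[ok, None]
        mixed = (1.0 - params.smoothing) * prev[ia] + params.smoothing * new_dir
        mnorm = np.linalg.norm(mixed, axis=1)
        ok &= mnorm > 1e-8
        mixed[ok] /= mnorm[ok, None]
        turn_cos = np.einsum("ij,ij->i", mixed, prev[ia])
        ok &= turn_cos >= cos_gate - 1e-12
        step_pos = pos[ia] + params.step_mm * mixed
        for j, gi in enumerate(ia):
            if ok[j]:
                out[gi].append(step_pos[j])
        pos[ia[ok]] = step_pos[ok]
        prev[ia[ok]] = mixed[ok]
        remaining[ia] -= params.step_mm
        active[ia] = ok & (remaining[ia] >= params.step_mm - 1e-12)
    return [np.array(p).reshape(-1, 3) for p in out]


def track_streamlines(field_: OrientationField, params: TrackingParams,
                      seed_mask: np.ndarray, chunk: int = 8192) -> StreamlineSet:
    """Bidirectional deterministic tracking from random sub-voxel seeds.

    Exactly ``params.seed_count`` seeds are drawn uniformly over the volume
    of ``seed_mask`` voxels (with replacement); each is tracked in both field
    polarities and the branches concatenated.  Streamlines shorter than
    ``min_length_mm`` are discarded; the combined length never exceeds
    ``max_length_mm``.
    """
    seed_mask = np.asarray(seed_mask, bool)
    if seed_mask.shape != tuple(field_.grid.shape):
        raise ValueError("seed mask shape must match the field grid")
    vox = np.argwhere(seed_mask)
    if len(vox) == 0:
        raise ValueError("seed mask is empty")
    if not np.any(field_.qa > 0):
        warnings.warn("orientation field is all-zero; no streamlines tracked",
                      stacklevel=2)
        return StreamlineSet([], [])

    rng = np.random.default_rng(params.rng_seed)
    choice = rng.integers(0, len(vox), size=params.seed_count)
    offsets = rng.uniform(-0.5, 0.5, size=(params.seed_count, 3))
    seeds_world = field_.grid.voxel_to_world(vox[choice] + offsets)

    streamlines: list[np.ndarray] = []
    for lo in range(0, params.seed_count, chunk):
        batch = seeds_world[lo:lo + chunk]
        nb = len(batch)
        nearest = field_.grid.round_to_indices(batch)
        inside = field_.grid.inside(nearest)
        nearest = np.clip(nearest, 0, np.asarray(field_.grid.shape) - 1)
        ref = field_.direction[nearest[:, 0], nearest[:, 1], nearest[:, 2]]
        zero_ref = np.linalg.norm(ref, axis=1) < 1e-8
        ref[zero_ref] = (0.0, 1.0, 0.0)
        vec, qa = _interpolate(field_, field_.grid.world_to_voxel(batch), ref)
        norms = np.linalg.norm(vec, axis=1)
        trackable = inside & (qa >= params.qa_threshold) & (qa > 0) & (norms > 1e-8)
        d0 = np.zeros((nb, 3))
        d0[trackable] = vec[trackable] / norms[trackable, None]

        budget_a = np.where(trackable, params.max_length_mm, 0.0)
        fwd = _track_branch(field_, batch, d0, budget_a, params)
        len_a = np.array([params.step_mm * len(p) for p in fwd])
        budget_b = np.maximum(params.max_length_mm - len_a, 0.0) * trackable
        bwd = _track_branch(field_, batch, -d0, budget_b, params)

        for i in range(nb):
            if not trackable[i]:
                continue
            pts = list(reversed(bwd[i])) + [batch[i]] + list(fwd[i])
            if len(pts) < 2:
                continue
            streamlines.append(np.asarray(pts))

    tracks = StreamlineSet(streamlines)
    lengths = tracks.lengths_mm()
    keep = [i for i, ln in enumerate(lengths)
            if params.min_length_mm <= ln <= params.max_length_mm + 1e-9]
    return StreamlineSet([tracks.streamlines[i] for i in keep],
                         [tracks.tags[i] for i in keep])


def filter_streamlines(tracks: StreamlineSet, roi_mask: np.ndarray,
                       grid: VolumeGrid, min_length_mm: float = 30.0,
                       max_length_mm: float = 300.0,
                       division: str | None = None) -> StreamlineSet:
    """Retain streamlines traversing the ROI with arc length in bounds.

    Retained streamlines are tagged with ``division`` when given (the
    seed-ROI combination defines the upper/lower subdivision).
    """
    from .atlas import streamline_voxels

    roi_mask = np.asarray(roi_mask, bool)
    if roi_mask.shape != tuple(grid.shape):
        raise ValueError("ROI mask shape must match its grid")
    if not np.any(roi_mask):
        warnings.warn("ROI mask is empty; no streamlines retained", stacklevel=2)
        return StreamlineSet([], [])
    keep_sl, keep_tags = [], []
    for sl, tag in zip(tracks.streamlines, tracks.tags):
        length = float(np.sum(np.linalg.norm(np.diff(sl, axis=0), axis=1)))
        if not (min_length_mm <= length <= max_length_mm):
            continue
        vox = streamline_voxels(sl, grid, clip=True)
        if len(vox) and np.any(roi_mask[vox[:, 0], vox[:, 1], vox[:, 2]]):
            new_tag = dict(tag)
            if division is not None:
                new_tag["division"] = division
            keep_sl.append(sl)
            keep_tags.append(new_tag)
    return StreamlineSet(keep_sl, keep_tags)
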