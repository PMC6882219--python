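"""Synthetic Meyer's-loop phantom cohorts with known ground truth.

The phantom emulates the geometry the atlas pipeline must reproduce: a
bundle that leaves an "LGN" point, turns sharply off an optic-tract-like
stub, fans while sweeping anteriorly around a "temporal horn" to a known
anterior apex, then runs posteriorly to two cortical target zones (upper and
lower divisions, ORu/ORl, in a twisting arrangement).  A cohort is a set of
smoothly deformed copies of one template bundle, each with its own
diffeomorphic transform and mapped landmarks, so every downstream
measurement has an exact truth to recover.

Centerlines are shape-preserving (PCHIP) splines through control points
LGN -> stub -> apex -> mid-return -> target.  PCHIP does not overshoot local
extrema at knots, so with zero jitter the anterior-most Y of the bundle
equals ``loop_apex_y`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.interpolate import PchipInterpolator

from .grid import VolumeGrid
from .streamlines import StreamlineSet
from .tracking import OrientationField
from .transforms import SpatialTransform

SIDES = ("left", "right")
_SIDE_INDEX = {"left": 0, "right": 1}


def _mirror(point, side: str) -> np.ndarray:
    """Left-side template coordinates mirrored about the X midline for 'right'."""
    p = np.asarray(point, float).copy()
    if side == "right":
        p[..., 0] = -p[..., 0]
    return p


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of the phantom bundle, per side.

    Geometry fields are dicts keyed by side.  Defaults place the template
    temporal tip 25 mm anterior to the loop apex (true dTM = 25 mm).
    """

    grid: VolumeGrid
    lgn_center: dict = field(default_factory=dict)
    temporal_tip: dict = field(default_factory=dict)
    loop_apex_y: dict = field(default_factory=dict)
    fan_half_angle: float = 12.0  # deg of fanning at the origin
    sharp_angle: float = 75.0  # deg between inflow stub and initial loop direction
    twist_gain: float = 4.0  # mm of ORu/ORl lateral crossover
    n_streamlines: int = 150  # per division, per side
    jitter_sd: float = 0.3  # mm per-point Gaussian noise
    rng_seed: int = 0

    # internal template geometry (left side; mirrored for right).  The loop
    # is a circular-arc hairpin around the "temporal horn": medial ascending
    # limb, apex at the top of the arc, lateral descending limb.  The radius
    # keeps the per-step tangent rotation small enough for an inertial
    # tracker to follow.
    loop_radius_mm: float = 12.0
    _apex_base: tuple = (-33.0, 25.0, -3.0)
    _mid_return: tuple = (-37.0, -12.0, 2.0)
    _target_upper: tuple = (-19.0, -45.0, 12.0)
    _target_lower: tuple = (-19.0, -45.0, -8.0)
    _twist_cross_y: float = -15.0
    _twist_width: float = 8.0
    _stub_mm: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lgn_center",
                           {s: np.asarray(self.lgn_center[s], float) for s in SIDES})
        object.__setattr__(self, "temporal_tip",
                           {s: np.asarray(self.temporal_tip[s], float) for s in SIDES})
        for side in SIDES:
            apex = float(self.loop_apex_y[side])
            if not (self.lgn_center[side][1] < apex < self.temporal_tip[side][1]):
                raise ValueError(
                    f"{side}: loop_apex_y={apex} must be anterior to the LGN "
                    f"(Y={self.lgn_center[side][1]}) and posterior to the temporal "
                    f"tip (Y={self.temporal_tip[side][1]})"
                )
        if not (0.0 < self.fan_half_angle < 90.0):
            raise ValueError("fan_half_angle must be in (0, 90) degrees")
        if self.n_streamlines < 1:
            raise ValueError("n_streamlines must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    @classmethod
    def default(cls, **overrides) -> "PhantomSpec":
        grid = overrides.pop("grid", None) or VolumeGrid.from_extent(
            (-52.0, -58.0, -30.0), (52.0, 56.0, 30.0), voxel_mm=1.5
        )
        geom = dict(
            lgn_center={"left": (-25.0, 0.0, 0.0), "right": (25.0, 0.0, 0.0)},
            temporal_tip={"left": (-32.0, 50.0, -8.0), "right": (32.0, 50.0, -8.0)},
            loop_apex_y={"left": 25.0, "right": 25.0},
        )
        geom.update({k: overrides.pop(k) for k in list(overrides)
                     if k in ("lgn_center", "temporal_tip", "loop_apex_y")})
        return cls(grid=grid, **geom, **overrides)

    def with_(self, **overrides) -> "PhantomSpec":
        return replace(self, **overrides)

    def true_dtm(self, side: str) -> float:
        """Template dTM: temporal-tip Y minus loop-apex Y, in mm."""
        return float(self.temporal_tip[side][1] - self.loop_apex_y[side])

    def apex_point(self, side: str) -> np.ndarray:
        """The template anterior-ridge point (noise-free apex knot)."""
        p = _mirror(self._apex_base, side)
        p[1] = self.loop_apex_y[side]
        return p


@dataclass
class CohortTruth:
    """Ground truth of a synthetic cohort for recovery experiments."""

    template_bundle: StreamlineSet
    transforms: list  # per-subject SpatialTransform (template -> subject)
    landmarks: list  # per-subject {side: {"lgn_center": p, "temporal_tip": p}}
    true_dtm: dict  # side -> template dTM mm
    subject_apex: list  # per-subject {side: transformed apex point}
    subject_dtm: list  # per-subject {side: transformed-tip-Y - transformed-apex-Y}

    def __post_init__(self) -> None:
        n = len(self.transforms)
        if not (len(self.landmarks) == len(self.subject_apex)
                == len(self.subject_dtm) == n):
            raise ValueError("per-subject truth lists must share one length")


# ------------------------------------------------------------------- bundles
def make_phantom_bundle(spec: PhantomSpec, side: str) -> StreamlineSet:
    """Generate the two-division phantom bundle for one side.

    Returns ``2 * n_streamlines`` polylines tagged with ``division``
    ("ORu"/"ORl") and ``side``.  Both divisions reuse the same fanning
    offsets, so with ``twist_gain = 0`` their per-slice X centroids agree
    exactly and the twist profile is flat.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    lgn = spec.lgn_center[side]
    apex = spec.apex_point(side)
    mid = _mirror(spec._mid_return, side)
    targets = {"ORu": _mirror(spec._target_upper, side),
               "ORl": _mirror(spec._target_lower, side)}

    # stub direction: the loop's initial XY heading rotated by the sharp angle
    u1 = apex[:2] - lgn[:2]
    u1 = u1 / np.linalg.norm(u1)
    # rotate toward the midline/anterior (optic-tract inflow from the chiasm)
    ang = np.radians(spec.sharp_angle) * (-1.0 if side == "left" else 1.0)
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    u0 = rot @ u1
    stub_end = lgn + spec._stub_mm * np.array([u0[0], u0[1], 0.0])

    # perturbation draws are shared by both sides: sides are exact mirrors
    rng_fan = np.random.default_rng([spec.rng_seed, 7])
    rng_noise = np.random.default_rng([spec.rng_seed, 11, _SIDE_INDEX[side]])
    n = spec.n_streamlines
    # coherent fan: one angular/radial draw per streamline, shared by divisions
    phi = rng_fan.uniform(0.0, 2.0 * np.pi, size=n)
    rad = np.sqrt(rng_fan.uniform(0.0, 1.0, size=n))
    rad[0] = 1.0  # one streamline per division rides the outer fan envelope
    r_apex = np.tan(np.radians(spec.fan_half_angle)) * np.linalg.norm(apex - lgn) * 0.5
    r_target = np.tan(np.radians(spec.fan_half_angle)) * np.linalg.norm(
        targets["ORu"] - lgn
    ) * 0.5
    msign = 1.0 if side == "left" else -1.0  # mirror fan X for exact symmetry
    fan_apex = np.stack([msign * r_apex * rad * np.cos(phi),
                         np.zeros(n),
                         r_apex * rad * np.sin(phi)], axis=1)
    fan_target = np.stack([msign * r_target * rad * np.cos(phi),
                           np.zeros(n),
                           r_target * rad * np.sin(phi)], axis=1)

    lateral_sign = -1.0 if side == "left" else 1.0  # world X of the lateral direction

    streamlines, tags = [], []
    for division, div_sign, dz in (("ORu", +1.0, +2.0), ("ORl", -1.0, -2.0)):
        target = targets[division]
        for i in range(n):
            dz_off = np.array([0.0, 0.0, dz])
            # hairpin knots on a circular arc around the "temporal horn".
            # Fanning thickens the loop radially *inward* only (delta <= 0,
            # zero for the envelope streamline rad=1), so with zero jitter
            # the bundle's anterior Y envelope is exactly loop_apex_y —
            # PCHIP's no-overshoot property pins the apex knot.
            horn = apex - np.array([0.0, spec.loop_radius_mm, 0.0])
            medial = 1.0 if side == "left" else -1.0  # +X is medial on the left
            delta = -r_apex * (1.0 - rad[i])
            z_fan = fan_apex[i][2]
            hairpin = [
                horn + (spec.loop_radius_mm + delta) * np.array(
                    [medial * np.cos(th), np.sin(th), 0.0])
                + np.array([0.0, 0.0, z_fan])
                for th in np.radians([20.0, 55.0, 90.0, 125.0, 160.0])
            ]
            knots = np.stack([
                lgn,
                stub_end,
                *(h + dz_off for h in hairpin),
                mid + 0.5 * fan_target[i] + dz_off,
                target + fan_target[i],
            ])
            t = np.concatenate([[0.0], np.cumsum(
                np.linalg.norm(np.diff(knots, axis=0), axis=1))])
            interp = PchipInterpolator(t, knots, axis=0)
            samples = np.union1d(np.arange(0.0, t[-1], 1.0), t)
            pts = interp(samples)
            # twisting arrangement: signed lateral offset crossing once
            # along Y, tapered to zero near the LGN so every streamline
            # still begins within 1 mm of the seed point
            lat = 0.5 * spec.twist_gain * np.tanh(
                (spec._twist_cross_y - pts[:, 1]) / spec._twist_width)
            taper = np.tanh(np.linalg.norm(pts - lgn, axis=1) / 10.0)
            pts[:, 0] += lateral_sign * div_sign * lat * taper
            if spec.jitter_sd > 0:
                # noise ramps in over the first millimetre so streamlines
                # begin exactly at the seed point
                noise = rng_noise.normal(0.0, spec.jitter_sd, size=pts.shape)
                arc = np.concatenate([[0.0], np.cumsum(
                    np.linalg.norm(np.diff(pts, axis=0), axis=1))])
                pts = pts + noise * np.minimum(arc, 1.0)[:, None]
            streamlines.append(pts)
            tags.append({"division": division, "side": side, "streamline": i})
    return StreamlineSet(streamlines, tags)


# --------------------------------------------------------------- rasterizing
def rasterize_orientation_field(bundle: StreamlineSet,
                                grid: VolumeGrid) -> OrientationField:
    """Rasterize a bundle into a single-peak orientation field.

    Per traversed voxel: direction = normalized mean of sign-aligned segment
    directions, QA = number of distinct traversing streamlines scaled so the
    maximum is 1.  Untraversed voxels carry QA 0 and a zero vector.
    """
    if len(bundle) == 0:
        raise ValueError("bundle is empty")
    pts = bundle.points
    ijk = grid.world_to_voxel(pts)
    if np.any(ijk < -0.5) or np.any(ijk > np.asarray(grid.shape) - 0.5):
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        raise ValueError(
            f"bundle extent X[{lo[0]:.1f},{hi[0]:.1f}] Y[{lo[1]:.1f},{hi[1]:.1f}] "
            f"Z[{lo[2]:.1f},{hi[2]:.1f}] mm exceeds the grid"
        )
    from .atlas import traversal_intervals

    vec_sum = np.zeros(tuple(grid.shape) + (3,))
    counts = np.zeros(grid.shape, dtype=np.int32)
    for sl in bundle:
        seg = np.diff(sl, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        dirs_seg = np.zeros_like(seg)
        ok = seg_len > 1e-12
        dirs_seg[ok] = seg[ok] / seg_len[ok, None]
        vox, seg_ids, inside = traversal_intervals(sl, grid)
        vox, seg_ids = vox[inside], seg_ids[inside]
        samp_dirs = dirs_seg[seg_ids]
        vi, vj, vk = vox[:, 0], vox[:, 1], vox[:, 2]
        ref = vec_sum[vi, vj, vk]
        ref_zero = np.linalg.norm(ref, axis=1) < 1e-12
        ref[ref_zero] = samp_dirs[ref_zero]
        sign = np.where(np.einsum("ij,ij->i", samp_dirs, ref) < 0, -1.0, 1.0)
        np.add.at(vec_sum, (vi, vj, vk), sign[:, None] * samp_dirs)
        uniq = np.unique(vox, axis=0)
        counts[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    qa = counts / counts.max()
    norms = np.linalg.norm(vec_sum, axis=-1)
    direction = np.zeros_like(vec_sum)
    nz = norms > 1e-12
    direction[nz] = vec_sum[nz] / norms[nz, None]
    # a voxel can be traversed yet have cancelling directions; keep QA where a
    # direction exists
    qa[~nz] = 0.0
    return OrientationField(grid=grid, direction=direction, qa=qa)


# -------------------------------------------------------------------- masks
def sphere_mask(grid: VolumeGrid, center, radius_mm: float) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within the sphere."""
    mesh = grid.voxel_center_mesh()
    return np.linalg.norm(mesh - np.asarray(center, float), axis=-1) <= radius_mm


def box_mask(grid: VolumeGrid, center, half_mm) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within the axis-aligned box."""
    mesh = grid.voxel_center_mesh()
    return np.all(np.abs(mesh - np.asarray(center, float))
                  <= np.asarray(half_mm, float), axis=-1)


def make_region_masks(spec: PhantomSpec, side: str, seed_radius_mm: float = 3.0,
                      roi_half_mm=(11.0, 8.0, 9.0)) -> dict:
    """Seed sphere at the LGN and ROI boxes at the two division termini.

    Returns ``{"seed_mask", "roi_upper_mask", "roi_lower_mask",
    "temporal_tip_landmark"}``; masks are pairwise disjoint by construction
    and checked.
    """
    grid = spec.grid
    seed = sphere_mask(grid, spec.lgn_center[side], seed_radius_mm)
    roi_u = box_mask(grid, _mirror(spec._target_upper, side), roi_half_mm)
    roi_l = box_mask(grid, _mirror(spec._target_lower, side), roi_half_mm)
    for a, b, names in ((seed, roi_u, "seed/roi_upper"),
                        (seed, roi_l, "seed/roi_lower"),
                        (roi_u, roi_l, "roi_upper/roi_lower")):
        if np.any(a & b):
            raise ValueError(f"region masks overlap: {names}")
    return {
        "seed_mask": seed,
        "roi_upper_mask": roi_u,
        "roi_lower_mask": roi_l,
        "temporal_tip_landmark": spec.temporal_tip[side].copy(),
    }


# --------------------------------------------------------------- transforms
def make_subject_transform(rng_seed: int, grid: VolumeGrid,
                           max_rot_deg: float = 3.0, max_scale_dev: float = 0.04,
                           max_shift_mm: float = 3.0, warp_amp_mm: float = 2.0,
                           warp_scale_mm: float = 15.0) -> SpatialTransform:
    """Random small diffeomorphic transform: affine plus smooth warp.

    The affine rotates (about the grid center) and scales within the given
    bounds, then translates.  The displacement field is Gaussian-smoothed
    noise with correlation length ``warp_scale_mm``, peak magnitude at most
    ``warp_amp_mm``, tapered to zero at the grid border; positivity of the
    Jacobian determinant is verified at every voxel.
    """
    for name, v in (("max_rot_deg", max_rot_deg), ("max_scale_dev", max_scale_dev),
                    ("max_shift_mm", max_shift_mm), ("warp_amp_mm", warp_amp_mm)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    rng = np.random.default_rng(rng_seed)
    angles = np.radians(rng.uniform(-max_rot_deg, max_rot_deg, size=3))
    scales = 1.0 + rng.uniform(-max_scale_dev, max_scale_dev, size=3)
    shift = rng.uniform(-max_shift_mm, max_shift_mm, size=3)
    from .atlas import _euler_rotation

    center = grid.voxel_to_world((np.asarray(grid.shape) - 1) / 2.0)
    rs = _euler_rotation(*angles) @ np.diag(scales)
    affine = np.eye(4)
    affine[:3, :3] = rs
    affine[:3, 3] = shift + center - rs @ center

    displacement = None
    if warp_amp_mm > 0:
        sigma_vox = warp_scale_mm / grid.voxel_sizes
        noise = rng.normal(size=tuple(grid.shape) + (3,))
        smooth = np.stack(
            [ndimage.gaussian_filter(noise[..., c], sigma=sigma_vox, mode="constant")
             for c in range(3)], axis=-1)
        taper = np.ones(grid.shape)
        for ax, size in enumerate(grid.shape):
            ramp = np.minimum(np.arange(size), np.arange(size)[::-1])
            w = np.clip(ramp / 10.0, 0.0, 1.0)
            w = w * w * (3.0 - 2.0 * w)  # smoothstep: C1 border taper
            taper *= w.reshape([-1 if a == ax else 1 for a in range(3)])
        smooth *= taper[..., None]
        mag = np.linalg.norm(smooth, axis=-1).max()
        if mag > 0:
            smooth *= warp_amp_mm / mag
        displacement = smooth

    t = SpatialTransform(affine=affine, displacement=displacement,
                         displacement_grid=grid if displacement is not None else None,
                         metadata=f"synthetic subject transform (seed {rng_seed})")
    if t.min_jacobian_det() <= 0:
        raise ValueError(
            "generated warp is not diffeomorphic (non-positive Jacobian); "
            "reduce warp_amp_mm or increase warp_scale_mm"
        )
    return t


# ------------------------------------------------------------------- cohort
def make_cohort(n_subjects: int, spec: PhantomSpec, rng_seed: int = 0,
                identity_transforms: bool = False,
                sides=SIDES, **transform_kw):
    """Generate a phantom cohort with known ground truth.

    Each subject is the template bundle pushed through its own random
    diffeomorphic transform and rasterized on the template grid; landmarks
    travel through the same transform.  Returns ``(truth, subjects)`` where
    ``subjects`` is a list of per-subject dicts with keys ``bundle``,
    ``field``, ``masks`` (per side) and ``transform``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    per_side = [make_phantom_bundle(spec, side) for side in sides]
    template = StreamlineSet(
        [sl for b in per_side for sl in b.streamlines],
        [t for b in per_side for t in b.tags],
    )

    transforms, landmarks, subj_apex, subj_dtm, subjects = [], [], [], [], []
    for i in range(n_subjects):
        if identity_transforms:
            t = SpatialTransform.identity()
        else:
            t = make_subject_transform(rng_seed=int(rng_seed) * 1000 + i,
                                       grid=spec.grid, **transform_kw)
        transforms.append(t)
        lm, apx, dtm = {}, {}, {}
        for side in sides:
            lgn_i = t(spec.lgn_center[side])
            tip_i = t(spec.temporal_tip[side])
            apex_i = t(spec.apex_point(side))
            lm[side] = {"lgn_center": lgn_i, "temporal_tip": tip_i}
            apx[side] = apex_i
            dtm[side] = float(tip_i[1] - apex_i[1])
        landmarks.append(lm)
        subj_apex.append(apx)
        subj_dtm.append(dtm)

        bundle_i = template.map_points(t.apply_to_points).with_tag(subject=i)
        field_i = rasterize_orientation_field(bundle_i, spec.grid)
        masks_i = {}
        for side in sides:
            masks_i[side] = {
                "seed_mask": sphere_mask(spec.grid, lm[side]["lgn_center"], 3.0),
                "roi_upper_mask": box_mask(
                    spec.grid, t(_mirror(spec._target_upper, side)),
                    (11.0, 8.0, 9.0)),
                "roi_lower_mask": box_mask(
                    spec.grid, t(_mirror(spec._target_lower, side)),
                    (11.0, 8.0, 9.0)),
                "temporal_tip_landmark": lm[side]["temporal_tip"],
            }
        subjects.append({"bundle": bundle_i, "field": field_i,
                         "masks": masks_i, "transform": t})

    truth = CohortTruth(
        template_bundle=template,
        transforms=transforms,
        landmarks=landmarks,
        true_dtm={side: spec.true_dtm(side) for side in sides},
        subject_apex=subj_apex,
        subject_dtm=subj_dtm,
    )
    return truth, subjects
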