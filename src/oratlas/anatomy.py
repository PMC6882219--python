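"""Geometric measurements of the optic-radiation atlas.

Quantifies the surgically relevant geometry: the anterior ridge of Meyer's
loop, the dTM (anterior temporal tip to anterior ridge, along the
anterior-posterior axis), the LGN-to-ridge distance, and the twisting
arrangement of the upper (ORu) and lower (ORl) divisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import DIVISION_LABELS, LabelVolume, side_labels
from .streamlines import StreamlineSet

_MIDLINE_X = 0.0


@dataclass
class GeometryReport:
    """Per-side geometry of the bundle."""

    side: str
    anterior_ridge: np.ndarray  # world point
    dtm_mm: float
    lgn_to_ridge_mm: float
    twist_diff_mm: np.ndarray = field(default_factory=lambda: np.empty(0))
    twist_slab_y: np.ndarray = field(default_factory=lambda: np.empty(0))
    twist_sign_changes: int | None = 0  # None when a division is absent

    def summary(self) -> str:
        r = self.anterior_ridge
        return "\n".join([
            f"Geometry ({self.side} side)",
            "-" * 40,
            f"anterior ridge  : ({r[0]:.1f}, {r[1]:.1f}, {r[2]:.1f}) mm",
            f"dTM             : {self.dtm_mm:.2f} mm",
            f"LGN -> ridge    : {self.lgn_to_ridge_mm:.2f} mm",
            f"twist crossings : {self.twist_sign_changes}",
        ])


def _side_points(obj, side: str) -> np.ndarray:
    """World points of one side from a streamline set or a label volume."""
    if isinstance(obj, StreamlineSet):
        sub = obj.select(side=side)
        if len(sub) == 0:
            raise ValueError(f"no streamlines tagged side={side!r}")
        return sub.points
    if isinstance(obj, LabelVolume):
        idx = np.argwhere(np.isin(obj.labels, side_labels(side)))
        if len(idx) == 0:
            raise ValueError(f"no labels on the {side} side")
        return obj.grid.voxel_to_world(idx)
    raise TypeError(f"expected StreamlineSet or LabelVolume, got {type(obj).__name__}")


def anterior_ridge(obj, side: str, lgn_y: float) -> np.ndarray:
    """Most anterior point of the Meyer's-loop portion of the bundle.

    The loop portion is everything anterior to the LGN coronal plane
    (``Y > lgn_y``); the ridge is its point of maximal world Y, ties broken
    toward the midline.  Works on streamline vertices or labeled voxel
    centers.
    """
    pts = _side_points(obj, side)
    ml = pts[pts[:, 1] > lgn_y]
    if len(ml) == 0:
        raise ValueError(
            f"no points anterior to the LGN plane (Y={lgn_y}); "
            "the side has no Meyer's-loop portion"
        )
    y_max = ml[:, 1].max()
    cand = ml[ml[:, 1] >= y_max - 1e-9]
    return cand[np.argmin(np.abs(cand[:, 0] - _MIDLINE_X))].copy()


def measure_dtm(temporal_tip, ridge, euclidean: bool = False) -> float:
    """dTM in mm: temporal-tip to anterior-ridge distance.

    Default is the anterior-posterior (Y) coordinate difference, matching the
    surgical "distance behind the temporal pole" convention; ``euclidean``
    switches to the straight-line distance.
    """
    tip = np.asarray(temporal_tip, float)
    rdg = np.asarray(ridge, float)
    if euclidean:
        return float(np.linalg.norm(tip - rdg))
    return float(tip[1] - rdg[1])


def lgn_to_ridge_distance(lgn_center, ridge) -> float:
    """Euclidean distance from the LGN center to the anterior ridge, mm."""
    a, b = np.asarray(lgn_center, float), np.asarray(ridge, float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("points must be finite")
    return float(np.linalg.norm(a - b))


def _division_points(obj, side: str, division: str) -> np.ndarray:
    if isinstance(obj, StreamlineSet):
        sub = obj.select(side=side, division=division)
        return sub.points if len(sub) else np.empty((0, 3))
    if isinstance(obj, LabelVolume):
        lab = DIVISION_LABELS[(side, division)]
        idx = np.argwhere(obj.labels == lab)
        return obj.grid.voxel_to_world(idx) if len(idx) else np.empty((0, 3))
    raise TypeError(f"expected StreamlineSet or LabelVolume, got {type(obj).__name__}")


def twist_profile(obj, side: str, slice_step_mm: float = 3.0,
                  dead_band_mm: float = 0.25) -> dict:
    """ORu-vs-ORl lateral centroid difference along the AP axis.

    For each Y slab of width ``slice_step_mm`` over the joint extent, the
    signed medial-to-lateral difference of the division centroids is emitted
    (positive = ORu lateral to ORl, with "lateral" pointing away from the X
    midline).  Sign changes are counted over slabs containing both divisions,
    ignoring differences below ``dead_band_mm`` (centroid noise).
    """
    if slice_step_mm <= 0:
        raise ValueError("slice_step_mm must be positive")
    pts_u = _division_points(obj, side, "ORu")
    pts_l = _division_points(obj, side, "ORl")
    if len(pts_u) == 0 or len(pts_l) == 0:
        raise ValueError(f"both divisions must be present on the {side} side")
    lateral = -1.0 if side == "left" else 1.0
    y_all = np.concatenate([pts_u[:, 1], pts_l[:, 1]])
    y_lo, y_hi = float(y_all.min()), float(y_all.max())
    edges = np.arange(y_lo, y_hi + slice_step_mm, slice_step_mm)
    slab_y, diffs = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_u = (pts_u[:, 1] >= lo) & (pts_u[:, 1] < hi)
        in_l = (pts_l[:, 1] >= lo) & (pts_l[:, 1] < hi)
        if not (np.any(in_u) and np.any(in_l)):
            continue
        cu = pts_u[in_u, 0].mean()
        cl = pts_l[in_l, 0].mean()
        slab_y.append(0.5 * (lo + hi))
        diffs.append(lateral * (cu - cl))
    diffs_arr = np.asarray(diffs)
    signs = np.sign(diffs_arr[np.abs(diffs_arr) >= dead_band_mm])
    sign_changes = int(np.sum(np.abs(np.diff(signs)) > 0)) if len(signs) else 0
    return {
        "slab_y_mm": np.asarray(slab_y),
        "lateral_diff_mm": diffs_arr,
        "sign_changes": sign_changes,
    }


def measure_geometry(obj, side: str, lgn_center, temporal_tip,
                     slice_step_mm: float = 3.0) -> GeometryReport:
    """Full geometry report for one side from tracks or a label volume."""
    lgn = np.asarray(lgn_center, float)
    ridge = anterior_ridge(obj, side, lgn_y=float(lgn[1]))
    try:
        twist = twist_profile(obj, side, slice_step_mm=slice_step_mm)
    except ValueError:  # single-division input: twist is undefined, not fatal
        twist = {"lateral_diff_mm": np.empty(0), "slab_y_mm": np.empty(0),
                 "sign_changes": None}
    return GeometryReport(
        side=side,
        anterior_ridge=ridge,
        dtm_mm=measure_dtm(temporal_tip, ridge),
        lgn_to_ridge_mm=lgn_to_ridge_distance(lgn, ridge),
        twist_diff_mm=twist["lateral_diff_mm"],
        twist_slab_y=twist["slab_y_mm"],
        twist_sign_changes=twist["sign_changes"],
    )
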