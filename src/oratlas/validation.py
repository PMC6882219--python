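"""Accuracy machinery for atlas-label validation.

The headline statistic is the correspondence rate (CR): the fraction of
maximal-tract-density voxels — per coronal slice, inside the middle third of
the bundle's anterior-posterior extent — that fall inside the atlas-labeled
region.  Around it sit the shift-tolerance profile ("cyber intervals" of
simulated lateral registration error), a bootstrap test of the cohort mean
CR, the 5-mm surgical safety-zone check, and the one-sample-t sample-size
calculation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .atlas import LabelVolume, TDIVolume, side_labels
from .grid import VolumeGrid
from .transforms import SpatialTransform, resample_labels

AP_AXIS = 1  # anterior-posterior = world Y in the RAS+ convention
LR_AXIS = 0  # left-right = world X


@dataclass
class CRReport:
    """Cohort-level correspondence-rate report."""

    per_side_cr: dict  # (subject, side) -> CR in [0, 1]
    mean: float
    sd: float
    ci: tuple  # bootstrap CI of the mean at `confidence`
    confidence: float
    mean_inside_ci: bool
    tolerable_profile: list = field(default_factory=list)  # (offset_mm, CR)
    tolerable_cr: float | None = None
    safety_pass: dict = field(default_factory=dict)  # (subject, side) -> bool

    def summary(self) -> str:
        lines = [
            "Correspondence-rate report",
            "-" * 40,
            f"sides evaluated : {len(self.per_side_cr)}",
            f"CR mean +/- SD  : {100 * self.mean:.2f}% +/- {100 * self.sd:.2f}%",
            f"{int(self.confidence * 100)}% bootstrap CI of mean : "
            f"[{100 * self.ci[0]:.2f}%, {100 * self.ci[1]:.2f}%]"
            f" (mean inside: {self.mean_inside_ci})",
        ]
        if self.tolerable_cr is not None:
            lines.append(f"tolerable CR    : {100 * self.tolerable_cr:.2f}%")
        if self.safety_pass:
            n_ok = sum(self.safety_pass.values())
            lines.append(f"safety zone     : {n_ok}/{len(self.safety_pass)} sides pass")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "per_side_cr": {f"{s}/{side}": v
                            for (s, side), v in self.per_side_cr.items()},
            "mean": self.mean, "sd": self.sd,
            "ci": list(self.ci), "confidence": self.confidence,
            "mean_inside_ci": bool(self.mean_inside_ci),
            "tolerable_profile": [list(p) for p in self.tolerable_profile],
            "tolerable_cr": self.tolerable_cr,
            "safety_pass": {f"{s}/{side}": bool(v)
                            for (s, side), v in self.safety_pass.items()},
        }


# ------------------------------------------------------------------- slabs
def _side_halfspace(grid: VolumeGrid, side: str) -> np.ndarray:
    x = grid.voxel_center_mesh()[..., 0]
    return x < 0 if side == "left" else x > 0


def _nonzero_side_mask(region, side: str) -> np.ndarray:
    if isinstance(region, LabelVolume):
        return region.mask(side)
    if isinstance(region, TDIVolume):
        return (region.counts > 0) & _side_halfspace(region.grid, side)
    raise TypeError(f"expected LabelVolume or TDIVolume, got {type(region).__name__}")


def middle_third_slab(region, side: str) -> np.ndarray:
    """Mask of the middle third of the side's anterior-posterior (Y) extent.

    The middle third of the bundle has the simplest anatomy (no loop, no
    terminal fanning), which is why the CR is evaluated there.
    """
    nz = _nonzero_side_mask(region, side)
    if not np.any(nz):
        raise ValueError(f"region is empty on the {side} side")
    grid = region.grid
    y = grid.voxel_center_mesh()[..., AP_AXIS]
    y_nz = y[nz]
    y_min, y_max = float(y_nz.min()), float(y_nz.max())
    third = (y_max - y_min) / 3.0
    slab = (y >= y_min + third) & (y <= y_min + 2.0 * third)
    return slab & _side_halfspace(grid, side)


def max_density_voxels(tdi: TDIVolume, slab: np.ndarray,
                       mode: str = "per_slice",
                       top_fraction: float = 0.02) -> np.ndarray:
    """Voxels of maximal tract density within the slab.

    ``per_slice`` (default): for every coronal slice intersecting the slab,
    all voxels attaining that slice's maximum TDI (ties included); the union
    over slices is returned as an (N, 3) index array.  ``global``: the top
    ``top_fraction`` of suprathreshold slab voxels by count.
    """
    slab = np.asarray(slab, bool)
    if slab.shape != tuple(tdi.grid.shape):
        raise ValueError("slab shape must match the TDI grid")
    counts = np.where(slab, tdi.counts, 0)
    if counts.max() == 0:
        raise ValueError("slab contains no nonzero tract density")
    if mode == "global":
        vals = counts[counts > 0]
        k = max(int(np.ceil(top_fraction * vals.size)), 1)
        thr = np.partition(vals, -k)[-k]
        return np.argwhere(counts >= thr)
    if mode != "per_slice":
        raise ValueError(f"unknown mode {mode!r}")
    out = []
    for j in range(tdi.grid.shape[AP_AXIS]):
        sl = counts[:, j, :]
        m = sl.max()
        if m == 0:
            continue
        ik = np.argwhere(sl == m)
        idx = np.empty((len(ik), 3), dtype=int)
        idx[:, 0], idx[:, AP_AXIS], idx[:, 2] = ik[:, 0], j, ik[:, 1]
        out.append(idx)
    return np.concatenate(out, axis=0)


def correspondence_rate(max_voxels: np.ndarray, labels: LabelVolume,
                        side: str) -> float:
    """Fraction of max-density voxels falling inside the side's labels."""
    max_voxels = np.asarray(max_voxels, int)
    if max_voxels.size == 0:
        raise ValueError("max_voxels is empty")
    vals = labels.labels[max_voxels[:, 0], max_voxels[:, 1], max_voxels[:, 2]]
    return float(np.mean(np.isin(vals, side_labels(side))))


# ----------------------------------------------------------- shift profile
def shift_labels(labels: LabelVolume, offset_mm: float,
                 axis: int = LR_AXIS) -> LabelVolume:
    """Translate a label volume by ``offset_mm`` along a world axis."""
    shift = np.zeros(3)
    shift[axis] = offset_mm
    # pull-back: the shifted volume reads its value from `p - offset`
    t = SpatialTransform.from_translation(-shift)
    return resample_labels(labels, t, labels.grid)


def shifted_cr_profile(tdi: TDIVolume, labels: LabelVolume, side: str,
                       max_offset_mm: float = 12.0, step_mm: float | None = None,
                       axis: int = LR_AXIS, mode: str = "per_slice") -> dict:
    """CR under simulated lateral registration error ("cyber intervals").

    Labels are translated left/right in steps (default one voxel) and the CR
    recomputed at each offset.  The tolerable CR is, per direction, the CR at
    the largest offset at which the max-density voxels still intersect the
    shifted label; it is None (flagged) when no intersection/non-intersection
    transition occurs within range.
    """
    if step_mm is None:
        step_mm = float(labels.grid.voxel_sizes[axis])
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    slab = middle_third_slab(tdi, side)
    mv = max_density_voxels(tdi, slab, mode=mode)
    n_steps = int(np.floor(max_offset_mm / step_mm + 1e-9))
    offsets = np.arange(-n_steps, n_steps + 1) * step_mm
    crs = np.array([
        correspondence_rate(mv, shift_labels(labels, o, axis=axis), side)
        for o in offsets
    ])
    tolerable = {}
    for direction, sign in (("negative", -1), ("positive", +1)):
        dir_offsets = offsets[np.sign(offsets) == sign]
        dir_crs = crs[np.sign(offsets) == sign]
        order = np.argsort(np.abs(dir_offsets))
        touched = None
        transition = False
        for i in order:
            if dir_crs[i] > 0:
                touched = (float(dir_offsets[i]), float(dir_crs[i]))
            else:
                transition = touched is not None or dir_crs[order[0]] == 0
                break
        else:
            transition = False
        tolerable[direction] = touched if transition else None
    defined = [v[1] for v in tolerable.values() if v is not None]
    return {
        "offsets_mm": offsets,
        "cr": crs,
        "tolerable_per_direction": tolerable,
        "tolerable_cr": float(np.mean(defined)) if defined else None,
        "max_voxels": mv,
    }


# ---------------------------------------------------------------- bootstrap
def bootstrap_mean_ci(cr_values, n_boot: int = 10_000, confidence: float = 0.95,
                      rng_seed: int = 0) -> tuple[float, float, bool]:
    """Percentile bootstrap CI of the mean; flag = observed mean inside it.

    With the stock settings this resamples the per-side CR sample 10,000
    times at 95% confidence.
    """
    vals = np.asarray(cr_values, float)
    if vals.size < 2:
        raise ValueError("need at least two CR values to bootstrap")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
    means = vals[idx].mean(axis=1)
    alpha = (1.0 - confidence) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    m = float(vals.mean())
    return float(lo), float(hi), bool(lo <= m <= hi)


# -------------------------------------------------------------- safety zone
def safety_zone_check(labels: LabelVolume, side: str, max_voxels: np.ndarray,
                      margin_mm: float = 5.0) -> tuple[bool, np.ndarray]:
    """Do all max-density voxels lie within ``margin_mm`` of the labels?

    The margin mask is the side's label mask dilated by Euclidean distance
    (in world mm); the flag is the surgical-safety criterion: even where CR
    drops, the maximal-density voxels must stay inside this zone.
    """
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")
    mask = labels.mask(side)
    if not np.any(mask):
        raise ValueError(f"no labels on the {side} side")
    dist = ndimage.distance_transform_edt(~mask, sampling=labels.grid.voxel_sizes)
    margin_mask = dist <= margin_mm + 1e-9
    mv = np.asarray(max_voxels, int)
    flag = bool(np.all(margin_mask[mv[:, 0], mv[:, 1], mv[:, 2]]))
    return flag, margin_mask


# -------------------------------------------------------------- sample size
def one_sample_t_power(n: int, effect_size: float, alpha: float = 0.05) -> float:
    """Exact power of the two-sided one-sample t-test via the noncentral t.

    ``effect_size`` is Cohen's d: |alt_mean - null_mean| / sd.
    """
    if n < 2:
        return 0.0
    df = n - 1
    ncp = abs(effect_size) * np.sqrt(n)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    # P(T' > c) + P(T' < -c); the lower tail is written via the ncp symmetry
    # P(T'(ncp) < -c) = P(T'(-ncp) > c) because nct.cdf underflows to NaN for
    # large noncentrality at small df
    upper = stats.nct.sf(tcrit, df, ncp)
    lower = stats.nct.sf(tcrit, df, -ncp)
    return float(upper + lower)


def required_sample_size(alt_mean: float, null_mean: float, sd: float,
                         alpha: float = 0.05, power: float = 0.90,
                         max_n: int = 1_000_000) -> int:
    """Smallest n (>= 2) giving the one-sample t-test the requested power.

    With the stock validation inputs (tested-CR mean 75%, tolerable-CR mean
    4%, SD 10%, alpha 0.05, power 0.90) this returns 3: three cases per group
    suffice.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if alt_mean == null_mean:
        raise ValueError("alt_mean must differ from null_mean")
    d = abs(alt_mean - null_mean) / sd
    lo, hi = 2, 2
    while one_sample_t_power(hi, d, alpha) < power:
        lo, hi = hi + 1, hi * 2
        if hi > max_n:
            raise ValueError(f"power {power} not reachable within n <= {max_n}")
    while lo < hi:
        mid = (lo + hi) // 2
        if one_sample_t_power(mid, d, alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    return int(lo)
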