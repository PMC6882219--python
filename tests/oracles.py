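"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by different algorithms than the
package (interval clipping instead of plane walking, exhaustive scans
instead of vectorized reductions, simulation instead of closed forms) so
agreement is evidence, not tautology.
"""

import numpy as np
from scipy import stats


def brute_force_tdi(tracks, grid):
    """TDI by per-voxel segment-box intersection (Liang-Barsky clipping)."""
    counts = np.zeros(grid.shape, dtype=int)
    centers = np.indices(grid.shape).reshape(3, -1).T.astype(float)
    for sl in tracks:
        vox_path = grid.world_to_voxel(sl)
        hit = np.zeros(len(centers), dtype=bool)
        for a, b in zip(vox_path[:-1], vox_path[1:]):
            d = b - a
            tmin = np.zeros(len(centers))
            tmax = np.ones(len(centers))
            ok = np.ones(len(centers), dtype=bool)
            for ax in range(3):
                lo = centers[:, ax] - 0.5 - a[ax]
                hi = centers[:, ax] + 0.5 - a[ax]
                if abs(d[ax]) < 1e-15:
                    ok &= (lo <= 0) & (0 <= hi)
                else:
                    t0, t1 = lo / d[ax], hi / d[ax]
                    tmin = np.maximum(tmin, np.minimum(t0, t1))
                    tmax = np.minimum(tmax, np.maximum(t0, t1))
            hit |= ok & (tmin <= tmax)
        counts += hit.reshape(grid.shape)
    return counts


def brute_force_slice_maxima(counts, slab):
    """Exhaustive per-coronal-slice argmax scan (ties included)."""
    out = set()
    masked = np.where(slab, counts, 0)
    for j in range(counts.shape[1]):
        m = masked[:, j, :].max()
        if m == 0:
            continue
        for i in range(counts.shape[0]):
            for k in range(counts.shape[2]):
                if masked[i, j, k] == m:
                    out.add((i, j, k))
    return out


def monte_carlo_power(n, alt, null, sd, alpha, n_sim, seed):
    """Power of the two-sided one-sample t-test by direct simulation."""
    rng = np.random.default_rng(seed)
    samples = rng.normal(alt, sd, size=(n_sim, n))
    t = (samples.mean(axis=1) - null) / (samples.std(axis=1, ddof=1) / np.sqrt(n))
    crit = stats.t.ppf(1 - alpha / 2, n - 1)
    return float(np.mean(np.abs(t) > crit))


def brute_force_sign_changes(bundle, side, step=3.0, tol=0.25):
    """Twist crossings by a plain per-slice centroid scan along Y."""
    pts_u = bundle.select(division="ORu").points
    pts_l = bundle.select(division="ORl").points
    lo = min(pts_u[:, 1].min(), pts_l[:, 1].min())
    hi = max(pts_u[:, 1].max(), pts_l[:, 1].max())
    signs = []
    y = lo
    while y < hi:
        in_u = (pts_u[:, 1] >= y) & (pts_u[:, 1] < y + step)
        in_l = (pts_l[:, 1] >= y) & (pts_l[:, 1] < y + step)
        if in_u.any() and in_l.any():
            diff = pts_u[in_u, 0].mean() - pts_l[in_l, 0].mean()
            if abs(diff) >= tol:
                signs.append(np.sign(diff))
        y += step
    return int(np.sum(np.abs(np.diff(signs)) > 0))
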