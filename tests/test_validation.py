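"""Correspondence-rate machinery, bootstrap, safety zone, sample size."""

import numpy as np
import pytest
from scipy import stats

import oratlas as oa
from oracles import brute_force_slice_maxima, monte_carlo_power
from oratlas.validation import one_sample_t_power


def bar_label_volume(grid, x_range=(-20, -5), y_range=(0, 30), z_range=(-5, 5),
                     label=1):
    mesh = grid.voxel_center_mesh()
    inside = np.ones(grid.shape, dtype=bool)
    for ax, (lo, hi) in enumerate([x_range, y_range, z_range]):
        inside &= (mesh[..., ax] >= lo) & (mesh[..., ax] <= hi)
    labels = np.where(inside, label, 0).astype(np.int16)
    return oa.LabelVolume(grid=grid, labels=labels)


@pytest.fixture(scope="module")
def bar_grid():
    return oa.VolumeGrid.from_extent((-30.0, -10.0, -10.0), (30.0, 40.0, 10.0), 1.0)


# ------------------------------------------------------------- middle third
def test_middle_third_slab_arithmetic(bar_grid):
    """A region spanning Y in [0, 30] has its middle third at Y in [10, 20]."""
    lab = bar_label_volume(bar_grid)
    slab = oa.middle_third_slab(lab, "left")
    y = bar_grid.voxel_center_mesh()[..., 1]
    assert y[slab].min() >= 10.0
    assert y[slab].max() <= 20.0
    # a uniform bar keeps one third of its voxels in the slab (+/- one slice)
    n_side = lab.mask("left").sum()
    per_slice = lab.mask("left")[:, 15, :].sum()
    assert abs((slab & lab.mask("left")).sum() - n_side / 3) <= per_slice
    assert (slab & lab.mask("left")).sum() <= n_side


def test_middle_third_empty_side_rejected(bar_grid):
    lab = bar_label_volume(bar_grid)
    with pytest.raises(ValueError, match="right"):
        oa.middle_third_slab(lab, "right")


# ------------------------------------------------------- max density voxels
def test_max_density_includes_ties():
    grid = oa.VolumeGrid.from_extent((0, 0, 0), (3, 0.5, 3), 1.0)
    counts = np.zeros(grid.shape, dtype=int)
    counts[0, 0, 0], counts[1, 0, 0], counts[2, 0, 0], counts[3, 0, 0] = 0, 3, 7, 7
    tdi = oa.TDIVolume(grid=grid, counts=counts)
    got = oa.max_density_voxels(tdi, np.ones(grid.shape, bool))
    got_set = set(map(tuple, got))
    assert (2, 0, 0) in got_set and (3, 0, 0) in got_set
    assert (1, 0, 0) not in got_set


def test_max_density_matches_brute_force(rng, tiny_grid):
    counts = rng.integers(0, 9, size=tiny_grid.shape)
    slab = rng.random(tiny_grid.shape) < 0.6
    if not np.any(np.where(slab, counts, 0)):
        counts[slab] = 1
    tdi = oa.TDIVolume(grid=tiny_grid, counts=counts)
    got = set(map(tuple, oa.max_density_voxels(tdi, slab)))
    assert got == brute_force_slice_maxima(counts, slab)


def test_max_density_all_zero_slab_rejected(tiny_grid):
    tdi = oa.TDIVolume(grid=tiny_grid, counts=np.zeros(tiny_grid.shape, int))
    with pytest.raises(ValueError, match="no nonzero"):
        oa.max_density_voxels(tdi, np.ones(tiny_grid.shape, bool))


# -------------------------------------------------------------------- CR
def test_cr_full_containment_and_miss(bar_grid):
    lab = bar_label_volume(bar_grid)
    inside = np.argwhere(lab.labels > 0)[:25]
    assert oa.correspondence_rate(inside, lab, "left") == 1.0
    outside = np.argwhere(lab.labels == 0)[:25]
    assert oa.correspondence_rate(outside, lab, "left") == 0.0


def test_cr_empty_set_rejected(bar_grid):
    with pytest.raises(ValueError, match="empty"):
        oa.correspondence_rate(np.empty((0, 3), int), bar_label_volume(bar_grid),
                               "left")


# ------------------------------------------------------------ shift profile
@pytest.fixture(scope="module")
def convex_fixture(bar_grid):
    lab = bar_label_volume(bar_grid)
    counts = np.zeros(bar_grid.shape, dtype=int)
    mask = lab.mask("left")
    # density peaked at the bar's X center, uniform elsewhere
    x = bar_grid.voxel_center_mesh()[..., 0]
    counts[mask] = np.maximum(10 - np.abs(x[mask] + 12.5).astype(int), 1)
    return oa.TDIVolume(grid=bar_grid, counts=counts), lab


def test_shift_profile_zero_offset_matches_cr(convex_fixture):
    tdi, lab = convex_fixture
    prof = oa.shifted_cr_profile(tdi, lab, "left", max_offset_mm=20.0)
    i0 = np.flatnonzero(prof["offsets_mm"] == 0.0)[0]
    slab = oa.middle_third_slab(tdi, "left")
    mv = oa.max_density_voxels(tdi, slab)
    assert prof["cr"][i0] == oa.correspondence_rate(mv, lab, "left")


def test_shift_profile_monotone_and_reaches_zero(convex_fixture):
    """On a convex bar, CR never increases with |offset| and hits 0 past the
    intersection transition."""
    tdi, lab = convex_fixture
    prof = oa.shifted_cr_profile(tdi, lab, "left", max_offset_mm=25.0)
    offs, crs = prof["offsets_mm"], prof["cr"]
    for sign in (-1, 1):
        sel = np.sign(offs) == sign
        ordered = crs[sel][np.argsort(np.abs(offs[sel]))]
        assert np.all(np.diff(ordered) <= 1e-12)
        assert ordered[-1] == 0.0
    assert prof["tolerable_cr"] is not None
    tol = prof["tolerable_per_direction"]
    assert tol["negative"] is not None and tol["positive"] is not None


def test_shift_profile_flags_missing_transition(convex_fixture):
    tdi, lab = convex_fixture
    prof = oa.shifted_cr_profile(tdi, lab, "left", max_offset_mm=2.0)
    assert prof["tolerable_cr"] is None


# ----------------------------------------------------------------- bootstrap
def test_bootstrap_constant_sample_degenerate():
    lo, hi, inside = oa.bootstrap_mean_ci([0.8, 0.8, 0.8], n_boot=500, rng_seed=3)
    assert lo == hi == pytest.approx(0.8)
    assert inside


def test_bootstrap_reproducible_and_contains_mean(rng):
    vals = rng.normal(0.85, 0.07, size=60).clip(0, 1)
    a = oa.bootstrap_mean_ci(vals, n_boot=10_000, rng_seed=7)
    b = oa.bootstrap_mean_ci(vals, n_boot=10_000, rng_seed=7)
    assert a == b
    assert a[0] <= vals.mean() <= a[1]


def test_bootstrap_ci_width_shrinks_with_sqrt_n(rng):
    widths = {}
    for n in (10, 40, 160):
        vals = rng.normal(0.8, 0.1, size=n)
        lo, hi, _ = oa.bootstrap_mean_ci(vals, n_boot=4000, rng_seed=5)
        widths[n] = hi - lo
    # quadrupling n roughly halves the CI width
    assert widths[40] < widths[10]
    assert widths[160] < widths[40]
    assert widths[160] < 0.45 * widths[10]


# --------------------------------------------------------------- safety zone
def test_safety_margin_zero_equals_full_containment(convex_fixture):
    tdi, lab = convex_fixture
    slab = oa.middle_third_slab(tdi, "left")
    mv = oa.max_density_voxels(tdi, slab)
    cr = oa.correspondence_rate(mv, lab, "left")
    flag, margin_mask = oa.safety_zone_check(lab, "left", mv, margin_mm=0.0)
    assert flag == (cr == 1.0)
    np.testing.assert_array_equal(margin_mask, lab.mask("left"))


def test_safety_zone_tolerates_3mm_mislocalization(convex_fixture):
    """The low-CR-but-safe patient scenario: a 3 mm label shift drops CR below
    1 while every max-density voxel stays within the 5 mm safety zone."""
    tdi, lab = convex_fixture
    shifted = oa.shift_labels(lab, 14.0)  # bar half-width 7.5 mm -> partial miss
    slab = oa.middle_third_slab(tdi, "left")
    mv = oa.max_density_voxels(tdi, slab)
    assert oa.correspondence_rate(mv, shifted, "left") < 1.0
    flag, _ = oa.safety_zone_check(shifted, "left", mv, margin_mm=5.0)
    assert not flag  # 14 mm is beyond any safety zone
    shifted3 = oa.shift_labels(lab, 3.0)
    flag3, _ = oa.safety_zone_check(shifted3, "left", mv, margin_mm=5.0)
    assert flag3


def test_safety_dilation_contains_label(convex_fixture):
    tdi, lab = convex_fixture
    mv = np.argwhere(lab.labels > 0)[:5]
    _, margin_mask = oa.safety_zone_check(lab, "left", mv, margin_mm=5.0)
    assert np.all(margin_mask[lab.mask("left")])


# --------------------------------------------------------------- sample size
def test_required_sample_size_stock_inputs():
    """Tested-CR mean 75%, tolerable-CR mean 4%, SD 10% -> three cases."""
    assert oa.required_sample_size(75.0, 4.0, 10.0, alpha=0.05, power=0.90) == 3


def test_power_matches_monte_carlo_oracle():
    for n in (2, 3, 4):
        exact = one_sample_t_power(n, effect_size=7.1, alpha=0.05)
        sim = monte_carlo_power(n, 75.0, 4.0, 10.0, 0.05, n_sim=20_000, seed=n)
        assert abs(exact - sim) < 0.02


def test_power_matches_statsmodels():
    from statsmodels.stats.power import TTestPower

    for n, d in [(5, 2.0), (10, 1.0), (25, 0.6)]:
        ours = one_sample_t_power(n, d)
        ref = TTestPower().power(effect_size=d, nobs=n, alpha=0.05,
                                 alternative="two-sided")
        assert abs(ours - ref) < 1e-6


def test_sample_size_limit_and_monotonicity():
    assert oa.required_sample_size(1e9, 0.0, 1.0) == 2
    sizes = [oa.required_sample_size(delta, 0.0, 10.0)
             for delta in (40.0, 20.0, 10.0, 5.0)]
    assert all(a <= b for a, b in zip(sizes, sizes[1:]))
    more_power = oa.required_sample_size(10.0, 0.0, 10.0, power=0.99)
    assert more_power >= oa.required_sample_size(10.0, 0.0, 10.0, power=0.80)


def test_sample_size_invalid_inputs():
    with pytest.raises(ValueError):
        oa.required_sample_size(5.0, 5.0, 1.0)
    with pytest.raises(ValueError):
        oa.required_sample_size(5.0, 4.0, 0.0)
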