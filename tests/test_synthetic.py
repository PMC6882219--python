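"""Phantom cohort generation: bundles, fields, masks, transforms, truth."""

import numpy as np
import pytest

import oratlas as oa
from oracles import brute_force_sign_changes
from oratlas.synthetic import make_subject_transform


# ------------------------------------------------------------------- bundles
def test_clean_bundle_reaches_apex_exactly(bundle_left_clean, clean_spec):
    """Zero jitter: the bundle's anterior Y envelope equals loop_apex_y."""
    for division in ("ORu", "ORl"):
        pts = bundle_left_clean.select(division=division).points
        assert pts[:, 1].max() == clean_spec.loop_apex_y["left"]


def test_bundle_counts_and_tags(bundle_left, default_spec):
    assert len(bundle_left) == 2 * default_spec.n_streamlines
    assert bundle_left.divisions() == {"ORu", "ORl"}
    assert {t["side"] for t in bundle_left.tags} == {"left"}


def test_bundle_starts_at_lgn(bundle_left, default_spec):
    lgn = default_spec.lgn_center["left"]
    starts = np.array([sl[0] for sl in bundle_left])
    assert np.all(np.linalg.norm(starts - lgn, axis=1) <= 1.0)


def test_bundle_determinism(default_spec):
    a = oa.make_phantom_bundle(default_spec, "left")
    b = oa.make_phantom_bundle(default_spec, "left")
    for sa, sb in zip(a.streamlines, b.streamlines):
        np.testing.assert_array_equal(sa, sb)


@pytest.mark.parametrize("twist_gain,expected", [(0.0, 0), (4.0, 1)])
def test_twist_sign_changes(clean_spec, twist_gain, expected):
    bundle = oa.make_phantom_bundle(clean_spec.with_(twist_gain=twist_gain), "left")
    assert brute_force_sign_changes(bundle, "left") == expected


def test_right_side_is_mirrored(clean_spec):
    left = oa.make_phantom_bundle(clean_spec, "left")
    right = oa.make_phantom_bundle(clean_spec, "right")
    for sl, sr in zip(left.streamlines, right.streamlines):
        np.testing.assert_allclose(sl * [-1, 1, 1], sr, atol=1e-9)


def test_degenerate_apex_rejected():
    with pytest.raises(ValueError, match="anterior"):
        oa.PhantomSpec.default(loop_apex_y={"left": -10.0, "right": 25.0})


# ----------------------------------------------------------- orientation field
def test_rasterize_straight_line_direction():
    grid = oa.VolumeGrid.from_extent((0, 0, 0), (10, 30, 10), 1.0)
    sl = np.array([[5.0, 2.0, 5.0], [5.0, 28.0, 5.0]])
    field = oa.rasterize_orientation_field(oa.StreamlineSet([sl]), grid)
    traversed = field.qa > 0
    assert traversed.sum() >= 25
    np.testing.assert_allclose(field.direction[traversed],
                               np.tile([0, 1, 0], (traversed.sum(), 1)))
    assert field.qa[traversed].max() == 1.0
    assert np.all(field.direction[~traversed] == 0)


def test_rasterize_qa_counts_streamlines():
    """QA of a voxel crossed by k streamlines equals k / max-count."""
    grid = oa.VolumeGrid.from_extent((0, 0, 0), (10, 30, 10), 1.0)
    shared = [np.array([[5.0, 2.0, 5.0], [5.0, 28.0, 5.0]]) for _ in range(3)]
    lone = [np.array([[2.0, 2.0, 2.0], [2.0, 28.0, 2.0]])]
    field = oa.rasterize_orientation_field(oa.StreamlineSet(shared + lone), grid)
    assert field.qa[5, 10, 5] == 1.0  # 3 / 3
    assert field.qa[2, 10, 2] == pytest.approx(1.0 / 3.0)


def test_rasterize_out_of_grid_rejected():
    grid = oa.VolumeGrid.from_extent((0, 0, 0), (5, 5, 5), 1.0)
    sl = np.array([[2.0, 2.0, 2.0], [50.0, 2.0, 2.0]])
    with pytest.raises(ValueError, match="exceeds the grid"):
        oa.rasterize_orientation_field(oa.StreamlineSet([sl]), grid)


# -------------------------------------------------------------------- masks
def test_region_masks_disjoint_and_sphere_volume(default_spec):
    masks = oa.make_region_masks(default_spec, "left", seed_radius_mm=3.0)
    seed, up, lo = (masks["seed_mask"], masks["roi_upper_mask"],
                    masks["roi_lower_mask"])
    assert not np.any(seed & up) and not np.any(seed & lo) and not np.any(up & lo)
    vox_vol = float(np.prod(default_spec.grid.voxel_sizes))
    expected = 4.0 / 3.0 * np.pi * 3.0**3 / vox_vol
    assert abs(seed.sum() - expected) <= 0.35 * expected  # coarse 1.5 mm grid
    assert masks["temporal_tip_landmark"][1] > default_spec.loop_apex_y["left"]


def test_region_masks_sphere_volume_fine_grid(default_spec):
    """On a 1 mm grid the seed-sphere voxel count is within 10% of the
    analytic sphere volume."""
    fine = default_spec.with_(grid=oa.VolumeGrid.from_extent(
        (-52.0, -58.0, -30.0), (52.0, 56.0, 30.0), 1.0))
    seed = oa.make_region_masks(fine, "left", seed_radius_mm=3.0)["seed_mask"]
    expected = 4.0 / 3.0 * np.pi * 27.0
    assert abs(seed.sum() - expected) <= 0.1 * expected


# --------------------------------------------------------------- transforms
def test_subject_transform_zero_amplitudes_is_identity(default_spec):
    t = make_subject_transform(0, default_spec.grid, max_rot_deg=0,
                               max_scale_dev=0, max_shift_mm=0, warp_amp_mm=0)
    np.testing.assert_allclose(t.affine, np.eye(4), atol=1e-12)
    assert not t.has_field


def test_subject_transform_respects_warp_bound(default_spec):
    t = make_subject_transform(3, default_spec.grid, warp_amp_mm=3.0)
    mags = np.linalg.norm(t.displacement, axis=-1)
    assert mags.max() <= 3.0 + 1e-9
    assert t.min_jacobian_det() > 0


def test_subject_transform_determinism(default_spec):
    a = make_subject_transform(9, default_spec.grid)
    b = make_subject_transform(9, default_spec.grid)
    np.testing.assert_array_equal(a.affine, b.affine)
    np.testing.assert_array_equal(a.displacement, b.displacement)


# ------------------------------------------------------------------- cohort
def test_single_identity_subject_equals_template(clean_spec):
    truth, subjects = oa.make_cohort(1, clean_spec, identity_transforms=True)
    template_field = oa.rasterize_orientation_field(truth.template_bundle,
                                                    clean_spec.grid)
    np.testing.assert_array_equal(subjects[0]["field"].qa, template_field.qa)
    np.testing.assert_array_equal(subjects[0]["field"].direction,
                                  template_field.direction)


def test_cohort_bookkeeping_and_apex_truth(default_spec):
    truth, subjects = oa.make_cohort(3, default_spec, rng_seed=2)
    assert len(truth.transforms) == len(subjects) == 3
    assert len(truth.landmarks) == 3
    affines = [t.affine for t in truth.transforms]
    assert not np.allclose(affines[0], affines[1])
    for i in range(3):
        for side in ("left", "right"):
            apex = truth.transforms[i](default_spec.apex_point(side))
            np.testing.assert_allclose(truth.subject_apex[i][side], apex)
            tip = truth.landmarks[i][side]["temporal_tip"]
            assert truth.subject_dtm[i][side] == pytest.approx(
                tip[1] - apex[1])
    assert truth.true_dtm["left"] == pytest.approx(25.0)
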