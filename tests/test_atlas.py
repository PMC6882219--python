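"""Atlas construction: merging, TDI, label assignment, rigid registration."""

import numpy as np
import pytest

import oratlas as oa
from oratlas.atlas import streamline_voxels


from oracles import brute_force_tdi


def random_tracks(rng, n, grid):
    tracks = []
    lo = grid.voxel_to_world((0, 0, 0))
    hi = grid.voxel_to_world(np.asarray(grid.shape) - 1)
    for _ in range(n):
        pts = rng.uniform(lo, hi, size=(rng.integers(2, 6), 3))
        tracks.append(pts)
    return oa.StreamlineSet(tracks)


# ---------------------------------------------------------------------- merge
def test_merge_concatenates_and_preserves_tags(rng, tiny_grid):
    groups = [
        random_tracks(rng, 4, tiny_grid).with_tag(subject=j) for j in range(30)
    ]
    merged = oa.merge_groups(groups)
    assert len(merged) == 30 * 4
    for j in (0, 7, 29):
        sub = merged.select(subject=j)
        assert len(sub) == 4
        for a, b in zip(sub.streamlines, groups[j].streamlines):
            np.testing.assert_array_equal(a, b)


def test_merge_single_group_is_identity(rng, tiny_grid):
    g = random_tracks(rng, 5, tiny_grid)
    merged = oa.merge_groups([g])
    assert len(merged) == 5
    for a, b in zip(merged.streamlines, g.streamlines):
        np.testing.assert_array_equal(a, b)


# ------------------------------------------------------------------------ TDI
def test_tdi_matches_brute_force_oracle(rng, tiny_grid):
    """Exact equivalence with an independent per-segment walk, 50 tracks, 20^3."""
    tracks = random_tracks(rng, 50, tiny_grid)
    tdi = oa.compute_tdi(tracks, tiny_grid)
    np.testing.assert_array_equal(tdi.counts, brute_force_tdi(tracks, tiny_grid))


def test_tdi_scales_with_identical_streamlines(tiny_grid):
    sl = np.array([[1.0, 1.0, 1.0], [10.0, 8.0, 3.0], [15.0, 15.0, 12.0]])
    one = oa.compute_tdi(oa.StreamlineSet([sl]), tiny_grid)
    assert set(np.unique(one.counts)) <= {0, 1}
    k = 7
    many = oa.compute_tdi(oa.StreamlineSet([sl.copy() for _ in range(k)]), tiny_grid)
    np.testing.assert_array_equal(many.counts, k * one.counts)


def test_tdi_reentering_voxel_counts_once(tiny_grid):
    # out-and-back path revisits its voxels; set semantics keep counts at 1
    sl = np.array([[2.0, 2.0, 2.0], [9.0, 2.0, 2.0], [2.5, 2.0, 2.0]])
    tdi = oa.compute_tdi(oa.StreamlineSet([sl]), tiny_grid)
    assert tdi.counts.max() == 1


def test_tdi_empty_tracks_all_zero(tiny_grid):
    tdi = oa.compute_tdi(oa.StreamlineSet([], []), tiny_grid)
    assert tdi.counts.sum() == 0


def test_tdi_sum_at_least_streamline_count(bundle_left, default_spec):
    tdi = oa.compute_tdi(bundle_left, default_spec.grid)
    assert tdi.counts.sum() >= len(bundle_left)


# --------------------------------------------------------------------- labels
def _line_set(points, **tag):
    return oa.StreamlineSet([np.asarray(points, float)], [tag])


def test_label_volume_basic_assignment(tiny_grid):
    up = _line_set([[2, 2, 10], [16, 2, 10]], subject=0)
    lo = _line_set([[2, 16, 4], [16, 16, 4]], subject=0)
    lab = oa.build_label_volume(
        {("left", "ORu"): up, ("left", "ORl"): lo}, tiny_grid)
    assert set(np.unique(lab.labels)) == {0, 1, 3}
    # voxel traversed only by the upper division carries label 1
    assert lab.labels[8, 2, 10] == 1
    assert lab.labels[8, 16, 4] == 3
    # untraversed voxel is background
    assert lab.labels[8, 8, 17] == 0


def test_label_tie_goes_to_upper_division(tiny_grid):
    """Equal subject support on a shared voxel resolves to ORu (lower label)."""
    path = [[2, 5, 5], [16, 5, 5]]
    lab = oa.build_label_volume(
        {("left", "ORu"): _line_set(path, subject=0),
         ("left", "ORl"): _line_set(path, subject=0)}, tiny_grid)
    traversed = lab.labels[np.array([5, 9]), 5, 5]
    assert set(traversed) == {1}


def test_label_overlap_resolved_by_subject_support(tiny_grid):
    path = [[2, 5, 5], [16, 5, 5]]
    two_subjects = oa.StreamlineSet(
        [np.asarray(path, float), np.asarray(path, float)],
        [{"subject": 0}, {"subject": 1}],
    )
    lab = oa.build_label_volume(
        {("left", "ORu"): _line_set(path, subject=0),
         ("left", "ORl"): two_subjects}, tiny_grid)
    assert lab.labels[9, 5, 5] == 3  # ORl supported by 2 subjects beats ORu's 1


def test_label_conservation(bundle_left, default_spec):
    """Nonzero labels exactly cover the union of division traversal masks."""
    grid = default_spec.grid
    division_map = {("left", d): bundle_left.select(division=d)
                    for d in ("ORu", "ORl")}
    lab = oa.build_label_volume(division_map, grid)
    union = np.zeros(grid.shape, dtype=bool)
    for tracks in division_map.values():
        for sl in tracks:
            vox = streamline_voxels(sl, grid)
            union[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    np.testing.assert_array_equal(lab.labels > 0, union)


def test_label_unknown_division_rejected(tiny_grid):
    with pytest.raises(ValueError, match="division"):
        oa.build_label_volume(
            {"left_OTHER": _line_set([[1, 1, 1], [5, 5, 5]])}, tiny_grid)


def test_min_subject_support_thresholds(tiny_grid):
    path = [[2, 5, 5], [16, 5, 5]]
    lab = oa.build_label_volume(
        {("left", "ORu"): _line_set(path, subject=0)}, tiny_grid,
        min_subject_support=2)
    assert lab.labels.sum() == 0


# --------------------------------------------------------- rigid registration
def _ellipsoid_labels(grid, center, radii, rot=np.eye(3)):
    mesh = grid.voxel_center_mesh()
    rel = (mesh - np.asarray(center, float)) @ rot
    inside = np.sum((rel / np.asarray(radii, float)) ** 2, axis=-1) <= 1.0
    return oa.LabelVolume(grid=grid, labels=inside.astype(np.int16))


@pytest.fixture(scope="module")
def reg_grid():
    return oa.VolumeGrid.from_extent((-40.0, -40.0, -40.0), (40.0, 40.0, 40.0), 2.0)


def test_rigid_self_registration_is_identity(reg_grid):
    lab = _ellipsoid_labels(reg_grid, (3.0, -2.0, 1.0), (22.0, 12.0, 6.0))
    t = oa.rigid_register_masks(lab, lab)
    rot = t.affine[:3, :3]
    angle = np.degrees(np.arccos(np.clip((np.trace(rot) - 1) / 2, -1, 1)))
    assert angle <= 0.1
    center = np.array([3.0, -2.0, 1.0])
    assert np.linalg.norm(t(center) - center) <= 0.1


def test_rigid_recovers_translation(reg_grid):
    fixed = _ellipsoid_labels(reg_grid, (5.0, 0.0, 0.0), (22.0, 12.0, 6.0))
    moving = _ellipsoid_labels(reg_grid, (0.0, 0.0, 0.0), (22.0, 12.0, 6.0))
    t = oa.rigid_register_masks(moving, fixed)
    shift = t(np.zeros(3))
    np.testing.assert_allclose(shift, [5.0, 0.0, 0.0], atol=0.5)


def _blob_labels(grid, rot=np.eye(3)):
    """Asymmetric two-lobe mask (no 180-degree self-symmetry)."""
    mesh = grid.voxel_center_mesh() @ rot
    lobe1 = np.sum((mesh / np.array([20.0, 10.0, 6.0])) ** 2, axis=-1) <= 1.0
    lobe2 = np.sum(((mesh - np.array([14.0, 8.0, 4.0])) / 7.0) ** 2, axis=-1) <= 1.0
    return oa.LabelVolume(grid=grid, labels=(lobe1 | lobe2).astype(np.int16))


def test_rigid_recovers_rotation(reg_grid):
    ang = np.radians(10.0)
    rz = np.array([[np.cos(ang), -np.sin(ang), 0],
                   [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
    fixed = _blob_labels(reg_grid, rot=rz)  # blob rotated about Z
    moving = _blob_labels(reg_grid)
    t = oa.rigid_register_masks(moving, fixed)
    rot = t.affine[:3, :3]
    angle = np.degrees(np.arccos(np.clip((np.trace(rot) - 1) / 2, -1, 1)))
    assert abs(angle - 10.0) <= 1.0


def test_rigid_degenerate_mask_rejected(reg_grid):
    lab = oa.LabelVolume(grid=reg_grid, labels=np.zeros(reg_grid.shape, np.int16))
    lab.labels[5, 5, 5] = 1
    with pytest.raises(ValueError, match="degenerate|larger"):
        oa.rigid_register_masks(lab, lab)
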