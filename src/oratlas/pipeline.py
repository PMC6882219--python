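"""End-to-end phantom study: cohort -> tracking -> atlas -> labeling -> validation.

This mirrors the full workflow the package implements: generate (or load) a
cohort of subjects, track each subject's optic radiation from the LGN seed
with division-specific ROIs, carry every subject's streamlines into the
common template space, merge them into the labeled group atlas and its
tract-density image, then label the atlas back onto each subject and score
the labeling with the correspondence-rate machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import anatomy, validation
from .atlas import (DIVISION_LABELS, LabelVolume, TDIVolume, build_label_volume,
                    compute_tdi, merge_groups)
from .streamlines import StreamlineSet
from .synthetic import SIDES, CohortTruth, PhantomSpec, make_cohort
from .tracking import OrientationField, TrackingParams, filter_streamlines, track_streamlines
from .transforms import resample_labels


def track_subject_side(field_: OrientationField, masks: dict, side: str,
                       params: TrackingParams) -> StreamlineSet:
    """Track one subject's bundle on one side and split it into divisions.

    Seeds sit in the LGN sphere; the upper/lower ROI boxes select the ORu and
    ORl subdivisions from the same tracking run (seed-ROI combinations).
    """
    tracks = track_streamlines(field_, params, masks["seed_mask"])
    grid = field_.grid
    parts = []
    for division, roi_key in (("ORu", "roi_upper_mask"), ("ORl", "roi_lower_mask")):
        parts.append(
            filter_streamlines(tracks, masks[roi_key], grid,
                               min_length_mm=params.min_length_mm,
                               max_length_mm=params.max_length_mm,
                               division=division).with_tag(side=side)
        )
    return merge_groups(parts)


@dataclass
class PhantomStudy:
    """Results of one full phantom pipeline run."""

    spec: PhantomSpec
    truth: CohortTruth
    atlas_labels: LabelVolume
    atlas_tdi: TDIVolume
    merged_tracks: StreamlineSet  # all subjects, template space
    subject_tracks: list  # per subject, subject space
    subject_tdi: list  # per subject TDIVolume, subject space
    subject_labels: list  # per subject LabelVolume (atlas labeled into subject)
    sides: tuple = SIDES
    params: TrackingParams = field(default_factory=TrackingParams)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_tracks)


def run_phantom_study(spec: PhantomSpec, n_subjects: int = 30, rng_seed: int = 0,
                      identity_transforms: bool = False,
                      tracking_params: TrackingParams | None = None,
                      sides=SIDES, min_subject_support: int = 1,
                      **transform_kw) -> PhantomStudy:
    """Run the whole pipeline on a synthetic cohort.

    Per subject and side the orientation field is tracked from the LGN seed;
    retained division streamlines are pulled back to the template space with
    the (known) inverse subject transform; the merged groups become the label
    atlas and TDI.  Each subject is then labeled by resampling the atlas
    through its own forward transform (pull-back from subject to template).
    """
    truth, subjects = make_cohort(n_subjects, spec, rng_seed=rng_seed,
                                  identity_transforms=identity_transforms,
                                  sides=sides, **transform_kw)
    base = tracking_params or TrackingParams(qa_threshold=0.001, seed_count=3000)

    division_groups: dict = {k: [] for k in DIVISION_LABELS
                             if DIVISION_LABELS[k] and k[0] in sides}
    subject_tracks, subject_tdi, template_groups = [], [], []
    for i, sub in enumerate(subjects):
        per_side = []
        for s_idx, side in enumerate(sides):
            params_i = TrackingParams(
                **{**base.__dict__, "rng_seed": base.rng_seed + 1000 * i + s_idx})
            per_side.append(
                track_subject_side(sub["field"], sub["masks"][side], side, params_i)
            )
        tracks_i = merge_groups(per_side).with_tag(subject=i)
        subject_tracks.append(tracks_i)
        subject_tdi.append(compute_tdi(tracks_i, spec.grid))
        inv = truth.transforms[i].invert()
        tracks_tpl = tracks_i.map_points(inv.apply_to_points)
        template_groups.append(tracks_tpl)
        for side in sides:
            for division in ("ORu", "ORl"):
                division_groups[(side, division)].append(
                    tracks_tpl.select(side=side, division=division))

    merged = merge_groups(template_groups)
    division_map = {key: merge_groups(groups)
                    for key, groups in division_groups.items()
                    if any(len(g) for g in groups)}
    atlas_labels = build_label_volume(division_map, spec.grid,
                                      min_subject_support=min_subject_support)
    atlas_tdi = compute_tdi(merged, spec.grid)

    subject_labels = [
        resample_labels(atlas_labels, truth.transforms[i].invert(), spec.grid)
        for i in range(n_subjects)
    ]
    return PhantomStudy(spec=spec, truth=truth, atlas_labels=atlas_labels,
                        atlas_tdi=atlas_tdi, merged_tracks=merged,
                        subject_tracks=subject_tracks, subject_tdi=subject_tdi,
                        subject_labels=subject_labels, sides=tuple(sides),
                        params=base)


def evaluate_study(study: PhantomStudy, margin_mm: float = 5.0,
                   n_boot: int = 10_000, confidence: float = 0.95,
                   rng_seed: int = 0,
                   shift_labels_mm: float = 0.0) -> validation.CRReport:
    """Correspondence-rate report over every (subject, side) of a study.

    ``shift_labels_mm`` applies a known lateral mislocalization to every
    subject's labels before scoring — the simulated registration-error
    scenario.
    """
    per_side_cr: dict = {}
    safety: dict = {}
    for i in range(study.n_subjects):
        tdi = study.subject_tdi[i]
        labels = study.subject_labels[i]
        if shift_labels_mm:
            labels = validation.shift_labels(labels, shift_labels_mm)
        for side in study.sides:
            slab = validation.middle_third_slab(tdi, side)
            mv = validation.max_density_voxels(tdi, slab)
            per_side_cr[(i, side)] = validation.correspondence_rate(mv, labels, side)
            safety[(i, side)], _ = validation.safety_zone_check(
                labels, side, mv, margin_mm=margin_mm)
    values = np.array(list(per_side_cr.values()))
    lo, hi, inside = validation.bootstrap_mean_ci(
        values, n_boot=n_boot, confidence=confidence, rng_seed=rng_seed)
    return validation.CRReport(
        per_side_cr=per_side_cr, mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        ci=(lo, hi), confidence=confidence, mean_inside_ci=inside,
        safety_pass=safety,
    )


def measure_study_geometry(study: PhantomStudy) -> list:
    """Per-subject, per-side geometry reports from the tracked streamlines."""
    out = []
    for i in range(study.n_subjects):
        per_side = {}
        for side in study.sides:
            lm = study.truth.landmarks[i][side]
            per_side[side] = anatomy.measure_geometry(
                study.subject_tracks[i], side,
                lgn_center=lm["lgn_center"], temporal_tip=lm["temporal_tip"])
        out.append(per_side)
    return out


def tdi_density_contrast(study: PhantomStudy, side: str = "left",
                         anterior_band_mm: float = 3.0) -> dict:
    """Mean merged-cohort TDI in the anterior-extension band vs the body.

    The anterior extension of the loop — the band within ``anterior_band_mm``
    of the side's anterior envelope — is reached only by the outermost fibers
    of each subject and by the anteriorly-shifted subjects of the cohort, so
    it collects fewer merged tracts per voxel than the bundle body (the
    middle third): the qualitative density dip at the anterior extension.
    """
    tdi = study.atlas_tdi
    mesh = tdi.grid.voxel_center_mesh()
    y = mesh[..., 1]
    halfspace = mesh[..., 0] < 0 if side == "left" else mesh[..., 0] > 0
    nz = (tdi.counts > 0) & halfspace
    apex_slab = nz & (y > y[nz].max() - anterior_band_mm)
    body = validation.middle_third_slab(tdi, side) & nz
    if not (np.any(apex_slab) and np.any(body)):
        raise ValueError("apex or body slab is empty")
    return {
        "apex_mean_tracts": float(tdi.counts[apex_slab].mean()),
        "body_mean_tracts": float(tdi.counts[body].mean()),
    }


def tracker_recall(study: PhantomStudy, subject: int = 0) -> float:
    """Voxel-set recall of one subject's tracking against its true bundle.

    Fraction of voxels of the rasterized true bundle that are traversed by
    the retained tracked streamlines.
    """
    from .atlas import streamline_voxels

    grid = study.spec.grid
    truth_vox = set()
    bundle = study.truth.template_bundle.map_points(
        study.truth.transforms[subject].apply_to_points)
    for sl in bundle:
        truth_vox.update(map(tuple, streamline_voxels(sl, grid)))
    got = set()
    for sl in study.subject_tracks[subject]:
        got.update(map(tuple, streamline_voxels(sl, grid)))
    if not truth_vox:
        raise ValueError("true bundle rasterizes to no voxels")
    return len(truth_vox & got) / len(truth_vox)
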