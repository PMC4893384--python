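"""Model adaptation and reset: when to learn, hold, or re-detect.

Appearance change (lighting, mild deformation, out-of-plane rotation) makes
a static keypoint model go stale, but updating during occlusion or while
the target is out of view poisons it.  The rule used here: whenever the
voted center falls outside the convex hull of the positive keypoints, the
frame keypoints inside the detected box are evaluated against the
segmentation model.  If the center sits inside the convex hull of these
high-weight candidates and there are enough of them, the candidates are
enrolled and stale (persistently negative) keypoints pruned; if the center
falls outside the candidate hull the target has most likely left the view
and the tracker switches to reset mode, where the model is frozen and each
frame attempts a whole-image re-detection instead.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from . import hough, segmentation
from ._geometry import point_in_hull, rect_contains, rotation_matrix, wrap_angle
from .keypoints import ModelKeypoint, detect_keypoints, match_model

__all__ = [
    "TrackerMode",
    "CandidateSet",
    "collect_candidates",
    "adaptation_decision",
    "AdaptationDecision",
    "apply_update",
    "redetect",
]


class TrackerMode(enum.Enum):
    NORMAL = "NORMAL"
    RESET = "RESET"


class AdaptationDecision(enum.Enum):
    UPDATE = "UPDATE"
    RESET = "RESET"
    HOLD = "HOLD"


@dataclass
class CandidateSet:
    """High-weight frame keypoints inside the detected box B_t."""

    candidates: list = field(default_factory=list)  # (Keypoint, weight)

    def __len__(self):
        return len(self.candidates)

    @property
    def positions(self):
        if not self.candidates:
            return np.zeros((0, 2))
        return np.array([kp.position for kp, _w in self.candidates])


def collect_candidates(frame_keypoints, bbox, prob_map, weight_threshold=0.5):
    """Keypoints inside ``bbox`` whose patch foreground weight exceeds the threshold."""
    out = []
    for kp in frame_keypoints:
        if not rect_contains(bbox, kp.position[None, :])[0]:
            continue
        w = segmentation.keypoint_weight(prob_map, kp)
        if w > weight_threshold:
            out.append((kp, w))
    return CandidateSet(candidates=out)


def adaptation_decision(center, candidates, count_threshold):
    """Classify the situation when the center left the positive-keypoint hull.

    UPDATE — center inside the candidate hull with enough candidates: the
    appearance changed but the target is present, learn the candidates.
    HOLD — center inside the hull but too few candidates: do nothing.
    RESET — center outside the hull (or hull degenerate): the target is most
    likely out of the image; switch to re-detection.
    """
    positions = candidates.positions
    if len(candidates) < 3:
        return AdaptationDecision.RESET
    inside = point_in_hull(center, positions)
    if not inside:
        return AdaptationDecision.RESET
    if len(candidates) > count_threshold:
        return AdaptationDecision.UPDATE
    return AdaptationDecision.HOLD


def apply_update(
    model,
    candidates,
    center,
    scale,
    rotation,
    removal_streak=5,
    min_keep_fraction=0.5,
    max_model_size=400,
    dedup_position_tol=2.0,
    dedup_descriptor_tol=350.0,
):
    """Enroll candidate keypoints and prune persistently negative ones.

    New candidates are stored in template units: distances de-scaled by the
    current scale and angles de-rotated by the current rotation, so the
    R-table stays expressed relative to the template frame.  A candidate
    duplicating an existing model keypoint (template position within
    ``dedup_position_tol`` px and descriptor distance within
    ``dedup_descriptor_tol``) is skipped.  Keypoints whose negative streak
    reached ``removal_streak`` are deleted, but never below
    ``min_keep_fraction`` of the enrollment size, to avoid model collapse
    during partial occlusion; total size is capped at ``max_model_size``.
    """
    center = np.asarray(center, dtype=float)
    # prune stale keypoints, oldest streaks first, respecting the floor
    floor = max(1, int(np.ceil(min_keep_fraction * model.enrollment_size)))
    removable = sorted(
        (i for i, mk in enumerate(model.keypoints) if mk.negative_streak >= removal_streak),
        key=lambda i: -model.keypoints[i].negative_streak,
    )
    n_removable = max(0, len(model.keypoints) - floor)
    for i in sorted(removable[:n_removable], reverse=True):
        del model.keypoints[i]

    # map candidate positions back to template coordinates for dedup
    R_inv = rotation_matrix(-rotation)
    existing = np.array([mk.keypoint.position for mk in model.keypoints])
    existing_desc = np.array(
        [mk.keypoint.descriptor for mk in model.keypoints], dtype=float
    )
    for kp, _w in candidates.candidates:
        if len(model.keypoints) >= max_model_size:
            break
        template_pos = model.reference_center + R_inv @ ((kp.position - center) / scale)
        if existing.shape[0]:
            d_pos = np.hypot(*(existing - template_pos).T)
            close = d_pos < dedup_position_tol
            if np.any(close):
                d_desc = np.linalg.norm(
                    existing_desc[close] - kp.descriptor.astype(float), axis=1
                )
                if np.any(d_desc < dedup_descriptor_tol):
                    continue
        diff = center - kp.position
        d_i = float(np.hypot(diff[0], diff[1])) / scale
        # de-rotate so absolute_center_angle is in template units
        angle = wrap_angle(float(np.arctan2(diff[1], diff[0])) - rotation)
        model.keypoints.append(
            ModelKeypoint(
                keypoint=kp,
                center_distance=d_i,
                center_angle=angle - kp.orientation,
                voting_state=1,
                negative_streak=0,
            )
        )
        existing = np.vstack([existing, template_pos]) if existing.shape[0] else template_pos[None, :]
        existing_desc = (
            np.vstack([existing_desc, kp.descriptor.astype(float)])
            if existing_desc.shape[0]
            else kp.descriptor.astype(float)[None, :]
        )
    return model


def redetect(
    model,
    frame,
    seg_model,
    min_matches=8,
    peak_fraction=0.25,
    self_match_peak=None,
    weight_threshold=0.5,
    max_ratio=0.8,
    detector=None,
):
    """Whole-frame re-detection attempt while in reset mode.

    Runs the full detect / match / weight / vote pipeline on the entire
    frame.  Keypoint weights come from the frozen histograms under a flat
    prior (the recursive posterior is stale after the target left).  The
    detection is accepted — and the caller switches back to normal mode —
    only when at least ``min_matches`` keypoints matched and the smoothed
    accumulator peak reaches ``peak_fraction`` of the template-frame
    self-match peak.  Returns a :class:`ghtrack.hough.VoteOutcome` or None.
    """
    kps = detect_keypoints(frame, detector=detector)
    if not kps:
        return None
    pmap = segmentation.likelihood_ratio_map(seg_model, frame)
    weights = [segmentation.keypoint_weight(pmap, kp) for kp in kps]
    matches = match_model(model, kps, weights=weights, max_ratio=max_ratio)
    if len(matches) < min_matches:
        return None
    acc = hough.cast_votes(
        matches,
        model,
        weight_threshold=weight_threshold,
        accumulator_extent=frame.shape[:2],
    )
    center = hough.find_center(acc)
    if center is None:
        return None
    peak = float(acc.smoothed().max())
    if self_match_peak is not None and peak < peak_fraction * self_match_peak:
        return None
    states, positive = hough.classify_votes(
        matches, model, center, weight_threshold=weight_threshold
    )
    if int(states.sum()) < min_matches:
        return None
    scale, theta, carried = hough.estimate_scale_rotation(
        positive, center, model, prev=(model.current_scale, model.current_rotation)
    )
    return hough.VoteOutcome(
        center=center,
        states=states,
        positive_pairs=positive,
        scale=scale,
        rotation=theta,
        pose_carried=carried,
        peak=peak,
    )
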