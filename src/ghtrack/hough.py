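"""Rotation-invariant annulus Hough voting for the object center.

Classic keypoint GHT voting casts a single displaced vote per matched
keypoint, which requires knowing the object's in-plane rotation in advance.
Here each matched keypoint instead votes for a *ring*: all image locations
at distance ``r_d * d_i * s_{t-1}`` from the keypoint, where ``d_i`` is the
keypoint's template distance to the center, ``s_{t-1}`` the scale tracked at
the previous frame and ``r_d = [0.95, 1.05]`` the ring thickness ratio.  The
rings of all inliers intersect at the true center regardless of rotation, so
the accumulator maximum finds the center with no rotation pre-estimate;
scale and rotation are then recovered afterwards from the keypoints whose
rings supported the winning center (the "positive" keypoints).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ._geometry import circular_median, wrap_angle

__all__ = [
    "THICKNESS_RATIO",
    "Accumulator",
    "Pose2D",
    "VoteOutcome",
    "vote_radius",
    "cast_votes",
    "find_center",
    "classify_votes",
    "estimate_scale_rotation",
]

#: default ring thickness ratio r_d
THICKNESS_RATIO = (0.95, 1.05)
#: default weight threshold w_thres for voting participation
WEIGHT_THRESHOLD = 0.5
#: Gaussian smoothing (pixels) applied to the accumulator before argmax
SMOOTHING_SIGMA = 2.0


@dataclass
class Pose2D:
    """2D pose lambda_2D = (u, v, theta, s): center, in-plane rotation, scale."""

    u: float
    v: float
    theta: float
    scale: float

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def center(self):
        return np.array([self.u, self.v])


@dataclass
class Accumulator:
    """Weighted vote array over pixel locations (bin size 1 px)."""

    grid: np.ndarray
    bin_size: float = 1.0

    @property
    def total_mass(self):
        return float(self.grid.sum())

    def smoothed(self, sigma=SMOOTHING_SIGMA):
        return gaussian_filter(self.grid, sigma)

    def to_uint8(self):
        """Heat-map rendering for debugging."""
        g = self.grid
        top = g.max()
        if top <= 0:
            return np.zeros(g.shape, dtype=np.uint8)
        return np.round(255.0 * g / top).astype(np.uint8)


@dataclass
class VoteOutcome:
    """Result of one voting round: center, per-keypoint states, pose estimate."""

    center: np.ndarray
    states: np.ndarray
    positive_pairs: list
    scale: float
    rotation: float
    pose_carried: bool = False
    peak: float = 0.0


def vote_radius(center_distance, prev_scale, thickness_ratio=THICKNESS_RATIO):
    """Radial interval [r_min, r_max] of a keypoint's voting ring.

    ``r = r_d * d_i * s_{t-1}``: the template distance scaled by the
    previously tracked scale, thickened by the ratio interval to absorb
    per-frame scale change and mild out-of-plane rotation.
    """
    if center_distance < 0:
        raise ValueError("center_distance must be non-negative")
    if prev_scale <= 0:
        raise ValueError("prev_scale must be positive")
    lo, hi = thickness_ratio
    return (lo * center_distance * prev_scale, hi * center_distance * prev_scale)


def _annulus_cells(position, r_min, r_max):
    """Integer cells whose distance to ``position`` lies in [r_min, r_max].

    Returned *unclipped*; callers drop off-image cells after the per-cell
    share has been computed, so clipping loses mass rather than
    concentrating it.
    """
    u, v = position
    if r_max < 0.5:
        return np.array([[int(round(u)), int(round(v))]])
    # thin rings (< 1 cell) are widened to a half-cell band about the ring
    # midline so they always rasterize to at least a one-cell-wide circle
    mid = 0.5 * (r_min + r_max)
    lo = min(r_min, max(mid - 0.5, 0.0))
    hi = max(r_max, mid + 0.5)
    u0, u1 = int(np.floor(u - hi - 1)), int(np.ceil(u + hi + 1))
    v0, v1 = int(np.floor(v - hi - 1)), int(np.ceil(v + hi + 1))
    uu, vv = np.meshgrid(np.arange(u0, u1 + 1), np.arange(v0, v1 + 1))
    dist = np.hypot(uu - u, vv - v)
    mask = (dist >= lo) & (dist <= hi)
    return np.column_stack([uu[mask], vv[mask]])


def cast_votes(
    matches,
    model,
    weight_threshold=WEIGHT_THRESHOLD,
    accumulator_extent=None,
    thickness_ratio=THICKNESS_RATIO,
    prev_scale=None,
):
    """Accumulate weighted ring votes from all eligible matches.

    Only keypoints whose segmentation weight exceeds ``weight_threshold``
    participate.  Each eligible keypoint deposits total mass equal to its
    weight, shared uniformly over its ring's cells, so keypoints far from
    the center (long perimeters) do not dominate by cell count.  Cells
    falling outside the image are dropped after the share is computed.
    """
    if accumulator_extent is None:
        raise ValueError("accumulator_extent (H, W) is required")
    H, W = accumulator_extent
    grid = np.zeros((H, W))
    scale = model.current_scale if prev_scale is None else prev_scale
    for model_index, kp, w in matches.pairs:
        if w <= weight_threshold:
            continue
        d_i = model.keypoints[model_index].center_distance
        r_min, r_max = vote_radius(d_i, scale, thickness_ratio)
        cells = _annulus_cells(kp.position, r_min, r_max)
        share = w / cells.shape[0]
        inside = (
            (cells[:, 0] >= 0) & (cells[:, 0] < W) & (cells[:, 1] >= 0) & (cells[:, 1] < H)
        )
        cells = cells[inside]
        np.add.at(grid, (cells[:, 1], cells[:, 0]), share)
    return Accumulator(grid=grid)


def find_center(acc, sigma=SMOOTHING_SIGMA):
    """Locate the object center as the accumulator argmax after smoothing.

    Rings intersect in thin quantized arcs, so a small Gaussian blur merges
    the intersection cluster before the argmax.  Ties resolve to the
    smallest (v, u) in lexicographic order (NumPy row-major first
    occurrence).  Returns None when the accumulator holds no mass.
    """
    if acc.total_mass <= 0:
        return None
    sm = acc.smoothed(sigma)
    flat = int(np.argmax(sm))
    v, u = np.unravel_index(flat, sm.shape)
    return np.array([float(u), float(v)])


def classify_votes(
    matches,
    model,
    center,
    tolerance=2.0,
    weight_threshold=WEIGHT_THRESHOLD,
    thickness_ratio=THICKNESS_RATIO,
    prev_scale=None,
):
    """Mark each model keypoint positive iff its ring supported the center.

    A keypoint is positive when it was eligible to vote (weight above
    threshold) and the detected center lies within its ring thickness plus
    ``tolerance`` pixels.  All other model keypoints — unmatched, under
    weight, or geometrically inconsistent — are negative.  Voting states
    and negative streaks on the model are updated in place.

    Returns ``(states, positive_pairs)`` where positive_pairs is the subset
    of match pairs classified positive.
    """
    center = np.asarray(center, dtype=float)
    scale = model.current_scale if prev_scale is None else prev_scale
    states = np.zeros(len(model), dtype=int)
    positive_pairs = []
    for model_index, kp, w in matches.pairs:
        if w <= weight_threshold:
            continue
        d_i = model.keypoints[model_index].center_distance
        r_min, r_max = vote_radius(d_i, scale, thickness_ratio)
        mid = 0.5 * (r_min + r_max)
        half = 0.5 * (r_max - r_min)
        dist = float(np.hypot(*(kp.position - center)))
        if abs(dist - mid) <= half + tolerance:
            states[model_index] = 1
            positive_pairs.append((model_index, kp, w))
    for i, mk in enumerate(model.keypoints):
        mk.voting_state = int(states[i])
        if states[i]:
            mk.negative_streak = 0
        else:
            mk.negative_streak += 1
    return states, positive_pairs


def estimate_scale_rotation(positive_pairs, center, model, prev=(1.0, 0.0)):
    """Estimate (s_t, theta_t) from the positive keypoints, post voting.

    Scale is the median ratio of observed to template center distance;
    rotation is the circular median of the angle change of each
    keypoint-to-center vector relative to its template angle.  Medians are
    used for robustness against misclassified positives.  With fewer than
    two usable positives the previous pose values are carried and flagged.

    Returns ``(scale, theta, carried)``.
    """
    center = np.asarray(center, dtype=float)
    ratios, angles = [], []
    for model_index, kp, _w in positive_pairs:
        mk = model.keypoints[model_index]
        if mk.center_distance < 1.0:
            continue  # near-center keypoints give unstable ratios/angles
        diff = center - kp.position
        dist = float(np.hypot(diff[0], diff[1]))
        ratios.append(dist / mk.center_distance)
        angles.append(
            wrap_angle(np.arctan2(diff[1], diff[0]) - mk.absolute_center_angle)
        )
    if len(ratios) < 2:
        return prev[0], prev[1], True
    return float(np.median(ratios)), float(circular_median(angles)), False
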