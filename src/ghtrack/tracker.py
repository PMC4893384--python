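"""Per-frame tracking pipeline and the 2D -> 3D pose-initialization bridge.

The :class:`Tracker` runs tracking-by-detection: every frame is processed
globally (detect keypoints, match against the object model, weight by the
segmentation posterior, cast rotation-invariant ring votes, locate the
center, classify positives, estimate scale and rotation), so the tracker
can recover from total failure rather than drifting.  A small state machine
decides per frame whether to adapt the model, hold, or switch into reset
(re-detection) mode.

The resulting 2D pose ``(u, v, theta, s)`` can initialize an external 3D
pose tracker: ``(u, v)`` is ray-cast through the pinhole camera with depth
``z_ref / s`` (apparent size scales inversely with depth), the in-plane
rotation seeds the roll about the optical axis, and the two out-of-plane
rotations are retained from the previous frame — exactly the parameters a
2D tracker cannot observe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from . import adaptation, hough, segmentation
from ._geometry import point_in_hull, rect_center
from .adaptation import AdaptationDecision, TrackerMode
from .hough import Pose2D
from .keypoints import build_model, detect_keypoints, match_model

logger = logging.getLogger(__name__)

__all__ = [
    "CameraModel",
    "Pose3D",
    "TrackerConfig",
    "TrajectoryRecord",
    "Tracker",
    "lift_to_3d",
    "project",
    "run_sequence",
    "write_trajectory",
    "read_trajectory",
    "load_camera",
]


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics: focal lengths and principal point in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self):
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")


@dataclass
class Pose3D:
    """3D pose lambda_3D = (x, y, z, phi, psi, theta_hat).

    Translation in metric units from the camera origin; phi, psi are the
    out-of-plane rotations and theta_hat the rotation about the optical
    axis, radians.
    """

    x: float
    y: float
    z: float
    phi: float = 0.0
    psi: float = 0.0
    theta_hat: float = 0.0

    def __post_init__(self):
        if self.z <= 0:
            raise ValueError("z must be positive (in front of the camera)")


def lift_to_3d(pose2d, camera, z_ref, prev_pose3d=None):
    """Initialize a 3D pose from the 2D detection by pinhole ray casting.

    ``z = z_ref / s`` where ``s`` is the cumulative scale relative to the
    enrollment frame (where s=1 and the depth was ``z_ref``): apparent size
    grows as the instrument approaches the camera.  ``theta`` seeds
    ``theta_hat`` directly; ``phi`` and ``psi`` are copied from the previous
    3D pose since the 2D tracker cannot observe them.
    """
    if pose2d.scale <= 0:
        raise ValueError("invalid 2D pose: non-positive scale")
    if z_ref <= 0:
        raise ValueError("z_ref must be positive")
    z = z_ref / pose2d.scale
    x = (pose2d.u - camera.cx) * z / camera.fx
    y = (pose2d.v - camera.cy) * z / camera.fy
    phi = prev_pose3d.phi if prev_pose3d is not None else 0.0
    psi = prev_pose3d.psi if prev_pose3d is not None else 0.0
    return Pose3D(x=x, y=y, z=z, phi=phi, psi=psi, theta_hat=pose2d.theta)


def project(pose3d, camera):
    """Project a 3D point through the pinhole camera; inverse of the ray cast."""
    u = camera.fx * pose3d.x / pose3d.z + camera.cx
    v = camera.fy * pose3d.y / pose3d.z + camera.cy
    return np.array([u, v])


@dataclass
class TrackerConfig:
    """All tunable parameters of the 2D tracker (defaults as documented)."""

    match_ratio: float = 0.8
    weight_threshold: float = 0.5
    thickness_ratio: tuple = hough.THICKNESS_RATIO
    smoothing_sigma: float = hough.SMOOTHING_SIGMA
    classify_tolerance: float = 2.0
    stay_prob: float = 0.6
    update_factor: float = 0.1
    removal_streak: int = 5
    min_keep_fraction: float = 0.5
    max_model_size: int = 400
    candidate_count_min: int = 5
    candidate_count_fraction: float = 0.1
    redetect_min_matches: int = 8
    redetect_peak_fraction: float = 0.25

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "thickness_ratio" in data:
            data["thickness_ratio"] = tuple(data["thickness_ratio"])
        return cls(**data)


@dataclass
class TrajectoryRecord:
    """One frame of tracker output: pose (or no-detection) plus diagnostics."""

    frame: int
    pose2d: Optional[Pose2D]
    pose3d: Optional[Pose3D] = None
    mode: str = "NORMAL"
    matches: int = 0
    peak: float = 0.0

    @property
    def detected(self):
        return self.pose2d is not None


class Tracker:
    """Stateful per-frame tracker, enrolled from frame 1 and a bounding box."""

    def __init__(self, frame, bbox, config=None, camera=None, z_ref=None):
        self.config = config or TrackerConfig()
        self.camera = camera
        self.z_ref = z_ref
        self.mode = TrackerMode.NORMAL
        self.frame_index = 0
        self.bbox = tuple(float(x) for x in bbox)

        self.model = build_model(frame, bbox)
        # self-match on the template gives the reference accumulator peak
        template_kps = [mk.keypoint for mk in self.model.keypoints]
        matches = match_model(self.model, template_kps, max_ratio=self.config.match_ratio)
        acc = hough.cast_votes(
            matches,
            self.model,
            weight_threshold=self.config.weight_threshold,
            accumulator_extent=frame.shape[:2],
            thickness_ratio=self.config.thickness_ratio,
        )
        self.self_match_peak = float(acc.smoothed(self.config.smoothing_sigma).max())

        positions = np.array([mk.keypoint.position for mk in self.model.keypoints])
        self.seg = segmentation.init_segmentation(
            frame,
            positions,
            bbox,
            stay_prob=self.config.stay_prob,
            update_factor=self.config.update_factor,
        )
        center = rect_center(bbox)
        self.pose = Pose2D(u=center[0], v=center[1], theta=0.0, scale=1.0)
        self.pose3d = None
        if self.camera is not None and self.z_ref is not None:
            self.pose3d = lift_to_3d(self.pose, self.camera, self.z_ref)
        self.records = [
            TrajectoryRecord(
                frame=0,
                pose2d=self.pose,
                pose3d=self.pose3d,
                mode=self.mode.value,
                matches=len(self.model),
                peak=self.self_match_peak,
            )
        ]

    # ------------------------------------------------------------------
    def _detected_bbox(self, center, scale, rotation):
        """Axis-aligned box B_t of the template rect posed at (center, s, theta)."""
        w0, h0 = self.model.bbox_size
        c, s = abs(np.cos(rotation)), abs(np.sin(rotation))
        hw = 0.5 * scale * (w0 * c + h0 * s)
        hh = 0.5 * scale * (w0 * s + h0 * c)
        return (center[0] - hw, center[1] - hh, 2 * hw, 2 * hh)

    def _candidate_count_threshold(self):
        return max(
            self.config.candidate_count_min,
            int(self.config.candidate_count_fraction * len(self.model)),
        )

    def _record(self, pose2d, matches, peak):
        pose3d = None
        if pose2d is not None and self.camera is not None and self.z_ref is not None:
            pose3d = lift_to_3d(pose2d, self.camera, self.z_ref, self.pose3d)
            self.pose3d = pose3d
        rec = TrajectoryRecord(
            frame=self.frame_index,
            pose2d=pose2d,
            pose3d=pose3d,
            mode=self.mode.value,
            matches=matches,
            peak=peak,
        )
        self.records.append(rec)
        return rec

    # ------------------------------------------------------------------
    def track_frame(self, frame):
        """Process one frame; returns the TrajectoryRecord for it.

        Pipeline order is fixed: detect -> match -> weight -> vote ->
        find center -> classify -> estimate scale/rotation -> adaptation
        decision -> histogram update (with the final pose).
        """
        self.frame_index += 1
        if frame is None:
            logger.warning("frame %d unreadable; recorded as no-detection", self.frame_index)
            return self._record(None, 0, 0.0)
        if self.mode is TrackerMode.RESET:
            return self._track_reset(frame)
        return self._track_normal(frame)

    def _track_normal(self, frame):
        cfg = self.config
        kps = detect_keypoints(frame)
        pmap = segmentation.posterior_map(self.seg, frame)
        weights = [segmentation.keypoint_weight(pmap, kp) for kp in kps]
        matches = match_model(self.model, kps, weights=weights, max_ratio=cfg.match_ratio)
        if len(matches) == 0:
            self.mode = TrackerMode.RESET
            return self._record(None, 0, 0.0)

        acc = hough.cast_votes(
            matches,
            self.model,
            weight_threshold=cfg.weight_threshold,
            accumulator_extent=frame.shape[:2],
            thickness_ratio=cfg.thickness_ratio,
        )
        center = hough.find_center(acc, sigma=cfg.smoothing_sigma)
        if center is None:
            self.mode = TrackerMode.RESET
            return self._record(None, len(matches), 0.0)
        peak = float(acc.smoothed(cfg.smoothing_sigma).max())

        states, positive = hough.classify_votes(
            matches,
            self.model,
            center,
            tolerance=cfg.classify_tolerance,
            weight_threshold=cfg.weight_threshold,
            thickness_ratio=cfg.thickness_ratio,
        )
        scale, theta, carried = hough.estimate_scale_rotation(
            positive,
            center,
            self.model,
            prev=(self.model.current_scale, self.model.current_rotation),
        )
        bbox_t = self._detected_bbox(center, scale, theta)
        pos_positions = np.array([kp.position for _i, kp, _w in positive]) if positive else np.zeros((0, 2))

        if not point_in_hull(center, pos_positions):
            # center left the trusted region: adapt, hold, or reset
            candidates = adaptation.collect_candidates(
                kps, bbox_t, pmap, weight_threshold=cfg.weight_threshold
            )
            decision = adaptation.adaptation_decision(
                center, candidates, self._candidate_count_threshold()
            )
            if decision is AdaptationDecision.RESET:
                self.mode = TrackerMode.RESET
                return self._record(None, len(matches), peak)
            if decision is AdaptationDecision.UPDATE:
                adaptation.apply_update(
                    self.model,
                    candidates,
                    center,
                    scale,
                    theta,
                    removal_streak=cfg.removal_streak,
                    min_keep_fraction=cfg.min_keep_fraction,
                    max_model_size=cfg.max_model_size,
                )

        self.model.current_scale = scale
        self.model.current_rotation = theta
        self.pose = Pose2D(u=float(center[0]), v=float(center[1]), theta=theta, scale=scale)
        segmentation.update_histograms(self.seg, frame, pos_positions, bbox_t)
        return self._record(self.pose, len(matches), peak)

    def _track_reset(self, frame):
        cfg = self.config
        outcome = adaptation.redetect(
            self.model,
            frame,
            self.seg,
            min_matches=cfg.redetect_min_matches,
            peak_fraction=cfg.redetect_peak_fraction,
            self_match_peak=self.self_match_peak,
            weight_threshold=cfg.weight_threshold,
            max_ratio=cfg.match_ratio,
        )
        if outcome is None:
            return self._record(None, 0, 0.0)
        self.mode = TrackerMode.NORMAL
        self.model.current_scale = outcome.scale
        self.model.current_rotation = outcome.rotation
        center = outcome.center
        self.pose = Pose2D(
            u=float(center[0]), v=float(center[1]), theta=outcome.rotation, scale=outcome.scale
        )
        # the recursive posterior is stale after an absence: restart it
        self.seg.prev_posterior = np.full(frame.shape[:2], 0.5)
        bbox_t = self._detected_bbox(center, outcome.scale, outcome.rotation)
        pos_positions = (
            np.array([kp.position for _i, kp, _w in outcome.positive_pairs])
            if outcome.positive_pairs
            else np.zeros((0, 2))
        )
        segmentation.update_histograms(self.seg, frame, pos_positions, bbox_t)
        return self._record(self.pose, len(outcome.positive_pairs), outcome.peak)


def run_sequence(frames, init_bbox, config=None, camera=None, z_ref=None):
    """Track a whole sequence; frame 1 enrolls the model.

    ``frames`` is an iterable of RGB arrays (or None for unreadable frames,
    which are logged and recorded as no-detection).  Deterministic for
    identical inputs.
    """
    it = iter(frames)
    try:
        first = next(it)
    except StopIteration:
        raise ValueError("need at least one frame")
    tracker = Tracker(first, init_bbox, config=config, camera=camera, z_ref=z_ref)
    for frame in it:
        tracker.track_frame(frame)
    return tracker.records


# ----------------------------------------------------------------------
# trajectory I/O

_BASE_COLS = ["frame", "u", "v", "theta", "scale", "mode", "matches", "peak"]
_3D_COLS = ["x", "y", "z", "phi", "psi", "theta_hat"]


def _fmt(x):
    return "" if x is None else f"{x:.6f}"


def write_trajectory(records, path):
    """Write records as CSV; missing detections become empty pose fields."""
    with_3d = any(r.pose3d is not None for r in records)
    cols = _BASE_COLS + (_3D_COLS if with_3d else [])
    lines = [",".join(cols)]
    for r in records:
        p = r.pose2d
        row = [
            str(r.frame),
            _fmt(p.u if p else None),
            _fmt(p.v if p else None),
            _fmt(p.theta if p else None),
            _fmt(p.scale if p else None),
            r.mode,
            str(r.matches),
            f"{r.peak:.6f}",
        ]
        if with_3d:
            q = r.pose3d
            row += [
                _fmt(getattr(q, name) if q else None)
                for name in ["x", "y", "z", "phi", "psi", "theta_hat"]
            ]
        lines.append(",".join(row))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_trajectory(path):
    """Read a trajectory CSV into a pandas DataFrame (NaN for no-detection)."""
    import pandas as pd

    return pd.read_csv(path)


def load_camera(path):
    """Load pinhole intrinsics from a plain-text/YAML file with fx, fy, cx, cy keys."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return CameraModel(
        fx=float(data["fx"]), fy=float(data["fy"]), cx=float(data["cx"]), cy=float(data["cy"])
    )
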