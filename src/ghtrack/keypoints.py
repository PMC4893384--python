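"""Keypoint-based object model for Generalized Hough Transform tracking.

The tracked instrument is represented as a set of scale/rotation-covariant
keypoints (SIFT), each storing its displacement to a reference center: the
distance ``d_i`` and the angle of the keypoint-to-center vector expressed
relative to the keypoint's own orientation.  Together these records form the
R-table of a Generalized Hough Transform: matched keypoints in a new frame
can vote for the instrument center without knowing the global rotation.

Every model keypoint also carries a binary voting state ``s_i`` (did it
support the detected center in the current frame?) and a count of
consecutive negative frames, which drives pruning during model adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from skimage.color import rgb2gray
from skimage.feature import SIFT

from ._geometry import rect_center, rect_clip, rect_contains

__all__ = [
    "Keypoint",
    "ModelKeypoint",
    "ObjectModel",
    "MatchSet",
    "detect_keypoints",
    "build_model",
    "match_model",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class Keypoint:
    """A detected interest point.

    Attributes
    ----------
    position : (2,) float array, (u, v) sub-pixel coordinates
    descriptor : fixed-length feature vector (uint8 SIFT descriptor)
    orientation : dominant gradient orientation, radians
    detector_scale : characteristic scale (sigma) of the detection
    """

    position: np.ndarray
    descriptor: np.ndarray
    orientation: float
    detector_scale: float

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if not np.all(np.isfinite(self.position)):
            raise ValueError("keypoint position must be finite")


@dataclass
class ModelKeypoint:
    """A keypoint enrolled in the object model (template units).

    ``center_distance`` is the distance from the keypoint to the reference
    center at enrollment scale 1; ``center_angle`` is the angle of the
    keypoint-to-center vector minus the keypoint's own orientation, so the
    stored geometry is covariant with in-plane rotation.
    """

    keypoint: Keypoint
    center_distance: float
    center_angle: float
    voting_state: int = 1
    negative_streak: int = 0

    @property
    def absolute_center_angle(self):
        """Angle of the keypoint-to-center vector in template coordinates."""
        return self.center_angle + self.keypoint.orientation


@dataclass
class ObjectModel:
    """The tracked object: R-table keypoints plus the current pose scale/rotation."""

    keypoints: list
    reference_center: np.ndarray
    bbox_size: tuple
    current_scale: float = 1.0
    current_rotation: float = 0.0
    enrollment_size: int = 0

    def __post_init__(self):
        self.reference_center = np.asarray(self.reference_center, dtype=float)
        if len(self.keypoints) < 1:
            raise ValueError("object model needs at least one keypoint")
        if self.current_scale <= 0:
            raise ValueError("current_scale must be positive")
        if self.enrollment_size == 0:
            self.enrollment_size = len(self.keypoints)

    def __len__(self):
        return len(self.keypoints)

    @property
    def voting_states(self):
        return np.array([mk.voting_state for mk in self.keypoints], dtype=int)


@dataclass
class MatchSet:
    """One-to-one matches between model keypoints and frame keypoints.

    ``pairs`` is a list of ``(model_index, frame_keypoint, vote_weight)``;
    weights come from the segmentation model and lie in [0, 1].
    """

    pairs: list = field(default_factory=list)

    def __len__(self):
        return len(self.pairs)

    @property
    def model_indices(self):
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def positions(self):
        if not self.pairs:
            return np.zeros((0, 2))
        return np.array([p[1].position for p in self.pairs])

    @property
    def weights(self):
        return np.array([p[2] for p in self.pairs], dtype=float)


def _to_gray(image):
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 3:
        img = rgb2gray(img)
    return img.astype(float)


def detect_keypoints(image, region=None, detector=None):
    """Detect SIFT keypoints, optionally restricted to a rectangular region.

    Parameters
    ----------
    image : 2D grayscale or 3D RGB array
    region : optional (u, v, w, h) rect; detection runs on the crop and
        positions are reported in full-image coordinates, strictly inside
        the region (half-open).
    detector : optional pre-configured ``skimage.feature.SIFT`` instance.

    Returns
    -------
    list of Keypoint, in the detector's (deterministic) output order.
    """
    gray = _to_gray(image)
    offset = np.zeros(2)
    if region is not None:
        clipped = rect_clip(region, gray.shape)
        if clipped is None:
            raise ValueError("region does not intersect image")
        u0, v0, w, h = clipped
        gray = gray[v0 : v0 + h, u0 : u0 + w]
        offset = np.array([u0, v0], dtype=float)
    if detector is None:
        # upsampling=1 skips the initial 2x upscale: substantially faster and
        # the instruments of interest are far larger than one octave anyway.
        detector = SIFT(upsampling=1)
    try:
        detector.detect_and_extract(gray)
    except RuntimeError:
        # the detector signals "no features found" with an exception
        return []
    positions = detector.positions[:, ::-1] + offset  # (row, col) -> (u, v)
    kps = [
        Keypoint(
            position=positions[i],
            descriptor=detector.descriptors[i],
            orientation=float(detector.orientations[i]),
            detector_scale=float(detector.sigmas[i]),
        )
        for i in range(len(detector.positions))
    ]
    if region is not None:
        inside = rect_contains(region, positions)
        kps = [kp for kp, ok in zip(kps, inside) if ok]
    return kps


def build_model(image, bbox, detector=None):
    """Enroll the object model from the template frame and its bounding box.

    The reference center is the bbox center; every keypoint found inside the
    bbox is enrolled with its distance and (orientation-relative) angle to
    that center, voting state 1 and scale 1.
    """
    kps = detect_keypoints(image, region=bbox, detector=detector)
    if not kps:
        raise ValueError("no keypoints found inside the bounding box; "
                         "cannot initialize the object model")
    center = rect_center(bbox)
    model_kps = []
    for kp in kps:
        diff = center - kp.position
        d = float(np.hypot(diff[0], diff[1]))
        angle = float(np.arctan2(diff[1], diff[0])) - kp.orientation
        model_kps.append(ModelKeypoint(keypoint=kp, center_distance=d, center_angle=angle))
    return ObjectModel(
        keypoints=model_kps,
        reference_center=center,
        bbox_size=(float(bbox[2]), float(bbox[3])),
    )


def match_model(model, frame_keypoints, weights=None, max_ratio=0.8):
    """Match model keypoints to frame keypoints (nearest neighbour + ratio test).

    A model keypoint is matched to its nearest frame descriptor when the
    nearest distance is below ``max_ratio`` times the second-nearest
    (Lowe ratio test).  Assignment is one-to-one: conflicts are resolved
    greedily by ascending descriptor distance, so each model index and each
    frame keypoint appears at most once.

    ``weights`` are per-frame-keypoint foreground weights (default 1.0);
    the matched pair carries the weight of its frame keypoint.
    """
    if not frame_keypoints or len(model) == 0:
        return MatchSet()
    if weights is None:
        weights = np.ones(len(frame_keypoints))
    weights = np.asarray(weights, dtype=float)

    md = np.array([mk.keypoint.descriptor for mk in model.keypoints], dtype=float)
    fd = np.array([kp.descriptor for kp in frame_keypoints], dtype=float)
    if md.shape[1] != fd.shape[1]:
        raise ValueError("descriptor lengths disagree")
    dist = cdist(md, fd)

    candidates = []
    for i in range(dist.shape[0]):
        row = dist[i]
        if row.shape[0] == 1:
            j = 0
            candidates.append((row[0], i, j))
            continue
        order = np.argpartition(row, 1)[:2]
        j1, j2 = order[np.argsort(row[order])]
        if row[j1] < max_ratio * row[j2]:
            candidates.append((row[j1], i, int(j1)))

    candidates.sort(key=lambda c: (c[0], c[1]))
    used_model, used_frame = set(), set()
    pairs = []
    for d, i, j in candidates:
        if i in used_model or j in used_frame:
            continue
        used_model.add(i)
        used_frame.add(j)
        pairs.append((i, frame_keypoints[j], float(np.clip(weights[j], 0.0, 1.0))))
    pairs.sort(key=lambda p: p[0])
    return MatchSet(pairs=pairs)


def save_model(model, path):
    """Serialize an ObjectModel to a NumPy ``.npz`` archive.

    Layout: ``positions`` (n, 2) float64, ``descriptors`` (n, D) row-major,
    ``orientations``, ``detector_scales``, ``center_distances``,
    ``center_angles``, ``voting_states``, ``negative_streaks`` (all length n)
    plus the scalars ``reference_center``, ``bbox_size``, ``current_scale``,
    ``current_rotation``, ``enrollment_size``.
    """
    kps = model.keypoints
    np.savez(
        path,
        positions=np.array([mk.keypoint.position for mk in kps]),
        descriptors=np.array([mk.keypoint.descriptor for mk in kps]),
        orientations=np.array([mk.keypoint.orientation for mk in kps]),
        detector_scales=np.array([mk.keypoint.detector_scale for mk in kps]),
        center_distances=np.array([mk.center_distance for mk in kps]),
        center_angles=np.array([mk.center_angle for mk in kps]),
        voting_states=np.array([mk.voting_state for mk in kps], dtype=int),
        negative_streaks=np.array([mk.negative_streak for mk in kps], dtype=int),
        reference_center=model.reference_center,
        bbox_size=np.array(model.bbox_size),
        current_scale=model.current_scale,
        current_rotation=model.current_rotation,
        enrollment_size=model.enrollment_size,
    )


def load_model(path):
    """Load an ObjectModel saved by :func:`save_model`."""
    with np.load(path) as z:
        kps = [
            ModelKeypoint(
                keypoint=Keypoint(
                    position=z["positions"][i],
                    descriptor=z["descriptors"][i],
                    orientation=float(z["orientations"][i]),
                    detector_scale=float(z["detector_scales"][i]),
                ),
                center_distance=float(z["center_distances"][i]),
                center_angle=float(z["center_angles"][i]),
                voting_state=int(z["voting_states"][i]),
                negative_streak=int(z["negative_streaks"][i]),
            )
            for i in range(z["positions"].shape[0])
        ]
        return ObjectModel(
            keypoints=kps,
            reference_center=z["reference_center"],
            bbox_size=tuple(z["bbox_size"]),
            current_scale=float(z["current_scale"]),
            current_rotation=float(z["current_rotation"]),
            enrollment_size=int(z["enrollment_size"]),
        )
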