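import numpy as np
import pytest

import ghtrack as gt


def textured_frame():
    """Deterministic frame with a high-contrast block-textured patch.

    The patch occupies the half-open rect (52, 32, 96, 96); the rest of the
    frame is uniform gray.
    """
    rng = np.random.default_rng(42)
    blocks = rng.uniform(0.2, 1.0, (12, 12))
    patch = np.kron(blocks, np.ones((8, 8)))
    frame = np.full((160, 200), 0.5)
    frame[32:128, 52:148] = patch
    return np.dstack([frame] * 3)


TEXTURED_BBOX = (52, 32, 96, 96)


def synthetic_model(center=(100.0, 80.0), n=12, radius=40.0, seed=0, desc_dim=16):
    """Hand-built object model with known geometry (detector-independent).

    Keypoints sit on a circle of the given radius around ``center`` with
    distinct random descriptors, so voting and pose estimation can be
    exercised on exactly known configurations.
    """
    rng = np.random.default_rng(seed)
    center = np.asarray(center, dtype=float)
    mks = []
    for i in range(n):
        ang = 2 * np.pi * i / n
        pos = center + radius * np.array([np.cos(ang), np.sin(ang)])
        kp = gt.Keypoint(
            position=pos,
            descriptor=rng.integers(0, 256, desc_dim).astype(np.uint8),
            orientation=float(rng.uniform(-np.pi, np.pi)),
            detector_scale=2.0,
        )
        diff = center - pos
        mks.append(
            gt.ModelKeypoint(
                keypoint=kp,
                center_distance=float(np.hypot(*diff)),
                center_angle=float(np.arctan2(diff[1], diff[0])) - kp.orientation,
            )
        )
    return gt.ObjectModel(keypoints=mks, reference_center=center, bbox_size=(90.0, 90.0))


def transformed_matches(model, new_center, rotation=0.0, scale=1.0, weights=None):
    """Noise-free MatchSet: model keypoints rigidly moved to a new pose."""
    new_center = np.asarray(new_center, dtype=float)
    R = gt.synthetic.rotation_matrix(rotation) if hasattr(gt.synthetic, "rotation_matrix") else None
    from ghtrack._geometry import rotation_matrix

    R = rotation_matrix(rotation)
    pairs = []
    for i, mk in enumerate(model.keypoints):
        rel = mk.keypoint.position - model.reference_center
        pos = new_center + scale * (R @ rel)
        kp = gt.Keypoint(
            position=pos,
            descriptor=mk.keypoint.descriptor,
            orientation=mk.keypoint.orientation + rotation,
            detector_scale=mk.keypoint.detector_scale * scale,
        )
        w = 1.0 if weights is None else weights[i]
        pairs.append((i, kp, w))
    return gt.MatchSet(pairs=pairs)


@pytest.fixture(scope="session")
def template():
    return textured_frame()


@pytest.fixture(scope="session")
def template_bbox():
    return TEXTURED_BBOX


@pytest.fixture(scope="session")
def static_sequence():
    """Five identical-pose frames of the synthetic target, with ground truth."""
    cfg = gt.SequenceConfig(poses=gt.make_poses(5, 160.0, 120.0), seed=11)
    frames, truth = gt.generate_sequence(cfg)
    return frames, truth, (115.0, 75.0, 90.0, 90.0)
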