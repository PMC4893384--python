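"""Ground-truthed synthetic sequences for exercising the tracker.

Real endoscopic footage with kinematic ground truth cannot ship with the
package, so this module renders the same *challenge structure* seen in
instrument-tracking benchmarks: a textured rigid target translating,
rotating in plane and changing scale over a textured tissue-like
background, occluded by a second rigid object or a tissue-colored blob, or
leaving the field of view entirely.  Every frame comes with the exact
continuous pose (u, v, theta, s), a visibility fraction and an in-view
flag, so tracker output can be scored without manual annotation.

The renderer is deliberately non-photorealistic (no specularities, smoke or
deformation): it emulates the geometric and chromatic structure of the
problem, not its appearance.  Texture is corner-rich multi-scale noise so
the keypoint detector finds plenty of features; foreground and background
palettes are separable in HSV by default, with a "camouflage" variant for
stress-testing the segmentation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb
from skimage.transform import AffineTransform, warp

from ._geometry import rotation_matrix

__all__ = [
    "OccluderProgram",
    "SequenceConfig",
    "make_poses",
    "generate_sequence",
    "preset",
    "save_sequence",
    "PRESET_NAMES",
]

PRESET_NAMES = ("instrument_occlusion", "tissue_occlusion", "out_of_view", "long_term")


@dataclass
class OccluderProgram:
    """A second object layered over the target.

    ``kind`` is "rigid" (a textured patch, like a second instrument) or
    "blob" (a soft-edged tissue-colored ellipse).  ``poses`` is an (n, 4)
    array of per-frame (u, v, theta, scale); ``size`` is the patch (w, h)
    for rigid occluders or the ellipse radii (ru, rv) for blobs.
    """

    kind: str
    poses: np.ndarray
    size: tuple

    def __post_init__(self):
        if self.kind not in ("rigid", "blob"):
            raise ValueError(f"unknown occluder kind {self.kind!r}")
        self.poses = np.asarray(self.poses, dtype=float)


@dataclass
class SequenceConfig:
    """Full description of a synthetic sequence.

    ``poses`` is the per-frame ground-truth motion program, an (n, 4) array
    of (u, v, theta, s).  ``noise_std`` is additive per-channel Gaussian
    noise in 8-bit units.  Identical configs (same seed) render identical
    pixels.
    """

    image_size: tuple = (320, 240)  # (W, H)
    target_size: tuple = (80, 80)  # (w, h)
    poses: np.ndarray = None
    occluders: list = field(default_factory=list)
    palette: str = "separable"
    noise_std: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.poses is None:
            raise ValueError("a motion program (poses) is required")
        self.poses = np.atleast_2d(np.asarray(self.poses, dtype=float))
        if self.poses.shape[1] != 4:
            raise ValueError("poses must be (n, 4): u, v, theta, scale")
        if np.any(self.poses[:, 3] <= 0):
            raise ValueError("scale schedule must be positive")
        W, H = self.image_size
        w, h = self.target_size
        if w > W or h > H:
            raise ValueError("target larger than image")

    @property
    def n_frames(self):
        return self.poses.shape[0]


def make_poses(n, u, v, theta=0.0, scale=1.0):
    """Assemble an (n, 4) pose program from scalars or per-frame arrays."""
    cols = [np.broadcast_to(np.asarray(x, dtype=float), (n,)) for x in (u, v, theta, scale)]
    return np.column_stack(cols)


# ----------------------------------------------------------------------
# textures


def _block_texture(rng, size, hue, sat, block=8, value_range=(0.25, 1.0)):
    """Corner-rich texture: random brightness blocks plus fine noise."""
    w, h = size
    nb_v, nb_u = -(-h // block), -(-w // block)
    blocks = rng.uniform(*value_range, size=(nb_v, nb_u))
    v = np.kron(blocks, np.ones((block, block)))[:h, :w]
    v = np.clip(v + 0.08 * rng.standard_normal((h, w)), 0.05, 1.0)
    hsv = np.stack(
        [
            np.clip(hue + 0.01 * rng.standard_normal((h, w)), 0.0, 1.0),
            np.full((h, w), sat),
            v,
        ],
        axis=-1,
    )
    return hsv2rgb(hsv)


def _smooth_texture(rng, size, hue, sat, lo=0.3, hi=0.85, blur=6.0):
    """Tissue-like background: low-frequency brightness variation + grain."""
    w, h = size
    v = gaussian_filter(rng.standard_normal((h, w)), blur)
    v = (v - v.min()) / (np.ptp(v) + 1e-9) * (hi - lo) + lo
    v = np.clip(v + 0.04 * rng.standard_normal((h, w)), 0.0, 1.0)
    hsv = np.stack(
        [
            np.clip(hue + 0.015 * rng.standard_normal((h, w)), 0.0, 1.0),
            np.clip(sat + 0.05 * rng.standard_normal((h, w)), 0.0, 1.0),
            v,
        ],
        axis=-1,
    )
    return hsv2rgb(hsv)


def _palette(name):
    """(target hue/sat, background hue/sat, occluder specs) per palette."""
    if name == "separable":
        return dict(
            target=(0.60, 0.65),  # blue-ish instrument head
            background=(0.03, 0.55),  # reddish tissue
            rigid=(0.13, 0.05),  # near-achromatic second instrument
            blob=(0.05, 0.50),  # tissue-colored blob
        )
    if name == "camouflage":
        return dict(
            target=(0.04, 0.55),
            background=(0.03, 0.55),
            rigid=(0.13, 0.05),
            blob=(0.05, 0.50),
        )
    raise ValueError(f"unknown palette {name!r}")


# ----------------------------------------------------------------------
# rendering


def _warp_layer(texture, mask, pose, out_shape):
    """Place a texture at pose (u, v, theta, s); returns (rgb, alpha)."""
    u, v, theta, s = pose
    h, w = texture.shape[:2]
    c0 = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    A = s * rotation_matrix(theta)
    t = np.array([u, v]) - A @ c0
    M = np.eye(3)
    M[:2, :2] = A
    M[:2, 2] = t
    tform = AffineTransform(matrix=M)
    rgb = warp(texture, tform.inverse, output_shape=out_shape, order=1, cval=0.0)
    alpha = warp(mask, tform.inverse, output_shape=out_shape, order=1, cval=0.0)
    return rgb, alpha


def _ellipse_mask(size):
    ru, rv = size
    h, w = int(np.ceil(2 * rv)) + 3, int(np.ceil(2 * ru)) + 3
    vv, uu = np.mgrid[0:h, 0:w]
    cu, cv = (w - 1) / 2.0, (h - 1) / 2.0
    m = ((uu - cu) / ru) ** 2 + ((vv - cv) / rv) ** 2 <= 1.0
    return gaussian_filter(m.astype(float), 1.5), (w, h)


def generate_sequence(config):
    """Render the sequence; returns (frames, ground_truth).

    ``frames`` is a list of uint8 RGB arrays; ``ground_truth`` a DataFrame
    with columns frame, u, v, theta, scale, visibility, in_view.  The
    visibility fraction is the portion of the target's area that is inside
    the image and not covered by an occluder.
    """
    W, H = config.image_size
    tw, th = config.target_size
    pal = _palette(config.palette)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))

    target_tex = _block_texture(rng, (tw, th), *pal["target"])
    target_mask = np.ones((th, tw))
    background = _smooth_texture(rng, (W, H), *pal["background"])

    occ_layers = []
    for occ in config.occluders:
        if occ.poses.shape[0] != config.n_frames:
            raise ValueError("occluder program length must match frame count")
        if occ.kind == "rigid":
            ow, oh = occ.size
            tex = _block_texture(rng, (int(ow), int(oh)), *pal["rigid"], block=10)
            mask = np.ones((int(oh), int(ow)))
        else:
            mask, (ow, oh) = _ellipse_mask(occ.size)
            tex = _smooth_texture(rng, (ow, oh), *pal["blob"], blur=4.0)
        occ_layers.append((occ, tex, mask))

    frames = []
    truth_rows = []
    # reference canvas for the full (unclipped, unoccluded) target area
    diag = int(np.ceil(np.hypot(tw, th) * config.poses[:, 3].max())) + 4
    for t in range(config.n_frames):
        pose = config.poses[t]
        frame = background.copy()
        rgb, alpha = _warp_layer(target_tex, target_mask, pose, (H, W))
        a3 = alpha[..., None]
        frame = frame * (1.0 - a3) + rgb * a3
        covered = np.zeros((H, W), dtype=bool)
        for occ, tex, mask in occ_layers:
            orgb, oalpha = _warp_layer(tex, mask, occ.poses[t], (H, W))
            o3 = oalpha[..., None]
            frame = frame * (1.0 - o3) + orgb * o3
            covered |= oalpha > 0.5

        visible = int(np.count_nonzero((alpha > 0.5) & ~covered))
        # same pose modulo translation, rendered unclipped, so rasterization
        # effects cancel and a fully visible, unoccluded target scores 1.0
        ref_pose = (diag / 2 + pose[0] % 1.0, diag / 2 + pose[1] % 1.0, pose[2], pose[3])
        _rgb, ref_alpha = _warp_layer(target_tex, target_mask, ref_pose, (diag + 1, diag + 1))
        denom = max(int(np.count_nonzero(ref_alpha > 0.5)), 1)
        visibility = float(np.clip(visible / denom, 0.0, 1.0))

        frame8 = np.clip(frame * 255.0, 0, 255)
        if config.noise_std > 0:
            nrng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 1, t]))
            frame8 = frame8 + nrng.normal(0.0, config.noise_std, frame8.shape)
        frames.append(np.clip(np.round(frame8), 0, 255).astype(np.uint8))
        truth_rows.append(
            dict(
                frame=t,
                u=pose[0],
                v=pose[1],
                theta=pose[2],
                scale=pose[3],
                visibility=visibility,
                in_view=visibility > 0.0,
            )
        )
    return frames, pd.DataFrame(truth_rows)


# ----------------------------------------------------------------------
# canonical challenge presets


def _ease(n, a, b):
    """Smoothstep interpolation from a to b over n frames."""
    x = np.linspace(0.0, 1.0, n)
    s = x * x * (3 - 2 * x)
    return a + (b - a) * s


def preset(name, seed=0):
    """Canonical fixture config for one of the four challenge regimes.

    - ``instrument_occlusion``: a second rigid textured patch sweeps across
      the (gently moving) target, occluding it partially to fully.
    - ``tissue_occlusion``: a tissue-colored blob passes over the target.
    - ``out_of_view``: the target exits the image completely, stays absent
      for 30 frames, then re-enters and settles.
    - ``long_term``: 2000 frames of slow simultaneous drift in position,
      in-plane rotation and scale, with no occluder.
    """
    if name == "instrument_occlusion":
        n = 150
        t = np.arange(n)
        u = 120.0 + 18.0 * np.sin(2 * np.pi * t / 140.0)
        v = 120.0 + 12.0 * np.sin(2 * np.pi * t / 110.0 + 1.0)
        poses = make_poses(n, u, v)
        occ_u = np.concatenate(
            [np.full(40, -90.0), _ease(70, -90.0, 420.0), np.full(n - 110, 420.0)]
        )
        occ = OccluderProgram(
            kind="rigid",
            poses=make_poses(n, occ_u, np.full(n, 120.0)),
            size=(70, 120),
        )
        return SequenceConfig(poses=poses, occluders=[occ], seed=seed)
    if name == "tissue_occlusion":
        n = 150
        poses = make_poses(n, 120.0, 120.0)
        occ_v = np.concatenate(
            [np.full(40, -80.0), _ease(70, -80.0, 330.0), np.full(n - 110, 330.0)]
        )
        occ = OccluderProgram(
            kind="blob",
            poses=make_poses(n, np.full(n, 120.0), occ_v),
            size=(62, 48),
        )
        return SequenceConfig(poses=poses, occluders=[occ], seed=seed)
    if name == "out_of_view":
        n = 120
        u = np.concatenate(
            [
                np.full(30, 140.0),
                _ease(15, 140.0, 420.0),  # exits the 320-wide image
                np.full(30, 420.0),  # fully absent
                _ease(15, 420.0, 140.0),
                np.full(n - 90, 140.0),
            ]
        )
        poses = make_poses(n, u, 120.0)
        return SequenceConfig(poses=poses, seed=seed)
    if name == "long_term":
        n = 2000
        t = np.arange(n)
        u = 160.0 + 55.0 * np.sin(2 * np.pi * t / 600.0)
        v = 120.0 + 38.0 * np.sin(2 * np.pi * t / 450.0 + 1.0)
        theta = 0.35 * np.sin(2 * np.pi * t / 800.0)
        scale = 1.0 + 0.12 * np.sin(2 * np.pi * t / 700.0)
        return SequenceConfig(poses=make_poses(n, u, v, theta, scale), seed=seed)
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def save_sequence(frames, truth, outdir):
    """Write frames as zero-padded PNGs plus ground_truth.csv."""
    import os

    import imageio.v3 as iio

    os.makedirs(outdir, exist_ok=True)
    width = max(6, len(str(len(frames) - 1)))
    for i, frame in enumerate(frames):
        iio.imwrite(os.path.join(outdir, f"{i:0{width}d}.png"), frame)
    truth.to_csv(os.path.join(outdir, "ground_truth.csv"), index=False)
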