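"""Recursive Bayesian color-histogram foreground/background model.

Each pixel is treated as a two-class hidden Markov chain (foreground /
background) observed through its HSV color.  The per-pixel foreground
posterior at frame t is

    p(c_t=1 | y_1:t) = Z^-1 * p(y_t | c_t=1) * sum_c p(c_t=1 | c_{t-1}=c) p(c_{t-1}=c | y_1:{t-1})

with the symmetric expression for the background class and Z normalising the
two to one.  Color likelihoods are global histograms: a 12x12 hue-saturation
histogram for chromatic pixels and a separate 8-bin value histogram for
achromatic pixels (low saturation or low value), the two sharing a single
normalization.  The foreground histogram is built from pixels inside the
convex hull of the positive (center-supporting) keypoints — a region that
contains far fewer background pixels than the bounding box — and the
background histogram from an annular region surrounding the detected box.
Both are adapted per frame by exponential blending with factor delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2hsv

from ._geometry import convex_hull_mask, rect_mask, rect_scale

__all__ = [
    "ColorHistogram",
    "SegmentationModel",
    "ProbabilityMap",
    "init_segmentation",
    "posterior_map",
    "update_histograms",
    "keypoint_weight",
    "likelihood_ratio_map",
]

HS_BINS = 12
V_BINS = 8
# pixels below these saturation/value fractions carry no reliable hue and are
# routed to the value-only histogram
SATURATION_MIN = 0.10
VALUE_MIN = 0.15
EPS = 1e-12


def _hsv_of(image):
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an RGB image")
    if img.dtype == np.uint8:
        img = img / 255.0
    return rgb2hsv(img)


def _bin_indices(hsv):
    """Per-pixel (chromatic flag, hs flat bin, v bin) for an HSV image/array."""
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    chromatic = (s > SATURATION_MIN) & (v > VALUE_MIN)
    hb = np.minimum((h * HS_BINS).astype(int), HS_BINS - 1)
    sb = np.minimum((s * HS_BINS).astype(int), HS_BINS - 1)
    vb = np.minimum((v * V_BINS).astype(int), V_BINS - 1)
    return chromatic, hb * HS_BINS + sb, vb


@dataclass
class ColorHistogram:
    """Joint HSV histogram: 12x12 hue-saturation bins plus 8 value bins.

    Chromatic pixels populate the H-S part, achromatic pixels the V part;
    normalization is shared so the whole histogram sums to one.
    """

    hs_bins: np.ndarray = field(default_factory=lambda: np.zeros((HS_BINS, HS_BINS)))
    v_bins: np.ndarray = field(default_factory=lambda: np.zeros(V_BINS))

    def total(self):
        return float(self.hs_bins.sum() + self.v_bins.sum())

    def normalized(self):
        t = self.total()
        if t <= 0:
            # empty histogram: fall back to uniform so lookups stay defined
            n = HS_BINS * HS_BINS + V_BINS
            return ColorHistogram(
                np.full((HS_BINS, HS_BINS), 1.0 / n), np.full(V_BINS, 1.0 / n)
            )
        return ColorHistogram(self.hs_bins / t, self.v_bins / t)

    def lookup(self, hsv):
        """Per-pixel likelihood p(y|c) for an HSV image (any leading shape)."""
        chromatic, hs_flat, vb = _bin_indices(hsv)
        out = np.where(chromatic, self.hs_bins.ravel()[hs_flat], self.v_bins[vb])
        return out

    @classmethod
    def from_pixels(cls, hsv_pixels):
        """Build a normalized histogram from an (n, 3) array of HSV pixels."""
        hist = cls()
        if hsv_pixels.shape[0] == 0:
            return hist.normalized()
        chromatic, hs_flat, vb = _bin_indices(hsv_pixels)
        np.add.at(hist.hs_bins.ravel(), hs_flat[chromatic], 1.0)
        np.add.at(hist.v_bins, vb[~chromatic], 1.0)
        return hist.normalized()


@dataclass
class ProbabilityMap:
    """Per-pixel foreground posterior, same extent as the frame."""

    values: np.ndarray

    def to_uint8(self):
        """8-bit grayscale rendering (value = round(255 p)) for debugging."""
        return np.round(255.0 * np.clip(self.values, 0.0, 1.0)).astype(np.uint8)


def _transition(stay_prob):
    t = np.array([[stay_prob, 1.0 - stay_prob], [1.0 - stay_prob, stay_prob]])
    return t


@dataclass
class SegmentationModel:
    """Foreground/background histograms + previous posterior + dynamics.

    ``transition[i, j] = p(c_t = j | c_{t-1} = i)`` with class 0 background,
    class 1 foreground.  ``update_factor`` is the histogram blending factor
    delta (0.1 by default).
    """

    fg_hist: ColorHistogram
    bg_hist: ColorHistogram
    prev_posterior: np.ndarray
    transition: np.ndarray = field(default_factory=lambda: _transition(0.6))
    update_factor: float = 0.1

    def __post_init__(self):
        if not (0.0 <= self.update_factor < 1.0):
            # delta = 0 is the "frozen histograms" limit case
            raise ValueError("update factor must lie in [0, 1)")
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")


def background_region_mask(shape_hw, bbox, inner=1.25, outer=1.75):
    """Annular background-sampling region around the detected bbox.

    The region between the bbox scaled by ``inner`` and by ``outer`` (about
    its center), clipped to the image: close enough to be representative,
    with a margin keeping stray object pixels out.
    """
    outer_mask = rect_mask(shape_hw, rect_scale(bbox, outer))
    inner_mask = rect_mask(shape_hw, rect_scale(bbox, inner))
    ann = outer_mask & ~inner_mask
    if not ann.any():
        # bbox covers (almost) the whole view: use everything outside it
        ann = ~rect_mask(shape_hw, bbox)
    return ann


def init_segmentation(
    image,
    positive_keypoints,
    detected_bbox,
    stay_prob=0.6,
    update_factor=0.1,
):
    """Initialize the segmentation model from the first detection.

    The foreground histogram is built from pixels inside the convex hull of
    the positive keypoints; when the hull is degenerate (fewer than three
    non-collinear points) the detected bbox is used instead.  The background
    histogram comes from the annulus surrounding the bbox, and the posterior
    starts uninformative at 0.5 everywhere.
    """
    hsv = _hsv_of(image)
    shape = hsv.shape[:2]
    pts = np.atleast_2d(np.asarray(positive_keypoints, dtype=float)) if len(
        positive_keypoints
    ) else np.zeros((0, 2))
    fg_mask = convex_hull_mask(shape, pts) if pts.shape[0] >= 3 else None
    if fg_mask is None:
        fg_mask = rect_mask(shape, detected_bbox)
    fg_hist = ColorHistogram.from_pixels(hsv[fg_mask])
    bg_mask = background_region_mask(shape, detected_bbox)
    bg_hist = ColorHistogram.from_pixels(hsv[bg_mask])
    return SegmentationModel(
        fg_hist=fg_hist,
        bg_hist=bg_hist,
        prev_posterior=np.full(shape, 0.5),
        transition=_transition(stay_prob),
        update_factor=update_factor,
    )


def posterior_map(model, image):
    """Per-pixel foreground posterior for the new frame (recursive update).

    Combines the color likelihoods with the class-transition prediction from
    the previous frame's posterior and renormalises the two classes to sum
    to one.  The result replaces ``model.prev_posterior``.
    """
    hsv = _hsv_of(image)
    if hsv.shape[:2] != model.prev_posterior.shape:
        raise ValueError("posterior extent does not match image")
    fgl = model.fg_hist.lookup(hsv)
    bgl = model.bg_hist.lookup(hsv)
    prior = model.prev_posterior
    T = model.transition
    pred_fg = T[1, 1] * prior + T[0, 1] * (1.0 - prior)
    pred_bg = T[1, 0] * prior + T[0, 0] * (1.0 - prior)
    num_fg = fgl * pred_fg
    num_bg = bgl * pred_bg
    denom = num_fg + num_bg
    # exact two-class normalization; where both likelihoods vanish the
    # posterior stays at the predicted prior
    with np.errstate(invalid="ignore", divide="ignore"):
        post = np.where(denom > 0.0, num_fg / np.where(denom > 0.0, denom, 1.0), pred_fg)
    model.prev_posterior = post
    return ProbabilityMap(values=post)


def update_histograms(model, image, positive_hull, detected_bbox):
    """Blend this frame's region histograms into the model (factor delta).

    ``positive_hull`` is the polygon (or point set) of positive keypoints;
    an empty or degenerate hull leaves the foreground histogram unchanged
    for this frame.  The background histogram updates symmetrically from
    the annulus around ``detected_bbox``.
    """
    hsv = _hsv_of(image)
    shape = hsv.shape[:2]
    d = model.update_factor

    pts = np.atleast_2d(np.asarray(positive_hull, dtype=float)) if len(
        positive_hull
    ) else np.zeros((0, 2))
    fg_mask = convex_hull_mask(shape, pts) if pts.shape[0] >= 3 else None
    if fg_mask is not None:
        new_fg = ColorHistogram.from_pixels(hsv[fg_mask])
        model.fg_hist = ColorHistogram(
            d * new_fg.hs_bins + (1.0 - d) * model.fg_hist.hs_bins,
            d * new_fg.v_bins + (1.0 - d) * model.fg_hist.v_bins,
        ).normalized()

    bg_mask = background_region_mask(shape, detected_bbox)
    if bg_mask.any():
        new_bg = ColorHistogram.from_pixels(hsv[bg_mask])
        model.bg_hist = ColorHistogram(
            d * new_bg.hs_bins + (1.0 - d) * model.bg_hist.hs_bins,
            d * new_bg.v_bins + (1.0 - d) * model.bg_hist.v_bins,
        ).normalized()
    return model


def keypoint_weight(prob_map, keypoint, patch_half_width=None):
    """Mean foreground probability over the square patch around a keypoint.

    The patch half-width defaults to max(4, 1.5 * detector scale) so it
    grows with the feature's support; at image borders the mean is taken
    over the valid intersection only.
    """
    values = prob_map.values
    H, W = values.shape
    u, v = keypoint.position
    if patch_half_width is None:
        patch_half_width = max(4.0, 1.5 * keypoint.detector_scale)
    r = int(round(patch_half_width))
    cu, cv = int(round(u)), int(round(v))
    u0, u1 = max(cu - r, 0), min(cu + r + 1, W)
    v0, v1 = max(cv - r, 0), min(cv + r + 1, H)
    if u1 <= u0 or v1 <= v0:
        return 0.0
    return float(values[v0:v1, u0:u1].mean())


def likelihood_ratio_map(model, image):
    """Posterior under a flat 0.5 prior: p = L_fg / (L_fg + L_bg).

    Used in reset (re-detection) mode, where the recursive posterior is
    stale because the target left the view; the frozen histograms still
    carry the color evidence.
    """
    hsv = _hsv_of(image)
    fgl = model.fg_hist.lookup(hsv)
    bgl = model.bg_hist.lookup(hsv)
    denom = fgl + bgl
    post = np.where(denom > 0.0, fgl / np.where(denom > 0.0, denom, 1.0), 0.5)
    return ProbabilityMap(values=post)
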