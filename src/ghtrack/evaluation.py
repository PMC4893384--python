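"""Tracker evaluation: center location error, precision plots, box statistics.

The standard benchmark methodology for single-target trackers: the per-frame
location error is the Euclidean distance between the estimated and true
center; the precision plot shows the fraction of frames with error below a
threshold as a function of that threshold, summarised by the area under the
curve (AUC).  Missed detections are accounted in one of two ways: over the
whole sequence with infinite error assigned to missed frames, or restricted
to the frames where all compared trackers report a detection.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

__all__ = [
    "PrecisionCurve",
    "ErrorSummary",
    "location_error",
    "precision_curve",
    "summarize_errors",
    "default_thresholds",
]


def default_thresholds():
    """0-50 px in 1 px steps; any monotone grid preserves comparisons."""
    return np.arange(0.0, 51.0, 1.0)


@dataclass
class PrecisionCurve:
    """Precision (fraction of frames within threshold) over a threshold grid."""

    thresholds: np.ndarray
    precision: np.ndarray
    auc: float

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        ax.plot(self.thresholds, self.precision, **kwargs)
        ax.set_xlabel("location error threshold (px)")
        ax.set_ylabel("precision")
        ax.set_ylim(0.0, 1.05)
        return ax


@dataclass
class ErrorSummary:
    """Box-plot statistics of per-frame errors (1.5 IQR outlier fences)."""

    mean: float
    std: float
    q25: float
    median: float
    q75: float
    whisker_low: float
    whisker_high: float
    outliers: np.ndarray


def location_error(estimate, truth):
    """Euclidean distance between estimated and true center, pixels."""
    e = np.asarray(estimate, dtype=float)
    t = np.asarray(truth, dtype=float)
    if not (np.all(np.isfinite(e)) and np.all(np.isfinite(t))):
        raise ValueError("positions must be finite")
    return float(np.hypot(*(e - t).T)) if e.ndim == 1 else np.hypot(*(e - t).T)


def precision_curve(
    errors,
    missed=None,
    thresholds=None,
    mode="whole_sequence",
    common_mask=None,
):
    """Precision plot and AUC from per-frame errors and missed-detection flags.

    ``mode="whole_sequence"`` scores every frame, treating missed detections
    as infinite error; ``mode="common_frames"`` restricts scoring to
    ``common_mask`` (frames where all compared trackers detected).  AUC is
    the mean precision over the (uniform) threshold grid.  An empty common
    mask yields None rather than a crash.
    """
    errors = np.asarray(errors, dtype=float)
    if errors.size == 0:
        raise ValueError("need at least one frame")
    if missed is None:
        missed = ~np.isfinite(errors)
    missed = np.asarray(missed, dtype=bool)
    if thresholds is None:
        thresholds = default_thresholds()
    thresholds = np.asarray(thresholds, dtype=float)

    eff = np.where(missed, np.inf, errors)
    if mode == "whole_sequence":
        sel = np.ones_like(missed)
    elif mode == "common_frames":
        if common_mask is None:
            common_mask = ~missed
        sel = np.asarray(common_mask, dtype=bool)
        if not sel.any():
            return None
    else:
        raise ValueError(f"unknown mode {mode!r}")
    eff = eff[sel]
    precision = np.array([(eff <= th).mean() for th in thresholds])
    return PrecisionCurve(
        thresholds=thresholds, precision=precision, auc=float(precision.mean())
    )


def summarize_errors(errors):
    """Mean +/- std, quartiles, whiskers and outliers of per-frame errors.

    Whiskers extend to the most extreme points within 1.5 IQR of the box
    edges; points beyond are listed as outliers (the conventional box-plot
    rule).
    """
    e = np.asarray(errors, dtype=float)
    if e.size == 0:
        raise ValueError("need at least one value")
    q25, med, q75 = np.percentile(e, [25, 50, 75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inliers = e[(e >= lo_fence) & (e <= hi_fence)]
    return ErrorSummary(
        mean=float(e.mean()),
        std=float(e.std()),
        q25=float(q25),
        median=float(med),
        q75=float(q75),
        whisker_low=float(inliers.min()),
        whisker_high=float(inliers.max()),
        outliers=np.sort(e[(e < lo_fence) | (e > hi_fence)]),
    )
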