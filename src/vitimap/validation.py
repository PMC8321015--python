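"""Detection validation against gold-standard masks, and threshold
robustness analysis.

A detected mask is scored against a dermatologist-style gold standard by
partitioning pixels into true positives (detected and marked), false
positives (detected only) and false negatives (marked only); the success
rate is the true-positive area over the union area (tp + fp + fn), in
percent, so 100% means perfect agreement and 0% means disjoint masks.
The overlay raster colors the partition green / red / blue respectively.

The stability map sweeps the global threshold over a range (default
0.35-0.65, i.e. 0.5 +/- 30%) and reports, per pixel, the percentage of
sweep values that detect it: the 100-valued core is the threshold-robust
part of the patches, while lower values trace the contour pixels that the
threshold fine-tunes.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .roi_detection import PolygonRoi, detect_patches

log = logging.getLogger(__name__)

#: Default sweep range and step count for the robustness analysis.
DEFAULT_SWEEP = (0.35, 0.65, 7)

TP_COLOR = (0, 255, 0)    # detected by both
FP_COLOR = (255, 0, 0)    # detected by the tool only
FN_COLOR = (0, 0, 255)    # marked in the gold standard only


@dataclasses.dataclass(frozen=True)
class ValidationResult:
    tp_pixels: int
    fp_pixels: int
    fn_pixels: int
    success_rate: float
    overlay: np.ndarray


@dataclasses.dataclass(frozen=True)
class StabilityMap:
    """Per-pixel detection frequency (percent) over the swept thresholds."""

    matrix: np.ndarray
    thresholds: np.ndarray


def compare_masks(detected: np.ndarray, gold: np.ndarray) -> ValidationResult:
    """Score a detected mask against the gold standard.

    success_rate = 100 * tp / (tp + fp + fn); when both masks are empty
    there is no lesion and no disagreement, so the rate is defined as 100
    with a warning.
    """
    d = np.asarray(detected).astype(bool)
    g = np.asarray(gold).astype(bool)
    if d.shape != g.shape:
        raise ValueError(f"mask shapes differ: {d.shape} vs {g.shape}")
    tp = int(np.count_nonzero(d & g))
    fp = int(np.count_nonzero(d & ~g))
    fn = int(np.count_nonzero(~d & g))
    union = tp + fp + fn
    if union == 0:
        log.warning("both masks empty: success rate defined as 100%%")
        rate = 100.0
    else:
        rate = 100.0 * tp / union
    overlay = np.zeros(d.shape + (3,), dtype=np.uint8)
    overlay[d & g] = TP_COLOR
    overlay[d & ~g] = FP_COLOR
    overlay[~d & g] = FN_COLOR
    return ValidationResult(tp_pixels=tp, fp_pixels=fp, fn_pixels=fn,
                            success_rate=rate, overlay=overlay)


def threshold_sweep(
    filtered: np.ndarray,
    rois: list[PolygonRoi],
    t_min: float = DEFAULT_SWEEP[0],
    t_max: float = DEFAULT_SWEEP[1],
    n_steps: int = DEFAULT_SWEEP[2],
) -> StabilityMap:
    """Run detection at ``n_steps`` evenly spaced global thresholds
    (endpoints included) and report per-pixel detection frequency.

    Because detection is monotone in the threshold, every cell value is
    100*k/n_steps with the detecting runs forming a prefix of the ascending
    threshold list, and the 100-valued cells coincide with the detection
    mask at ``t_max``.
    """
    if not (0.0 <= t_min < t_max <= 1.0):
        raise ValueError(
            f"need 0 <= t_min < t_max <= 1, got [{t_min}, {t_max}]"
        )
    if n_steps < 2:
        raise ValueError(f"n_steps must be >= 2, got {n_steps}")
    thresholds = np.linspace(t_min, t_max, n_steps)
    counts = np.zeros(np.asarray(filtered).shape, dtype=np.int64)
    for t in thresholds:
        counts += detect_patches(filtered, rois, float(t)).pixels
    return StabilityMap(matrix=100.0 * counts / n_steps, thresholds=thresholds)
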