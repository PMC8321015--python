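"""Polygonal ROIs and the adaptive-threshold patch detection.

The user (or the synthetic generator) supplies a rough polygonal contour
for each region of interest.  Detection then runs per ROI: the global
threshold ``t`` in [0, 1] is rescaled by the maximum filtered gray level of
that ROI, giving an adaptive cutoff ``t * max(ROI)``; every ROI pixel at or
above the cutoff is marked as vitiligo.  Scaling by the local maximum makes
the same global threshold work across unevenly lit face regions, which is
the reason shady areas should get their own ROI.

Limit behavior: ``t = 0`` marks every ROI pixel (manual contouring);
``t = 1`` marks only the pixels at the ROI's maximum gray level.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

log = logging.getLogger(__name__)

_BOUNDARY_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class PolygonRoi:
    """Implicitly closed polygon given as an ordered (N, 2) array of
    (x, y) = (col, row) float vertices, N >= 3."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError(
                f"a polygon needs an (N>=3, 2) vertex array, got shape {v.shape}"
            )
        object.__setattr__(self, "vertices", v)

    def to_list(self) -> list:
        return self.vertices.tolist()

    @classmethod
    def from_list(cls, vertices: list) -> "PolygonRoi":
        return cls(vertices=np.asarray(vertices, dtype=float))


@dataclasses.dataclass(frozen=True)
class PatchMask:
    """Binary vitiligo map plus per-pixel provenance: the 1-based index of
    the first ROI that detected each pixel, 0 for background."""

    pixels: np.ndarray
    provenance: np.ndarray

    def __post_init__(self) -> None:
        if self.pixels.shape != self.provenance.shape:
            raise ValueError("pixels and provenance shapes differ")


def _on_boundary(px, py, x1, y1, x2, y2):
    """Points (px, py) lying on segment (x1,y1)-(x2,y2), vectorized."""
    cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
    within = ((px >= np.minimum(x1, x2) - _BOUNDARY_TOL)
              & (px <= np.maximum(x1, x2) + _BOUNDARY_TOL)
              & (py >= np.minimum(y1, y2) - _BOUNDARY_TOL)
              & (py <= np.maximum(y1, y2) + _BOUNDARY_TOL))
    seg_len = np.hypot(x2 - x1, y2 - y1)
    return within & (np.abs(cross) <= _BOUNDARY_TOL * max(seg_len, 1.0))


def rasterize_roi(roi: PolygonRoi, height: int, width: int) -> np.ndarray:
    """Rasterize a polygon: a pixel is set iff its center (integer x, y)
    lies strictly inside the polygon under the even-odd rule, or on its
    boundary.

    Raises ``ValueError`` if no pixel center falls inside (degenerate or
    fully out-of-frame polygon).
    """
    v = roi.vertices
    # confine the test to the polygon's bounding box, clamped to the frame
    x0 = max(int(np.floor(v[:, 0].min())), 0)
    x1 = min(int(np.ceil(v[:, 0].max())), width - 1)
    y0 = max(int(np.floor(v[:, 1].min())), 0)
    y1 = min(int(np.ceil(v[:, 1].max())), height - 1)
    mask = np.zeros((height, width), dtype=bool)
    if x0 > x1 or y0 > y1:
        raise ValueError("polygon rasterizes to zero area (outside the frame)")
    py, px = np.mgrid[y0:y1 + 1, x0:x1 + 1].astype(float)
    inside = np.zeros(px.shape, dtype=bool)
    boundary = np.zeros(px.shape, dtype=bool)
    n = len(v)
    for i in range(n):
        xa, ya = v[i]
        xb, yb = v[(i + 1) % n]
        boundary |= _on_boundary(px, py, xa, ya, xb, yb)
        if ya == yb:
            continue
        crosses = (ya > py) != (yb > py)
        with np.errstate(invalid="ignore"):
            xint = xa + (py - ya) * (xb - xa) / (yb - ya)
        inside ^= crosses & (px < xint)
    region = inside | boundary
    if not region.any():
        raise ValueError("polygon rasterizes to zero area")
    mask[y0:y1 + 1, x0:x1 + 1] = region
    return mask


def detect_patches(
    filtered: np.ndarray,
    rois: list[PolygonRoi],
    global_threshold: float,
) -> PatchMask:
    """Adaptive-threshold vitiligo detection over a list of ROIs.

    Each ROI is thresholded independently at ``global_threshold`` times its
    own maximum filtered gray level (comparison is >=, so the maximum pixel
    is always detected); per-ROI detections combine by union.  An ROI whose
    maximum gray level is 0 carries no usable contrast: it is skipped with
    a warning unless the global threshold is exactly 0, in which case all
    its pixels are marked (the manual-contouring limit).
    """
    if not rois:
        raise ValueError("at least one ROI is required for detection")
    if not (0.0 <= global_threshold <= 1.0):
        raise ValueError(
            f"global threshold must be in [0, 1], got {global_threshold}"
        )
    filt = np.asarray(filtered, dtype=float)
    height, width = filt.shape
    pixels = np.zeros((height, width), dtype=bool)
    provenance = np.zeros((height, width), dtype=np.int32)
    for idx, roi in enumerate(rois, start=1):
        region = rasterize_roi(roi, height, width)
        roi_max = float(filt[region].max())
        if roi_max == 0.0:
            if global_threshold == 0.0:
                selected = region
            else:
                log.warning(
                    "ROI %d has zero maximum gray level; skipped "
                    "(set the global threshold to 0 to contour it manually)",
                    idx,
                )
                continue
        else:
            adaptive_t = global_threshold * roi_max
            selected = region & (filt >= adaptive_t)
            log.info("ROI %d: max gray %.4f, adaptive threshold %.4f",
                     idx, roi_max, adaptive_t)
        provenance[selected & (provenance == 0)] = idx
        pixels |= selected
    return PatchMask(pixels=pixels, provenance=provenance)


def manual_patch(roi: PolygonRoi, height: int, width: int) -> PatchMask:
    """Manual patch contouring: every pixel of the ROI is marked, which is
    exactly :func:`detect_patches` on that single ROI at threshold 0."""
    region = rasterize_roi(roi, height, width)
    return PatchMask(pixels=region,
                     provenance=region.astype(np.int32))
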