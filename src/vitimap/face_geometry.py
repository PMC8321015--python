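"""Face-contour geometry and template registration.

Every patient photograph carries an axis-aligned ellipse roughly contouring
the face.  The ellipse serves two purposes: it gives a face-area reference
for patch-area fractions, and it defines the affine (scale + translate)
mapping that normalizes each patient's detected pixels onto a fixed
610-row x 407-column face template, so that detections from different
patients can be aggregated into one population occurrence map.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

log = logging.getLogger(__name__)

#: Working frame in pixels, (rows, cols).  Every photograph is rescaled to
#: this size on ingest; it equals the size of the face-template raster so
#: that registered coordinates index the occurrence matrix directly.
FRAME_HEIGHT = 610
FRAME_WIDTH = 407
FRAME_SHAPE = (FRAME_HEIGHT, FRAME_WIDTH)


@dataclasses.dataclass(frozen=True)
class FaceEllipse:
    """Axis-aligned ellipse: center (cx, cy) in pixel (x=col, y=row)
    coordinates, horizontal semi-axis ``a`` and vertical semi-axis ``b``,
    both in pixels and strictly positive."""

    cx: float
    cy: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(
                f"ellipse semi-axes must be positive, got a={self.a}, b={self.b}"
            )

    def to_dict(self) -> dict:
        return {"cx": self.cx, "cy": self.cy, "a": self.a, "b": self.b}

    @classmethod
    def from_dict(cls, d: dict) -> "FaceEllipse":
        return cls(cx=float(d["cx"]), cy=float(d["cy"]),
                   a=float(d["a"]), b=float(d["b"]))


def ellipse_area(e: FaceEllipse) -> float:
    """Area of the face ellipse in pixels^2 (pi * a * b)."""
    return math.pi * e.a * e.b


def rasterize_ellipse(e: FaceEllipse, height: int, width: int) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside or on the ellipse."""
    yy, xx = np.mgrid[0:height, 0:width]
    return ((xx - e.cx) / e.a) ** 2 + ((yy - e.cy) / e.b) ** 2 <= 1.0


def patch_area_fraction(mask: np.ndarray, e: FaceEllipse) -> float:
    """Detected patch area as a fraction of the face-ellipse area.

    The patch area is the raw set-pixel count of the binary mask, the face
    area is the analytic ellipse area pi*a*b; the fraction is dimensionless
    and can slightly exceed the true skin fraction because the ellipse is
    only a rough face contour.
    """
    return float(np.count_nonzero(mask)) / ellipse_area(e)


def round_half_away(values: np.ndarray) -> np.ndarray:
    """Round to nearest integer with ties going away from zero.

    Stated explicitly (rather than relying on a language's default banker's
    rounding) so registered coordinates are reproducible across platforms.
    """
    v = np.asarray(values, dtype=float)
    return np.copysign(np.floor(np.abs(v) + 0.5), v).astype(np.int64)


def to_template(
    points: np.ndarray,
    patient_e: FaceEllipse,
    template_e: FaceEllipse,
    frame_shape: tuple[int, int] = FRAME_SHAPE,
) -> np.ndarray:
    """Map (x, y) pixel coordinates from a patient image onto the template.

    Coordinates are scaled per-axis by the ratio of template to patient
    semi-axes and translated so the patient's ellipse center lands on the
    template ellipse center, then rounded to integer pixel coordinates.
    Points that fall outside the template frame are dropped with a warning.

    Parameters
    ----------
    points : (N, 2) array of float (x, y) coordinates.

    Returns
    -------
    (M, 2) int64 array of template (x, y) coordinates, M <= N.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    sx = template_e.a / patient_e.a
    sy = template_e.b / patient_e.b
    x = round_half_away(template_e.cx + (pts[:, 0] - patient_e.cx) * sx)
    y = round_half_away(template_e.cy + (pts[:, 1] - patient_e.cy) * sy)
    h, w = frame_shape
    keep = (x >= 0) & (x < w) & (y >= 0) & (y < h)
    n_drop = int(np.count_nonzero(~keep))
    if n_drop:
        log.warning("to_template: dropped %d point(s) mapping outside the "
                    "%dx%d frame", n_drop, h, w)
    return np.stack([x[keep], y[keep]], axis=1)


def register_mask(
    mask: np.ndarray,
    patient_e: FaceEllipse,
    template_e: FaceEllipse,
    frame_shape: tuple[int, int] = FRAME_SHAPE,
) -> np.ndarray:
    """Register a binary patch mask onto the template frame.

    The set-pixel coordinates are mapped with :func:`to_template` and
    re-binarized: a template cell is set if at least one patient pixel maps
    to it, so one patient can never contribute more than 1 to any
    occurrence-matrix cell even where rounding collapses several source
    pixels onto one template cell.
    """
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    pts = np.stack([xs, ys], axis=1).astype(float)
    mapped = to_template(pts, patient_e, template_e, frame_shape)
    out = np.zeros(frame_shape, dtype=bool)
    if mapped.size:
        out[mapped[:, 1], mapped[:, 0]] = True
    return out


#: Ellipse of the bundled neutral face template (fixed by convention; any
#: user-supplied template may replace it via the CLI --template option).
DEFAULT_TEMPLATE_ELLIPSE = FaceEllipse(cx=203.5, cy=305.0, a=180.0, b=280.0)


@dataclasses.dataclass(frozen=True)
class TemplateFace:
    """Reference face raster (grayscale, [0, 1], FRAME_SHAPE) plus the
    ellipse that registration maps every patient ellipse onto."""

    image: np.ndarray
    ellipse: FaceEllipse

    def __post_init__(self) -> None:
        if self.image.shape != FRAME_SHAPE:
            raise ValueError(
                f"template raster must be {FRAME_SHAPE}, got {self.image.shape}"
            )


def default_template() -> TemplateFace:
    """Synthetic neutral face template, generated deterministically.

    A light face ellipse on dark background with schematic eyes, nose and
    mouth, serving as the visual reference under the occurrence-map overlay.
    """
    e = DEFAULT_TEMPLATE_ELLIPSE
    img = np.full(FRAME_SHAPE, 0.08)
    face = rasterize_ellipse(e, *FRAME_SHAPE)
    img[face] = 0.75
    # schematic features, placed proportionally to the ellipse axes
    for dx in (-0.38, 0.38):  # eyes
        eye = FaceEllipse(e.cx + dx * e.a, e.cy - 0.25 * e.b,
                          0.16 * e.a, 0.06 * e.b)
        img[rasterize_ellipse(eye, *FRAME_SHAPE)] = 0.25
    nose = FaceEllipse(e.cx, e.cy + 0.08 * e.b, 0.07 * e.a, 0.14 * e.b)
    img[rasterize_ellipse(nose, *FRAME_SHAPE)] = 0.55
    mouth = FaceEllipse(e.cx, e.cy + 0.45 * e.b, 0.30 * e.a, 0.05 * e.b)
    img[rasterize_ellipse(mouth, *FRAME_SHAPE)] = 0.30
    return TemplateFace(image=img, ellipse=e)
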