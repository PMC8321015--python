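"""Synthetic black-light face photographs with known ground truth.

Real acquisitions are portrait photographs under ~365 nm illumination: the
face is an ellipse on a dark background, healthy skin is dominated by the
red channel, and depigmented vitiligo patches fluoresce, boosting the blue
and green channels.  The generator reproduces these conditions, plus the
nuisances reported in clinical use — uneven illumination, overexposed
cheek spots, beard texture and hair-strand occlusions — while keeping an
exact per-pixel ground-truth mask, so every pipeline stage can be tested
without patient data.

Scenes are fully determined by a :class:`SceneSpec` (seeded), and
:func:`generate_cohort` produces a whole on-disk cohort (images, session
files, ground-truth masks, metadata CSV).  An ``occurrence_design`` can pin
rectangular template regions to chosen patient subsets, making the
population occurrence percentages over those regions exactly predictable.
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .face_geometry import (FRAME_HEIGHT, FRAME_SHAPE, FRAME_WIDTH,
                            FaceEllipse, TemplateFace, default_template,
                            rasterize_ellipse, round_half_away)
from .image_io import AnnotationSession, PatientRecord, save_image, save_mask, save_session
from .roi_detection import PolygonRoi

#: Base skin color under black light: red-dominant, fairly dark.
DEFAULT_SKIN_RGB = (0.55, 0.35, 0.30)
BACKGROUND_LEVEL = 0.02
OCCLUSION_LEVEL = 0.03
OVEREXPOSED_LEVEL = 0.97

DEFAULT_BLUE_BOOST = 0.3
DEFAULT_GREEN_BOOST = 0.15
DEFAULT_NOISE_SIGMA = 0.01
DEFAULT_ILLUMINATION_STRENGTH = 0.2
DEFAULT_ROI_DILATION = 5
DEFAULT_PATCHES_RANGE = (3, 6)


@dataclasses.dataclass(frozen=True)
class PatchSpec:
    """Elliptical fluorescent patch: center (x, y), semi-axes (rx, ry),
    and the additive channel boosts that make it stand out."""

    center: tuple[float, float]
    radii: tuple[float, float]
    blue_boost: float = DEFAULT_BLUE_BOOST
    green_boost: float = DEFAULT_GREEN_BOOST

    def __post_init__(self) -> None:
        if self.blue_boost <= 0:
            raise ValueError("blue_boost must be positive")


@dataclasses.dataclass(frozen=True)
class RectPatch:
    """Axis-aligned rectangular patch with inclusive integer pixel bounds
    (col_lo, col_hi, row_lo, row_hi); used for designed occurrence regions
    whose template footprint must be pixel-exact."""

    col_lo: int
    col_hi: int
    row_lo: int
    row_hi: int
    blue_boost: float = DEFAULT_BLUE_BOOST
    green_boost: float = DEFAULT_GREEN_BOOST


@dataclasses.dataclass(frozen=True)
class OccludingBar:
    """Dark bar (e.g. a hair strand): segment endpoints plus width."""

    p0: tuple[float, float]
    p1: tuple[float, float]
    width: float


@dataclasses.dataclass
class SceneSpec:
    """Complete deterministic description of one synthetic photograph."""

    seed: int
    face_ellipse: FaceEllipse = dataclasses.field(
        default_factory=lambda: FaceEllipse(203.5, 305.0, 180.0, 280.0))
    skin_rgb: tuple[float, float, float] = DEFAULT_SKIN_RGB
    patches: tuple[PatchSpec, ...] = ()
    rect_patches: tuple[RectPatch, ...] = ()
    illumination_direction_deg: float = 90.0
    illumination_strength: float = DEFAULT_ILLUMINATION_STRENGTH
    overexposed_regions: tuple[FaceEllipse, ...] = ()
    beard_region: PolygonRoi | None = None
    beard_amplitude: float = 0.3
    occlusions: tuple[OccludingBar, ...] = ()
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    roi_dilation: float = DEFAULT_ROI_DILATION


def _ellipse_polygon(cx: float, cy: float, rx: float, ry: float,
                     n_vertices: int = 24) -> PolygonRoi:
    ang = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    xs = np.clip(cx + rx * np.cos(ang), 0, FRAME_WIDTH - 1)
    ys = np.clip(cy + ry * np.sin(ang), 0, FRAME_HEIGHT - 1)
    return PolygonRoi(vertices=np.stack([xs, ys], axis=1))


def _bar_mask(bar: OccludingBar) -> np.ndarray:
    yy, xx = np.mgrid[0:FRAME_HEIGHT, 0:FRAME_WIDTH].astype(float)
    x0, y0 = bar.p0
    x1, y1 = bar.p1
    dx, dy = x1 - x0, y1 - y0
    seg2 = dx * dx + dy * dy
    t = np.clip(((xx - x0) * dx + (yy - y0) * dy) / max(seg2, 1e-12), 0.0, 1.0)
    dist = np.hypot(xx - (x0 + t * dx), yy - (y0 + t * dy))
    return dist <= bar.width / 2.0


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray,
                                             AnnotationSession]:
    """Render one synthetic photograph.

    Returns
    -------
    image : (610, 407, 3) float RGB in [0, 1].
    ground_truth : boolean patch mask (occluded pixels excluded).
    session : one rough ROI per patch (the patch dilated by
        ``spec.roi_dilation`` pixels), the face ellipse, filter 4 and the
        default global threshold — the annotation a careful user would draw.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = FRAME_SHAPE
    img = np.full((h, w, 3), BACKGROUND_LEVEL)
    face = rasterize_ellipse(spec.face_ellipse, h, w)
    img[face] = spec.skin_rgb

    gt = np.zeros((h, w), dtype=bool)
    rois: list[PolygonRoi] = []
    for p in spec.patches:
        pm = rasterize_ellipse(
            FaceEllipse(p.center[0], p.center[1], p.radii[0], p.radii[1]),
            h, w) & face
        img[pm, 1] += p.green_boost
        img[pm, 2] += p.blue_boost
        gt |= pm
        rois.append(_ellipse_polygon(p.center[0], p.center[1],
                                     p.radii[0] + spec.roi_dilation,
                                     p.radii[1] + spec.roi_dilation))
    for r in spec.rect_patches:
        img[r.row_lo:r.row_hi + 1, r.col_lo:r.col_hi + 1, 1] += r.green_boost
        img[r.row_lo:r.row_hi + 1, r.col_lo:r.col_hi + 1, 2] += r.blue_boost
        gt[r.row_lo:r.row_hi + 1, r.col_lo:r.col_hi + 1] = True
        d = spec.roi_dilation
        xs = np.clip([r.col_lo - d, r.col_hi + d], 0, w - 1)
        ys = np.clip([r.row_lo - d, r.row_hi + d], 0, h - 1)
        rois.append(PolygonRoi(vertices=np.array(
            [[xs[0], ys[0]], [xs[1], ys[0]], [xs[1], ys[1]], [xs[0], ys[1]]],
            dtype=float)))

    if spec.beard_region is not None:
        from .roi_detection import rasterize_roi
        beard = rasterize_roi(spec.beard_region, h, w) & face
        texture = 1.0 - spec.beard_amplitude * rng.random((h, w))
        img[beard] *= texture[beard, None]

    # multiplicative illumination gradient across the frame
    if spec.illumination_strength > 0:
        theta = np.deg2rad(spec.illumination_direction_deg)
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        proj = np.cos(theta) * xx + np.sin(theta) * yy
        proj = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-12)
        img *= (1.0 - spec.illumination_strength * proj)[..., None]

    for e in spec.overexposed_regions:
        img[rasterize_ellipse(e, h, w)] = OVEREXPOSED_LEVEL

    for bar in spec.occlusions:
        bm = _bar_mask(bar)
        img[bm] = OCCLUSION_LEVEL
        gt &= ~bm  # occluded skin shows no fluorescence

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    session = AnnotationSession(rois=rois, ellipse=spec.face_ellipse,
                                filter_id=4, global_threshold=0.5)
    return img, gt, session


# ---------------------------------------------------------------------------
# cohort generation

@dataclasses.dataclass(frozen=True)
class RegionDesign:
    """A rectangular template region (inclusive template-pixel bounds
    x_lo..x_hi, y_lo..y_hi) assigned to a known subset of patients, so the
    aggregated occurrence over the region is exactly
    100 * len(patients) / n."""

    x_lo: int
    x_hi: int
    y_lo: int
    y_hi: int
    patients: tuple[int, ...]


@dataclasses.dataclass
class SyntheticPatient:
    """One generated cohort member, kept in memory alongside any files."""

    record: PatientRecord
    image: np.ndarray
    ground_truth: np.ndarray
    session: AnnotationSession
    spec: SceneSpec


def _designed_rect_patch(region: RegionDesign, patient_e: FaceEllipse,
                         template_e: FaceEllipse) -> RectPatch:
    """Patient-frame rectangle whose registered footprint is exactly the
    designed template rectangle.

    The patch is the preimage of the template rectangle under the forward
    (scale + translate + round) registration; because cohort ellipses are
    at least as large as the template's, the contraction guarantees every
    template cell of the rectangle is hit by some patient pixel.
    """
    cols = np.arange(FRAME_WIDTH)
    rows = np.arange(FRAME_HEIGHT)
    mapped_x = round_half_away(
        template_e.cx + (cols - patient_e.cx) * (template_e.a / patient_e.a))
    mapped_y = round_half_away(
        template_e.cy + (rows - patient_e.cy) * (template_e.b / patient_e.b))
    csel = np.nonzero((mapped_x >= region.x_lo) & (mapped_x <= region.x_hi))[0]
    rsel = np.nonzero((mapped_y >= region.y_lo) & (mapped_y <= region.y_hi))[0]
    if csel.size == 0 or rsel.size == 0:
        raise ValueError("designed region has empty preimage in the patient frame")
    return RectPatch(col_lo=int(csel.min()), col_hi=int(csel.max()),
                     row_lo=int(rsel.min()), row_hi=int(rsel.max()))


def _boxes_overlap(b1, b2, margin=0.0) -> bool:
    return not (b1[1] + margin < b2[0] or b2[1] + margin < b1[0]
                or b1[3] + margin < b2[2] or b2[3] + margin < b1[2])


def generate_cohort(
    n: int,
    seed: int,
    occurrence_design: dict[str, RegionDesign] | None = None,
    out_dir: str | Path | None = None,
    *,
    n_patches_range: tuple[int, int] = DEFAULT_PATCHES_RANGE,
    blue_boost: float = DEFAULT_BLUE_BOOST,
    green_boost: float = DEFAULT_GREEN_BOOST,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    illumination_strength: float = DEFAULT_ILLUMINATION_STRENGTH,
    roi_dilation: float = DEFAULT_ROI_DILATION,
    template: TemplateFace | None = None,
) -> list[SyntheticPatient]:
    """Generate a seeded synthetic cohort of ``n`` patients.

    Each patient gets a jittered face ellipse (never smaller than the
    template's, so registration contracts), 3-6 random fluorescent patches
    by default, and with some probability an overexposed cheek spot, a
    beard region or a hair-strand occlusion.  When ``occurrence_design``
    assigns template regions to patient subsets, those patients receive an
    extra rectangular patch registering exactly onto the region, and random
    patches are kept clear of all designed regions.

    If ``out_dir`` is given, writes ``<id>.png`` (image), ``<id>.json``
    (session), ``<id>_gt.png`` (ground truth) and ``cohort.csv``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    occurrence_design = occurrence_design or {}
    for name, region in occurrence_design.items():
        bad = [i for i in region.patients if not (0 <= i < n)]
        if bad:
            raise ValueError(
                f"region {name!r} references patient indices {bad} outside 0..{n-1}"
            )
    tmpl = template if template is not None else default_template()
    rng = np.random.default_rng(seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    patients: list[SyntheticPatient] = []
    rows = []
    for i in range(n):
        child_seed = int(rng.integers(2 ** 31))
        e = FaceEllipse(
            cx=tmpl.ellipse.cx + rng.uniform(-2, 2),
            cy=tmpl.ellipse.cy + rng.uniform(-2, 2),
            a=tmpl.ellipse.a * rng.uniform(1.0, 1.08),
            b=tmpl.ellipse.b * rng.uniform(1.0, 1.05),
        )
        rects = tuple(
            dataclasses.replace(
                _designed_rect_patch(region, e, tmpl.ellipse),
                blue_boost=blue_boost, green_boost=green_boost)
            for region in occurrence_design.values() if i in region.patients
        )
        # template-frame boxes to keep random patches away from designs
        forbidden = [(r.x_lo, r.x_hi, r.y_lo, r.y_hi)
                     for r in occurrence_design.values()]
        margin = roi_dilation + 3
        patches = []
        n_patches = int(rng.integers(n_patches_range[0], n_patches_range[1] + 1))
        for _ in range(n_patches):
            for _attempt in range(50):
                ang = rng.uniform(0, 2 * np.pi)
                rad = np.sqrt(rng.uniform()) * 0.72
                cx = e.cx + rad * e.a * np.cos(ang)
                cy = e.cy + rad * e.b * np.sin(ang)
                rx, ry = rng.uniform(8, 20, size=2)
                sx, sy = tmpl.ellipse.a / e.a, tmpl.ellipse.b / e.b
                box_t = (tmpl.ellipse.cx + (cx - rx - e.cx) * sx,
                         tmpl.ellipse.cx + (cx + rx - e.cx) * sx,
                         tmpl.ellipse.cy + (cy - ry - e.cy) * sy,
                         tmpl.ellipse.cy + (cy + ry - e.cy) * sy)
                if not any(_boxes_overlap(box_t, fb, margin) for fb in forbidden):
                    patches.append(PatchSpec(center=(cx, cy), radii=(rx, ry),
                                             blue_boost=blue_boost,
                                             green_boost=green_boost))
                    break
        # occasional nuisances, placed clear of the patch ROIs
        patch_boxes = [(p.center[0] - p.radii[0] - roi_dilation,
                        p.center[0] + p.radii[0] + roi_dilation,
                        p.center[1] - p.radii[1] - roi_dilation,
                        p.center[1] + p.radii[1] + roi_dilation)
                       for p in patches]
        overexposed = []
        if rng.uniform() < 0.4:
            side = rng.choice([-1.0, 1.0])
            oe = FaceEllipse(e.cx + side * 0.45 * e.a, e.cy + 0.05 * e.b,
                             0.10 * e.a, 0.08 * e.b)
            oe_box = (oe.cx - oe.a, oe.cx + oe.a, oe.cy - oe.b, oe.cy + oe.b)
            if not any(_boxes_overlap(oe_box, pb, 2) for pb in patch_boxes):
                overexposed.append(oe)
        occl = []
        if rng.uniform() < 0.3:
            yj = rng.uniform(-0.05, 0.05) * e.b
            occl.append(OccludingBar(
                p0=(e.cx - e.a, e.cy - 0.75 * e.b + yj),
                p1=(e.cx + e.a, e.cy - 0.55 * e.b + yj),
                width=rng.uniform(4, 8)))
        beard = None
        if rng.uniform() < 0.3:
            beard = _ellipse_polygon(e.cx, e.cy + 0.70 * e.b,
                                     0.5 * e.a, 0.22 * e.b, n_vertices=12)
        spec = SceneSpec(
            seed=child_seed, face_ellipse=e,
            patches=tuple(patches), rect_patches=rects,
            illumination_direction_deg=float(rng.uniform(0, 360)),
            illumination_strength=illumination_strength,
            overexposed_regions=tuple(overexposed),
            beard_region=beard, occlusions=tuple(occl),
            noise_sigma=noise_sigma, roi_dilation=roi_dilation,
        )
        image, gt, session = generate_scene(spec)

        pid = f"P{i + 1:03d}"
        onset_year = int(rng.integers(1975, 2016))
        visit_year = onset_year + int(rng.integers(0, 21))
        record = PatientRecord(
            patient_id=pid,
            gender=str(rng.choice(["female", "male"])),
            familiarity=bool(rng.uniform() < 0.3),
            onset_date=datetime.date(onset_year, 1, 1),
            first_visit_date=datetime.date(visit_year, 1, 1),
            image_path=f"{pid}.png",
            onset_age=int(rng.integers(5, 51)),
            session=session,
        )
        patients.append(SyntheticPatient(record=record, image=image,
                                         ground_truth=gt, session=session,
                                         spec=spec))
        rows.append({
            "patient_id": pid, "gender": record.gender,
            "familiarity": str(record.familiarity).lower(),
            "onset_date": onset_year, "first_visit_date": visit_year,
            "image_path": f"{pid}.png", "onset_age": record.onset_age,
        })
        if out is not None:
            save_image(image, out / f"{pid}.png")
            save_mask(gt, out / f"{pid}_gt.png")
            save_session(session, out / f"{pid}.json")
    if out is not None:
        pd.DataFrame(rows).to_csv(out / "cohort.csv", index=False)
    return patients
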