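"""Population occurrence maps.

Each patient's detected patch mask, once registered onto the face template,
is a binary 610 x 407 matrix m_i.  Summing the m_i over the N patients of a
(possibly filtered) cohort gives the occurrence matrix M, whose entries
count how many patients show vitiligo at each template coordinate;
normalizing by N expresses it as a percentage map (100% where every patient
is affected).  Sub-populations are selected with metadata filters: gender,
familiarity, onset age, first-visit year, and the delay between onset and
first visit.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import matplotlib
import numpy as np
from PIL import Image, ImageDraw

from .face_geometry import FRAME_SHAPE, TemplateFace
from .image_io import PatientRecord

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class OccurrenceMap:
    """Percentage map over the template frame: each cell is
    100 * (number of patients with vitiligo there) / n_patients."""

    matrix: np.ndarray
    n_patients: int
    filter_description: str = "all patients"


def accumulate(masks: list[np.ndarray],
               filter_description: str = "all patients") -> OccurrenceMap:
    """Sum template-registered binary masks into a percentage map.

    Every input mask must already live on the template frame and be
    binary; each contributes at most 1 per cell, so cell values are exact
    multiples of 100/N.
    """
    if not masks:
        raise ValueError("at least one registered mask is required")
    total = np.zeros(FRAME_SHAPE, dtype=np.int64)
    for i, m in enumerate(masks):
        arr = np.asarray(m)
        if arr.shape != FRAME_SHAPE:
            raise ValueError(
                f"mask {i} has shape {arr.shape}, expected {FRAME_SHAPE}"
            )
        total += arr.astype(bool)
    n = len(masks)
    return OccurrenceMap(matrix=100.0 * total / n, n_patients=n,
                         filter_description=filter_description)


@dataclasses.dataclass
class CohortFilter:
    """Sub-population selection criteria; any criterion left None is
    inactive, and the empty filter selects every patient."""

    gender: str | None = None
    familiarity: bool | None = None
    onset_age_range: tuple[float, float] | None = None
    first_visit_year_range: tuple[int, int] | None = None
    delay_range: tuple[float, float] | None = None

    def describe(self) -> str:
        parts = []
        if self.gender is not None:
            parts.append(f"gender={self.gender}")
        if self.familiarity is not None:
            parts.append(f"familiarity={self.familiarity}")
        if self.onset_age_range is not None:
            parts.append(f"onset age in {list(self.onset_age_range)}")
        if self.first_visit_year_range is not None:
            parts.append(f"first visit in {list(self.first_visit_year_range)}")
        if self.delay_range is not None:
            parts.append(f"delay in {list(self.delay_range)} years")
        return ", ".join(parts) or "all patients"


def _in_range(value, rng) -> bool:
    return value is not None and rng[0] <= value <= rng[1]


def select_cohort(records: list[PatientRecord],
                  f: CohortFilter) -> list[PatientRecord]:
    """Return the records satisfying every active criterion.

    A criterion that references a field absent from *all* records (e.g. an
    onset-age range when no record carries an onset age) is skipped with a
    warning rather than silently emptying the selection.
    """
    selected = list(records)
    if f.gender is not None:
        selected = [r for r in selected if r.gender == f.gender]
    if f.familiarity is not None:
        if all(r.familiarity is None for r in records):
            log.warning("familiarity filter skipped: no record has the field")
        else:
            selected = [r for r in selected if r.familiarity == f.familiarity]
    if f.onset_age_range is not None:
        if all(r.onset_age is None for r in records):
            log.warning("onset-age filter skipped: no record has an onset age")
        else:
            selected = [r for r in selected
                        if _in_range(r.onset_age, f.onset_age_range)]
    if f.first_visit_year_range is not None:
        if all(r.first_visit_date is None for r in records):
            log.warning("first-visit filter skipped: no record has a visit date")
        else:
            selected = [
                r for r in selected
                if r.first_visit_date is not None
                and _in_range(r.first_visit_date.year, f.first_visit_year_range)
            ]
    if f.delay_range is not None:
        if all(r.delay_years is None for r in records):
            log.warning("delay filter skipped: no record has both dates")
        else:
            selected = [r for r in selected
                        if _in_range(r.delay_years, f.delay_range)]
    return selected


def render_map(m: OccurrenceMap, template: TemplateFace) -> np.ndarray:
    """Render the occurrence map over the face template.

    Cells with zero occurrence show the template raster; cells with any
    occurrence take their color from the jet colormap at occurrence/100,
    so distinct occurrence levels map to distinct colors.  A vertical
    colorbar strip with the patient count is appended on the right.

    Returns an (H, W + 40, 3) uint8 raster; rendering is deterministic.
    """
    if m.matrix.shape != template.image.shape:
        raise ValueError("occurrence map and template dimensions differ")
    h, w = m.matrix.shape
    cmap = matplotlib.colormaps["jet"]
    base = np.repeat(template.image[:, :, None], 3, axis=2)
    colored = cmap(m.matrix / 100.0)[..., :3]
    overlay = np.where((m.matrix > 0)[..., None], colored, base)
    # colorbar strip: 100% at the top, 0% at the bottom
    strip_w = 40
    levels = np.linspace(1.0, 0.0, h)
    strip = np.tile(cmap(levels)[:, None, :3], (1, strip_w, 1))
    out = np.concatenate([overlay, strip], axis=1)
    img = Image.fromarray((out * 255.0 + 0.5).astype(np.uint8))
    draw = ImageDraw.Draw(img)
    draw.text((w + 3, 2), f"n={m.n_patients}", fill=(0, 0, 0))
    return np.asarray(img)


def save_map(m: OccurrenceMap, path: str | Path) -> None:
    """Write the percentage matrix as CSV with a one-line header comment
    recording the patient count and filter."""
    header = f"occurrence %% over {m.n_patients} patients ({m.filter_description})"
    np.savetxt(path, m.matrix, fmt="%.6g", delimiter=",", header=header)


def load_map(path: str | Path, n_patients: int,
             filter_description: str = "all patients") -> OccurrenceMap:
    matrix = np.loadtxt(path, delimiter=",")
    return OccurrenceMap(matrix=matrix, n_patients=n_patients,
                         filter_description=filter_description)
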