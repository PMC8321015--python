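"""I/O: photographs, binary masks, annotation sessions and cohort metadata.

All images are ingested to the fixed working frame (610 rows x 407 cols)
with intensities on [0, 1], so downstream threshold arithmetic is
independent of camera resolution and bit depth.  Per-patient annotations
(ROIs, face ellipse, filter choice, global threshold) persist as JSON
session files; cohort metadata is a CSV with one row per patient.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize

from .face_geometry import FRAME_SHAPE, FaceEllipse
from .roi_detection import PolygonRoi

log = logging.getLogger(__name__)

#: Required metadata CSV columns.  ``onset_age`` (whole years) is optional.
METADATA_COLUMNS = ("patient_id", "gender", "familiarity",
                    "onset_date", "first_visit_date", "image_path")


# ---------------------------------------------------------------------------
# images and masks

def load_image(path: str | Path) -> np.ndarray:
    """Load a color photograph and rescale it to the working frame.

    The image is decoded, checked to be 3-channel RGB, mapped from its
    native bit depth to [0, 1] and bilinearly resampled to exactly
    610 x 407 (rows x cols), stretching if the aspect ratio differs.

    Returns
    -------
    (610, 407, 3) float array with intensities in [0, 1].
    """
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim == 2:
        raise ValueError(f"{path}: expected a 3-channel RGB image, got 1 channel")
    if arr.shape[2] != 3:
        raise ValueError(
            f"{path}: expected a 3-channel RGB image, got {arr.shape[2]} channels"
        )
    if arr.dtype == np.uint8:
        scale = 255.0
    elif arr.dtype == np.uint16:
        scale = 65535.0
    else:
        scale = float(np.iinfo(arr.dtype).max) if np.issubdtype(
            arr.dtype, np.integer) else 1.0
    img = arr.astype(float) / scale
    if img.shape[:2] != FRAME_SHAPE:
        img = resize(img, FRAME_SHAPE, order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(img, 0.0, 1.0)


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write an RGB [0, 1] float image as an 8-bit PNG/JPEG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255.0 + 0.5).astype(np.uint8)).save(path)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as a lossless 8-bit grayscale PNG, detected
    pixels at 255 and background at 0; round-trips bit-exactly."""
    m = np.asarray(mask)
    if m.dtype != bool and not np.isin(m, (0, 1)).all():
        raise ValueError("mask must be binary")
    Image.fromarray(np.where(m.astype(bool), 255, 0).astype(np.uint8)).save(
        path, format="PNG")


def load_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask PNG back to a boolean array (threshold at 128)."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr >= 128


# ---------------------------------------------------------------------------
# annotation sessions

@dataclasses.dataclass
class AnnotationSession:
    """Per-patient elaboration settings: the polygonal ROIs, the face
    ellipse, the filter choice and the global threshold."""

    rois: list[PolygonRoi]
    ellipse: FaceEllipse
    filter_id: int = 4
    global_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.filter_id not in (1, 2, 3, 4):
            raise ValueError(f"filter_id must be in 1..4, got {self.filter_id}")
        if not (0.0 <= self.global_threshold <= 1.0):
            raise ValueError(
                f"global_threshold must be in [0, 1], got {self.global_threshold}"
            )

    def to_dict(self) -> dict:
        return {
            "rois": [r.to_list() for r in self.rois],
            "ellipse": self.ellipse.to_dict(),
            "filter_id": self.filter_id,
            "global_threshold": self.global_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationSession":
        return cls(
            rois=[PolygonRoi.from_list(v) for v in d["rois"]],
            ellipse=FaceEllipse.from_dict(d["ellipse"]),
            filter_id=int(d["filter_id"]),
            global_threshold=float(d["global_threshold"]),
        )


def save_session(session: AnnotationSession, path: str | Path) -> None:
    Path(path).write_text(json.dumps(session.to_dict(), indent=1))


def load_session(path: str | Path) -> AnnotationSession:
    return AnnotationSession.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# cohort metadata

def _parse_date(value) -> datetime.date | None:
    """Parse an ISO-8601 date or a bare year; empty/NaN gives None.
    A bare year is anchored at January 1st."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in ("nan", "na", "unspecified"):
        return None
    if s.isdigit() and len(s) == 4:
        return datetime.date(int(s), 1, 1)
    return datetime.date.fromisoformat(s)


def _parse_gender(value) -> str:
    s = str(value).strip().lower() if value is not None else ""
    if s in ("f", "female"):
        return "female"
    if s in ("m", "male"):
        return "male"
    return "unspecified"


def _parse_bool(value) -> bool | None:
    s = str(value).strip().lower() if value is not None else ""
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n"):
        return False
    return None


@dataclasses.dataclass
class PatientRecord:
    """One cohort entry: identity, the metadata used by population filters,
    the photograph path and (if already annotated) the session."""

    patient_id: str
    gender: str = "unspecified"
    familiarity: bool | None = None
    onset_date: datetime.date | None = None
    first_visit_date: datetime.date | None = None
    image_path: str = ""
    onset_age: int | None = None
    session: AnnotationSession | None = None

    def __post_init__(self) -> None:
        if (self.onset_date is not None and self.first_visit_date is not None
                and self.onset_date > self.first_visit_date):
            raise ValueError(
                f"patient {self.patient_id}: onset date {self.onset_date} is "
                f"after first visit {self.first_visit_date}"
            )

    @property
    def delay_years(self) -> int | None:
        """Whole years between vitiligo onset and the first visit."""
        if self.onset_date is None or self.first_visit_date is None:
            return None
        d, o = self.first_visit_date, self.onset_date
        return d.year - o.year - (1 if (d.month, d.day) < (o.month, o.day) else 0)


def load_cohort(metadata_path: str | Path,
                sessions_dir: str | Path | None = None) -> list[PatientRecord]:
    """Load cohort metadata and attach per-patient sessions when present.

    One record per CSV row; a row whose ``<patient_id>.json`` session file
    does not exist in ``sessions_dir`` loads with ``session=None``.  Image
    files are not touched here (I/O is deferred to detection time).
    """
    df = pd.read_csv(metadata_path, dtype=str, keep_default_na=False)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{metadata_path}: missing required column(s): {', '.join(missing)}"
        )
    ids = df["patient_id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(
            f"{metadata_path}: duplicate patient_id(s): {', '.join(dupes)}"
        )
    sessions = Path(sessions_dir) if sessions_dir is not None else None
    records = []
    for _, row in df.iterrows():
        session = None
        if sessions is not None:
            spath = sessions / f"{row['patient_id']}.json"
            if spath.exists():
                session = load_session(spath)
        age = row.get("onset_age", "")
        records.append(PatientRecord(
            patient_id=row["patient_id"],
            gender=_parse_gender(row["gender"]),
            familiarity=_parse_bool(row["familiarity"]),
            onset_date=_parse_date(row["onset_date"]),
            first_visit_date=_parse_date(row["first_visit_date"]),
            image_path=row["image_path"],
            onset_age=int(age) if str(age).strip().isdigit() else None,
            session=session,
        ))
    return records
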