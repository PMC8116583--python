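"""Readers and writers for every on-disk artifact of the pipeline.

Coordinate convention (used everywhere in this package): image origin at the
top-left corner, ``x`` increasing rightward (columns), ``y`` increasing
downward (rows).  Contour points are ``(x, y)`` pairs in pixel units with
sub-pixel precision and are implicitly closed (last point connects back to the
first).  "Superior" on the retina corresponds to image-up (decreasing ``y``).

All writers are deterministic: JSON keys are emitted in a fixed order and
floats are formatted with ``repr`` round-trip precision, so re-running a
generation or analysis step with the same inputs produces byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

ANNOTATION_SCHEMA_VERSION = 1

EYES = ("right", "left", "unknown")


class ValidationError(ValueError):
    """An input file violates a documented invariant; names the field."""


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------


@dataclass
class Annotation:
    """Manual-style annotation of one fundus photograph.

    disc_contour / ppa_contour : (N, 2) float arrays of (x, y) pixel points,
        implicitly closed; the PPA contour may be empty (shape (0, 2)).
    fovea : (x, y) pixel point.
    vessel_mask : boolean raster with the image's (H, W) shape.
    eye : "right", "left" or "unknown".
    """

    disc_contour: np.ndarray
    ppa_contour: np.ndarray
    fovea: tuple[float, float]
    vessel_mask: np.ndarray
    eye: str = "unknown"

    def __post_init__(self) -> None:
        self.disc_contour = np.asarray(self.disc_contour, dtype=float)
        self.ppa_contour = np.asarray(self.ppa_contour, dtype=float).reshape(-1, 2)
        self.vessel_mask = np.asarray(self.vessel_mask, dtype=bool)

    def validate(self, image_shape: tuple[int, int] | None = None) -> None:
        from shapely.geometry import LinearRing  # local: keep import cost off the hot path

        if self.eye not in EYES:
            raise ValidationError(f"eye: unknown value {self.eye!r}")
        for name, contour in (("disc_contour", self.disc_contour),
                              ("ppa_contour", self.ppa_contour)):
            if contour.size == 0:
                if name == "disc_contour":
                    raise ValidationError("disc_contour: empty")
                continue
            pts = _deduplicate_closure(contour)
            if len(pts) < 8:
                raise ValidationError(f"{name}: fewer than 8 points")
            ring = LinearRing(pts)
            if not ring.is_valid or not ring.is_simple:
                raise ValidationError(f"{name}: self-intersecting contour")
        fx, fy = self.fovea
        shape = image_shape if image_shape is not None else self.vessel_mask.shape
        if not (0 <= fx < shape[1] and 0 <= fy < shape[0]):
            raise ValidationError("fovea: fovea out of bounds")
        if image_shape is not None and self.vessel_mask.shape != tuple(image_shape):
            raise ValidationError("vessel_mask: shape differs from image")

    def to_dict(self) -> dict:
        return {
            "schema_version": ANNOTATION_SCHEMA_VERSION,
            "eye": self.eye,
            "fovea": [float(self.fovea[0]), float(self.fovea[1])],
            "disc_contour": [[float(x), float(y)] for x, y in self.disc_contour],
            "ppa_contour": [[float(x), float(y)] for x, y in self.ppa_contour],
            "vessel_mask": _mask_to_rle(self.vessel_mask),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Annotation":
        version = d.get("schema_version")
        if version != ANNOTATION_SCHEMA_VERSION:
            raise ValidationError(f"schema_version: unsupported {version!r}")
        mask = _rle_to_mask(d["vessel_mask"])
        return cls(
            disc_contour=np.asarray(d["disc_contour"], dtype=float),
            ppa_contour=np.asarray(d["ppa_contour"], dtype=float).reshape(-1, 2),
            fovea=tuple(d["fovea"]),
            vessel_mask=mask,
            eye=d.get("eye", "unknown"),
        )


def _deduplicate_closure(contour: np.ndarray) -> np.ndarray:
    """Drop an explicit closing point (first == last) if present."""
    if len(contour) > 1 and np.allclose(contour[0], contour[-1]):
        return contour[:-1]
    return contour


def _mask_to_rle(mask: np.ndarray) -> dict:
    """Run-length encode a boolean raster (row-major) for compact JSON."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return {"shape": list(mask.shape), "runs": []}
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    starts = np.concatenate(([0], changes + 1))
    ends = np.concatenate((changes + 1, [flat.size]))
    runs = [[int(s), int(e - s)] for s, e, v in zip(starts, ends, flat[starts]) if v]
    return {"shape": [int(s) for s in mask.shape], "runs": runs}


def _rle_to_mask(d: dict) -> np.ndarray:
    shape = tuple(d["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in d["runs"]:
        flat[start:start + length] = True
    return flat.reshape(shape)


# ---------------------------------------------------------------------------
# Subject records
# ---------------------------------------------------------------------------


@dataclass
class SubjectRecord:
    """Clinical scalars for one subject (right eye).

    Units: age years; sbp/dbp/map/iop mm Hg; acd mm; sphere/cylinder/ser
    diopters; bcva logMAR; al mm; mcht/pcht/mret/prnflt micrometers.
    """

    id: str
    age: float
    sex: str  # "male" | "female"
    sbp: float = np.nan
    dbp: float = np.nan
    map: float = np.nan
    iop: float = np.nan
    acd: float = np.nan
    sphere: float = np.nan
    cylinder: float = np.nan
    ser: float = np.nan
    bcva: float = np.nan
    al: float = np.nan
    mcht: float = np.nan
    pcht: float = np.nan
    mret: float = np.nan
    prnflt: float = np.nan

    def validate(self) -> None:
        if np.isfinite(self.al) and self.al <= 0:
            raise ValidationError("al: must be positive")
        if np.isfinite(self.sbp) and np.isfinite(self.dbp) and np.isfinite(self.map):
            if abs(self.map - (self.sbp + 2.0 * self.dbp) / 3.0) > 1e-6:
                raise ValidationError("map: inconsistent with (sbp + 2*dbp)/3")
        if (np.isfinite(self.sphere) and np.isfinite(self.cylinder)
                and np.isfinite(self.ser)):
            if abs(self.ser - (self.sphere + self.cylinder / 2.0)) > 1e-6:
                raise ValidationError("ser: inconsistent with sphere + cylinder/2")


SUBJECT_COLUMNS = [f.name for f in dataclasses.fields(SubjectRecord)]


def subjects_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records],
                        columns=SUBJECT_COLUMNS)


def subjects_from_frame(df: pd.DataFrame) -> list[SubjectRecord]:
    return [SubjectRecord(**{k: row[k] for k in SUBJECT_COLUMNS})
            for _, row in df.iterrows()]


# ---------------------------------------------------------------------------
# Images and cases
# ---------------------------------------------------------------------------


def load_image(path: str | Path) -> np.ndarray:
    """Decode an image file to an 8-bit RGB array (H, W, 3)."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValidationError("image: 3-channel RGB input required")
    return np.ascontiguousarray(arr[:, :, :3], dtype=np.uint8)


def save_image(image: np.ndarray, path: str | Path) -> None:
    image = np.asarray(image)
    if image.dtype != np.uint8 or image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError("image: expected uint8 RGB (H, W, 3)")
    Image.fromarray(image, mode="RGB").save(path, format="PNG")


def load_case(image_path: str | Path, annotation_path: str | Path
              ) -> tuple[np.ndarray, Annotation]:
    """Load one photograph plus its annotation, validating all invariants."""
    image = load_image(image_path)
    with open(annotation_path) as fh:
        ann = Annotation.from_dict(json.load(fh))
    ann.validate(image.shape[:2])
    return image, ann


def save_annotation(annotation: Annotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(annotation.to_dict(), fh, separators=(",", ":"))


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Per-case feature matrix with units metadata for geometric columns.

    ``data`` holds one row per case (index = case id); target columns
    ``mChT``/``pChT`` (micrometers) are plain columns.  ``units`` maps column
    name -> unit string for every column carrying physical units.
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValidationError(f"columns: duplicate names {dupes}")

    def require_target(self, target: str) -> pd.Series:
        if target not in self.data.columns:
            raise ValidationError(f"{target}: target column missing")
        return self.data[target]


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    path = Path(path)
    table.data.to_csv(path, index=True, index_label="case_id",
                      float_format="%.17g")
    sidecar = path.with_suffix(path.suffix + ".units.json")
    with open(sidecar, "w") as fh:
        json.dump(table.units, fh, indent=0, sort_keys=True)


def read_feature_table(path: str | Path, require_targets: bool = False
                       ) -> FeatureTable:
    path = Path(path)
    df = pd.read_csv(path, index_col="case_id")
    sidecar = path.with_suffix(path.suffix + ".units.json")
    units: dict[str, str] = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            units = json.load(fh)
    table = FeatureTable(df, units)
    if require_targets:
        table.require_target("mChT")
        table.require_target("pChT")
    return table


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


def save_model(model, path: str | Path) -> None:
    """Serialize an IODModel to versioned JSON."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1, sort_keys=False)


def load_model(path: str | Path):
    from .iod_model import IODModel

    with open(path) as fh:
        return IODModel.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Checksums (dataset manifests)
# ---------------------------------------------------------------------------


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
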