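"""ROI construction and optic-disc geometry in millimeters.

Converts annotated pixel geometry (disc contour, PPA contour, fovea) into the
morphometric indices used clinically — ovality index, torsion angle, PPA
area/perimeter/width, disc–fovea distance — and builds the four
feature-extraction ROIs (disc D, inner ring I, inner temporal IT, outer
temporal OT) together with the ETDRS sector grids.

Magnification: fundus-camera pixels are converted to millimeters with the
axial-length-only form of Littmann's telecentric formula (Bennett's
adjustment), t = p * q with q = 0.01306 * (AL - 1.82).  ``q`` carries the
ocular contribution, the camera constant ``p`` the instrument contribution;
their product is the mm-per-pixel scale of a case.

Directions are defined from the disc-center -> fovea unit vector (temporal),
so every quadrant construction is agnostic to eye laterality: nasal is the
opposite direction and superior is the perpendicular on the image-up side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString, Polygon

from .case_io import Annotation

LITTMANN_COEFF = 0.01306
LITTMANN_OFFSET = 1.82  # mm

#: Camera constant chosen so a mean-axial-length eye (25.51 mm) maps to the
#: generator's nominal 0.0075 mm/px at full resolution.
DEFAULT_CAMERA_CONSTANT = 0.0075 / (LITTMANN_COEFF * (25.51 - LITTMANN_OFFSET))

#: Ovality above which the principal axes are numerically degenerate and the
#: torsion angle is reported as 0 by convention (near-circular disc).
CIRCULAR_OVALITY_LIMIT = 0.995


@dataclass(frozen=True)
class MagnificationModel:
    """Littmann/Bennett magnification correction for one eye."""

    camera_constant: float  # p, mm per pixel per unit q
    q: float                # ocular factor 0.01306*(AL - 1.82)
    scale: float            # mm per pixel for this case

    @property
    def mm_per_px(self) -> float:
        return self.scale


def littmann_scale(al: float, camera_constant: float = DEFAULT_CAMERA_CONSTANT
                   ) -> MagnificationModel:
    """Magnification model for an eye of axial length ``al`` (mm)."""
    if not (15.0 < al < 40.0):
        raise ValueError(f"axial length {al} mm outside supported range (15, 40)")
    if camera_constant <= 0:
        raise ValueError("camera_constant must be positive")
    q = LITTMANN_COEFF * (al - LITTMANN_OFFSET)
    return MagnificationModel(camera_constant=camera_constant, q=q,
                              scale=camera_constant * q)


# ---------------------------------------------------------------------------
# Polygon moments
# ---------------------------------------------------------------------------


def _polygon_moments(pts: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Area, centroid and central second-moment matrix of a closed polygon.

    Green's-theorem formulas; points are (x, y), implicitly closed.  The
    second-moment matrix is the covariance of the uniform measure over the
    polygon interior.
    """
    x, y = pts[:, 0], pts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:
        raise ValueError("degenerate contour: zero area")
    cx = ((x + x1) * cross).sum() / (6.0 * area)
    cy = ((y + y1) * cross).sum() / (6.0 * area)
    # raw second moments about the origin
    ixx = ((x * x + x * x1 + x1 * x1) * cross).sum() / (12.0 * area)
    iyy = ((y * y + y * y1 + y1 * y1) * cross).sum() / (12.0 * area)
    ixy = ((2 * x * y + x * y1 + x1 * y + 2 * x1 * y1) * cross).sum() / (24.0 * area)
    cov = np.array([[ixx - cx * cx, ixy - cx * cy],
                    [ixy - cx * cy, iyy - cy * cy]])
    return abs(area), np.array([cx, cy]), cov


def contour_centroid(contour: np.ndarray) -> np.ndarray:
    """Area centroid (x, y) of a closed contour polygon."""
    _, c, _ = _polygon_moments(np.asarray(contour, dtype=float))
    return c


# ---------------------------------------------------------------------------
# Disc geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiscGeometry:
    ld_mm: float                 # longest disc diameter
    sd_mm: float                 # shortest disc diameter
    ovality_index: float         # SD / LD in (0, 1]
    torsion_deg: float           # signed, (-90, 90]; superonasal positive
    center_px: tuple[float, float]
    long_axis: tuple[float, float]  # unit vector, oriented image-up


def _temporal_frame(center: np.ndarray, fovea: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(temporal, nasal, superior-reference) unit vectors in image coords."""
    t = np.asarray(fovea, dtype=float) - center
    norm = np.hypot(*t)
    if norm < 1e-9:
        raise ValueError("fovea coincides with disc center; temporal axis undefined")
    t = t / norm
    n = -t
    # perpendicular to the disc->fovea line, oriented toward image-up (-y)
    u = np.array([t[1], -t[0]])
    if u[1] > 0 or (u[1] == 0 and u[0] < 0):
        u = -u
    return t, n, u


def disc_shape_metrics(annotation: Annotation,
                       mag: MagnificationModel) -> DiscGeometry:
    """LD/SD, ovality index and torsion angle from the disc contour.

    The long/short diameters are the contour extents along the principal axes
    of the polygon's second moments.  Torsion is the signed angle between the
    long axis and the perpendicular to the disc-center->fovea line: positive
    when the superior end of the long axis leans toward the nasal side
    (superonasal torsion), negative toward the temporal side (inferotemporal).
    """
    contour = np.asarray(annotation.disc_contour, dtype=float)
    if len(contour) < 8:
        raise ValueError("degenerate disc contour: fewer than 8 points")
    _, center, cov = _polygon_moments(contour)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]
    minor = evecs[:, int(np.argmin(evals))]

    rel = contour - center
    proj_major = rel @ major
    proj_minor = rel @ minor
    ld_px = proj_major.max() - proj_major.min()
    sd_px = proj_minor.max() - proj_minor.min()
    if ld_px <= 0 or sd_px <= 0:
        raise ValueError("degenerate disc contour: zero extent")
    ovality = sd_px / ld_px

    _, n, u = _temporal_frame(center, np.asarray(annotation.fovea, dtype=float))
    v = major.copy()
    if (v @ u) < 0:
        v = -v
    if ovality >= CIRCULAR_OVALITY_LIMIT:
        torsion = 0.0
    else:
        torsion = math.degrees(math.atan2(v @ n, v @ u))
        if torsion <= -90.0:
            torsion += 180.0
        elif torsion > 90.0:
            torsion -= 180.0
    return DiscGeometry(
        ld_mm=ld_px * mag.scale,
        sd_mm=sd_px * mag.scale,
        ovality_index=float(ovality),
        torsion_deg=float(torsion),
        center_px=(float(center[0]), float(center[1])),
        long_axis=(float(v[0]), float(v[1])),
    )


# ---------------------------------------------------------------------------
# PPA geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PPAGeometry:
    area_mm2: float
    perimeter_mm: float
    width_mm: float
    disc_fovea_distance_mm: float


def ppa_metrics(annotation: Annotation, mag: MagnificationModel) -> PPAGeometry:
    """PPA area/perimeter/width plus disc-fovea distance, in mm units.

    Area is the polygon area of the PPA region minus any overlap with the
    disc; perimeter is the length of the annotated PPA contour; width is the
    chord of the PPA region along the disc-center->fovea ray.
    """
    disc_poly = Polygon(annotation.disc_contour)
    center = contour_centroid(annotation.disc_contour)
    fovea = np.asarray(annotation.fovea, dtype=float)
    dfd = float(np.hypot(*(fovea - center))) * mag.scale

    if annotation.ppa_contour.size == 0:
        return PPAGeometry(0.0, 0.0, 0.0, dfd)

    ppa_poly = Polygon(annotation.ppa_contour)
    if not ppa_poly.is_valid:
        ppa_poly = ppa_poly.buffer(0)
    region = ppa_poly.difference(disc_poly)
    if region.area <= 0:
        raise ValueError("PPA contour lies entirely inside the disc")
    area = region.area * mag.scale ** 2
    perimeter = ppa_poly.exterior.length * mag.scale

    t = fovea - center
    t = t / np.hypot(*t)
    far = center + t * 1e5
    ray = LineString([tuple(center), tuple(far)])
    width = ray.intersection(region).length * mag.scale
    return PPAGeometry(float(area), float(perimeter), float(width), dfd)


# ---------------------------------------------------------------------------
# ROI masks and sector grids
# ---------------------------------------------------------------------------

ETDRS_CENTRAL_RADIUS_MM = 0.5
ETDRS_INNER_RADIUS_MM = 1.5
ETDRS_OUTER_RADIUS_MM = 3.0

QUADRANTS = ("temporal", "superior", "nasal", "inferior")


@dataclass
class ROIMaskSet:
    """Binary rasters for the four extraction ROIs plus the ring partition.

    ``disc``, ``inner_ring``, ``inner_temporal``, ``outer_temporal`` are the
    extraction ROIs (vessel pixels removed when ``vessel_excluded``);
    ``ring_quadrants`` holds the full 2-ring x 4-quadrant peripapillary
    partition (8 pairwise-disjoint regions).  ``inner_temporal`` is the
    temporal quadrant of ``inner_ring`` and therefore a subset of it.
    """

    disc: np.ndarray
    inner_ring: np.ndarray
    inner_temporal: np.ndarray
    outer_temporal: np.ndarray
    ring_quadrants: dict[str, np.ndarray]
    vessel_excluded: bool

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"D": self.disc, "I": self.inner_ring,
                "IT": self.inner_temporal, "OT": self.outer_temporal}


def _polygon_mask(contour: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.draw import polygon2mask

    rc = np.column_stack([contour[:, 1], contour[:, 0]])  # (row, col)
    return polygon2mask(shape, rc)


def _quadrant_labels(shape: tuple[int, int], center: np.ndarray,
                     temporal: np.ndarray) -> np.ndarray:
    """Label each pixel center with its quadrant index (0=T, 1=S, 2=N, 3=I).

    Quadrant boundaries lie at +/-45 degrees around the four axis directions;
    boundary pixels go to the sector reached counter-clockwise (on screen)
    from the boundary, via half-open angular bins.
    """
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    dx = xx - center[0]
    dy = yy - center[1]
    # signed angle from the temporal axis, CCW-on-screen positive
    ang = np.degrees(np.arctan2(temporal[0] * dy - temporal[1] * dx,
                                temporal[0] * dx + temporal[1] * dy))
    labels = np.full(shape, 2, dtype=np.int8)  # nasal by default (|ang| >= 135)
    labels[(ang >= -45.0) & (ang < 45.0)] = 0          # temporal
    sup_side = dy < 0                                   # image-up
    perp = (ang >= 45.0) & (ang < 135.0)
    perp |= (ang >= -135.0) & (ang < -45.0)
    labels[perp & sup_side] = 1
    labels[perp & ~sup_side] = 3
    return labels


def build_roi_masks(annotation: Annotation, mag: MagnificationModel,
                    image_shape: tuple[int, int],
                    exclude_vessels: bool = True) -> ROIMaskSet:
    """Build the D / I / IT / OT extraction masks and the 8-region partition.

    Circles of radius 1.5 and 3.0 mm (ETDRS 3/6-mm diameters) are centered on
    the disc centroid; the inner ring is the inner circle minus the disc
    (PPA pixels are retained), the outer ring the 1.5-3.0 mm annulus.
    Membership is by pixel-center test.
    """
    shape = tuple(image_shape[:2])
    center = contour_centroid(annotation.disc_contour)
    r_inner = ETDRS_INNER_RADIUS_MM / mag.scale
    r_outer = ETDRS_OUTER_RADIUS_MM / mag.scale
    if (center[0] - r_outer < -0.5 or center[1] - r_outer < -0.5
            or center[0] + r_outer > shape[1] - 0.5
            or center[1] + r_outer > shape[0] - 0.5):
        raise ValueError("6-mm ETDRS circle does not fit inside the image")

    t, _, _ = _temporal_frame(center, np.asarray(annotation.fovea, dtype=float))

    disc = _polygon_mask(annotation.disc_contour, shape)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    r = np.hypot(xx - center[0], yy - center[1])
    inner_circle = r <= r_inner
    outer_annulus = (r > r_inner) & (r <= r_outer)
    inner_ring = inner_circle & ~disc
    labels = _quadrant_labels(shape, center, t)

    vessels = annotation.vessel_mask if exclude_vessels else np.zeros(shape, bool)

    def _clean(m: np.ndarray) -> np.ndarray:
        return m & ~vessels

    ring_quadrants = {}
    for qi, qname in enumerate(QUADRANTS):
        ring_quadrants[f"inner_{qname}"] = _clean(inner_ring & (labels == qi))
        ring_quadrants[f"outer_{qname}"] = _clean(outer_annulus & (labels == qi))

    return ROIMaskSet(
        disc=_clean(disc),
        inner_ring=_clean(inner_ring),
        inner_temporal=ring_quadrants["inner_temporal"],
        outer_temporal=ring_quadrants["outer_temporal"],
        ring_quadrants=ring_quadrants,
        vessel_excluded=exclude_vessels,
    )


def etdrs_sector_means(value_map: np.ndarray, center: tuple[float, float],
                       mag: MagnificationModel, mode: str,
                       temporal_axis: tuple[float, float] = (1.0, 0.0)
                       ) -> dict[str, float]:
    """Mean of ``value_map`` over each ETDRS sector.

    macula mode: 9 sectors (1-mm central circle + 4 inner-ring + 4 outer-ring
    quadrants); peripapillary mode: only the 4 outer-ring quadrants.
    """
    if mode not in ("macula", "peripapillary"):
        raise ValueError(f"unknown mode {mode!r}")
    value_map = np.asarray(value_map, dtype=float)
    shape = value_map.shape
    center = np.asarray(center, dtype=float)
    t = np.asarray(temporal_axis, dtype=float)
    t = t / np.hypot(*t)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    r = np.hypot(xx - center[0], yy - center[1])
    labels = _quadrant_labels(shape, center, t)

    r_c = ETDRS_CENTRAL_RADIUS_MM / mag.scale
    r_i = ETDRS_INNER_RADIUS_MM / mag.scale
    r_o = ETDRS_OUTER_RADIUS_MM / mag.scale
    if center[0] - r_o < -0.5 or center[1] - r_o < -0.5 \
            or center[0] + r_o > shape[1] - 0.5 or center[1] + r_o > shape[0] - 0.5:
        raise ValueError("ETDRS grid does not fit inside the raster")

    sectors: dict[str, np.ndarray] = {}
    if mode == "macula":
        sectors["central"] = r <= r_c
        inner = (r > r_c) & (r <= r_i)
        for qi, qname in enumerate(QUADRANTS):
            sectors[f"inner_{qname}"] = inner & (labels == qi)
    outer = (r > r_i) & (r <= r_o)
    for qi, qname in enumerate(QUADRANTS):
        sectors[f"outer_{qname}"] = outer & (labels == qi)

    means: dict[str, float] = {}
    for name, m in sectors.items():
        if not m.any():
            raise ValueError(f"sector {name}: no pixels")
        means[name] = float(value_map[m].mean())
    return means
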