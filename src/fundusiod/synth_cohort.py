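"""Synthetic cohorts of young myopic eyes with rendered fundus photographs.

Generates subjects whose marginals match the study cohort (axial length
25.51 +/- 1.34 mm, ovality index 0.79 +/- 0.10, torsion 4.98 +/- 19.78 deg,
PPA area 0.68 +/- 0.63 mm^2, mChT 211 +/- 62 um, pChT 143 +/- 46 um), plus a
per-case latent "atrophy severity" that couples choroidal thinning to the
appearance of the temporal peripapillary region (brighter, desaturated,
higher-variance pixels), mirroring the clinical reading that a thin choroid
goes with a larger intensity range and a larger proportion of bright area.

Choroidal thickness decomposes as

    ChT = mean - slope * (AL - AL_mean) + sqrt(f) * sd * Z + e,

where Z is the (negated) severity, f = ``signal_fraction`` is the fraction of
ChT variance carried by the image-intensity signal, and e is independent
noise sized so the total variance matches the cohort target.  PPA area is
lognormal (positivity) with its log-scale driver correlated with both AL and
severity; ovality is anti-correlated with both (longer, more atrophic eyes
are more tilted).

Rendering is schematic, not photorealistic: a flat fundus-colored background,
an elliptical disc with the planted semi-axes and torsion, a temporal PPA
crescent solved to the planted area, 4-8 dark vessel arcs with an exact
vessel mask, and a temporal texture field whose per-channel amplitude (range)
and shape (skewness of u**gamma, u ~ U(0,1)) are the planted intensity
parameters.  Annotations returned are the exact contours used for rendering.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm
from shapely.geometry import Polygon
from skimage import color
from skimage.draw import disk, polygon2mask

from . import case_io
from .case_io import Annotation, FeatureTable, SubjectRecord
from .roi_geometry import DEFAULT_CAMERA_CONSTANT, littmann_scale

DEFAULT_IMAGE_SIZE = 1024
#: nominal mm/px at the default image size for a mean-axial-length eye
DEFAULT_NOMINAL_SCALE = 0.0075


@dataclass
class CohortParams:
    """Sampling targets for one synthetic cohort (defaults = study cohort)."""

    n_subjects: int = 300
    seed: int = 0
    al_mean_mm: float = 25.51
    al_sd_mm: float = 1.34
    ovality_mean: float = 0.79
    ovality_sd: float = 0.10
    torsion_mean_deg: float = 4.98
    torsion_sd_deg: float = 19.78
    ppa_area_mean_mm2: float = 0.68
    ppa_area_sd_mm2: float = 0.63
    mcht_mean_um: float = 211.00
    mcht_sd_um: float = 62.03
    pcht_mean_um: float = 143.33
    pcht_sd_um: float = 45.58
    signal_fraction: float = 0.5
    al_cht_slope_um_per_mm: float = 23.0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for f in dataclasses.fields(self):
            if f.name.endswith(("_sd_mm", "_sd", "_sd_deg", "_sd_mm2", "_sd_um")):
                if getattr(self, f.name) < 0:
                    raise ValueError(f"{f.name} must be non-negative")
        if not (0.0 <= self.signal_fraction <= 1.0):
            raise ValueError("signal_fraction must lie in [0, 1]")
        for sd, slope_sd in ((self.mcht_sd_um, self.al_cht_slope_um_per_mm),):
            if sd > 0:
                frac_al = (slope_sd * self.al_sd_mm / sd) ** 2
                if frac_al + self.signal_fraction > 1.0 + 1e-9:
                    raise ValueError(
                        "AL slope and signal_fraction together exceed the "
                        "total ChT variance budget")


@dataclass
class GroundTruth:
    """Planted per-case parameters, stored losslessly beside each case."""

    case_id: str
    mcht_um: float
    pcht_um: float
    severity: float           # latent atrophy severity, ~N(0,1)
    disc_a_mm: float          # semi-major axis
    disc_b_mm: float          # semi-minor axis
    ovality: float
    torsion_deg: float
    ppa_area_mm2: float
    amp_l: float              # planted L-channel range (native Lab units)
    amp_a: float
    amp_b: float
    skew_l: float             # planted skewness of the temporal texture
    skew_a: float
    skew_b: float
    gamma: float              # texture shape parameter


def _pattern_skewness(gamma: float) -> float:
    """Closed-form skewness of u**gamma for u ~ U(0, 1)."""
    e1 = 1.0 / (gamma + 1.0)
    e2 = 1.0 / (2.0 * gamma + 1.0)
    e3 = 1.0 / (3.0 * gamma + 1.0)
    m2 = e2 - e1 ** 2
    m3 = e3 - 3.0 * e1 * e2 + 2.0 * e1 ** 3
    return float(m3 / m2 ** 1.5) if m2 > 0 else 0.0


def _intensity_params(severity: float) -> dict[str, float]:
    """Planted temporal-texture parameters as a function of severity."""
    phi = float(norm.cdf(severity))
    gamma = float(np.clip(np.exp(0.8 * severity), 0.2, 5.0))
    sk = _pattern_skewness(gamma)
    return {
        "amp_l": 7.0 + 9.0 * phi,
        "amp_a": 2.5 + 4.0 * phi,
        "amp_b": 3.0 + 5.0 * phi,
        "skew_l": sk,
        "skew_a": -sk,   # A/B channels subtract the pattern (desaturation)
        "skew_b": -sk,
        "gamma": gamma,
    }


def sample_subjects(params: CohortParams
                    ) -> tuple[list[SubjectRecord], list[GroundTruth]]:
    """Draw a cohort of subjects plus the planted ground truth per case."""
    params.validate()
    rng = np.random.default_rng([params.seed, 2081])
    n = params.n_subjects

    z_al = np.clip(rng.standard_normal(n), -3.2, 3.2)
    al = params.al_mean_mm + params.al_sd_mm * z_al
    severity = rng.standard_normal(n)
    z_signal = -severity

    # ovality: anti-correlated with axial length and severity
    w_ov = (-0.45 * z_al - 0.35 * severity
            + np.sqrt(1.0 - 0.45 ** 2 - 0.35 ** 2) * rng.standard_normal(n))
    ovality = np.clip(params.ovality_mean + params.ovality_sd * w_ov,
                      0.402, 1.0)

    torsion = np.clip(params.torsion_mean_deg
                      + params.torsion_sd_deg * rng.standard_normal(n),
                      -89.0, 90.0)

    # PPA area: lognormal matched to the target mean/sd (positivity), with a
    # log-scale driver correlated with AL and severity
    if params.ppa_area_mean_mm2 > 0:
        cv2 = (params.ppa_area_sd_mm2 / params.ppa_area_mean_mm2) ** 2
        s_log = np.sqrt(np.log1p(cv2))
        m_log = np.log(params.ppa_area_mean_mm2) - s_log ** 2 / 2.0
        w_ppa = (0.45 * z_al + 0.40 * severity
                 + np.sqrt(1.0 - 0.45 ** 2 - 0.40 ** 2) * rng.standard_normal(n))
        ppa_area = np.exp(m_log + s_log * w_ppa)
        ppa_area[ppa_area < 0.05] = 0.0
    else:
        ppa_area = np.zeros(n)

    def _cht(mean, sd):
        slope = params.al_cht_slope_um_per_mm * sd / params.mcht_sd_um \
            if params.mcht_sd_um > 0 else 0.0
        var_al = (slope * params.al_sd_mm) ** 2
        var_sig = params.signal_fraction * sd ** 2
        var_e = max(sd ** 2 - var_al - var_sig, 0.0)
        return np.clip(mean - slope * (al - params.al_mean_mm)
                       + np.sqrt(var_sig) * z_signal
                       + np.sqrt(var_e) * rng.standard_normal(n), 20.0, None)

    mcht = _cht(params.mcht_mean_um, params.mcht_sd_um)
    pcht = _cht(params.pcht_mean_um, params.pcht_sd_um)

    age = rng.uniform(16.0, 40.0, n)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    sbp = np.clip(rng.normal(115.0, 10.0, n), 90.0, 150.0)
    dbp = np.clip(rng.normal(72.0, 8.0, n), 50.0, 95.0)
    iop = np.clip(rng.normal(14.0, 2.8, n), 8.0, 21.0)
    acd = np.clip(rng.normal(3.60, 0.34, n), 2.5, 4.6)
    ser = -4.91 - 2.2 * (al - params.al_mean_mm) + rng.normal(0.0, 1.0, n)
    cylinder = -np.abs(rng.normal(0.0, 0.5, n))
    sphere = ser - cylinder / 2.0
    bcva = np.clip(rng.normal(0.02, 0.06, n), -0.08, 0.5)
    mret = rng.normal(276.01, 12.72, n)
    prnflt = rng.normal(91.93, 10.04, n)
    disc_a = np.clip(rng.normal(0.95, 0.06, n), 0.80, 1.10)

    subjects, truths = [], []
    for i in range(n):
        cid = f"case_{i:04d}"
        subjects.append(SubjectRecord(
            id=cid, age=float(age[i]), sex=str(sex[i]),
            sbp=float(sbp[i]), dbp=float(dbp[i]),
            map=float((sbp[i] + 2.0 * dbp[i]) / 3.0),
            iop=float(iop[i]), acd=float(acd[i]),
            sphere=float(sphere[i]), cylinder=float(cylinder[i]),
            ser=float(ser[i]), bcva=float(bcva[i]), al=float(al[i]),
            mcht=float(mcht[i]), pcht=float(pcht[i]),
            mret=float(mret[i]), prnflt=float(prnflt[i]),
        ))
        ip = _intensity_params(float(severity[i]))
        truths.append(GroundTruth(
            case_id=cid, mcht_um=float(mcht[i]), pcht_um=float(pcht[i]),
            severity=float(severity[i]),
            disc_a_mm=float(disc_a[i]),
            disc_b_mm=float(disc_a[i] * ovality[i]),
            ovality=float(ovality[i]), torsion_deg=float(torsion[i]),
            ppa_area_mm2=float(ppa_area[i]), **ip,
        ))
    return subjects, truths


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


#: widens the nominal field so the 6-mm circle plus the fovea fit at every
#: axial length in the sampled range (short eyes image at a smaller mm/px)
FIELD_MARGIN = 1.15


def camera_constant_for(image_size_px: int) -> float:
    """Camera constant giving the nominal field of view at a given resolution."""
    return DEFAULT_CAMERA_CONSTANT * FIELD_MARGIN \
        * (DEFAULT_IMAGE_SIZE / image_size_px)


def _ellipse_contour(center: np.ndarray, a_px: float, b_px: float,
                     torsion_deg: float, n_pts: int = 180) -> np.ndarray:
    """Contour of a disc ellipse whose long axis is the perpendicular to the
    (+x) temporal axis rotated by the planted torsion (superonasal positive)."""
    tau = np.radians(torsion_deg)
    v = np.array([-np.sin(tau), -np.cos(tau)])        # long axis, image-up
    w = np.array([-v[1], v[0]])                       # short axis
    th = np.linspace(0.0, 2.0 * np.pi, n_pts, endpoint=False)
    pts = (center[None, :] + np.outer(a_px * np.cos(th), v)
           + np.outer(b_px * np.sin(th), w))
    return pts


def _solve_ppa_contour(disc_pts: np.ndarray, center: np.ndarray,
                       a_px: float, b_px: float, torsion_deg: float,
                       target_area_mm2: float, scale: float) -> np.ndarray:
    """Temporal crescent whose area (outside the disc) hits the target."""
    disc_poly = Polygon(disc_pts)

    def crescent(m_mm: float):
        m_px = m_mm / scale
        outer = _ellipse_contour(center + np.array([0.45 * m_px, 0.0]),
                                 a_px + m_px, b_px + 0.55 * m_px, torsion_deg)
        region = Polygon(outer).difference(disc_poly)
        return outer, region.area * scale ** 2

    lo, hi = 1e-4, 2.5
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        _, area = crescent(mid)
        if area < target_area_mm2:
            lo = mid
        else:
            hi = mid
    outer, _ = crescent(0.5 * (lo + hi))
    region = Polygon(outer).difference(disc_poly)
    if region.geom_type == "MultiPolygon":
        region = max(region.geoms, key=lambda g: g.area)
    return np.asarray(region.exterior.coords)[:-1]


def render_fundus_case(subject: SubjectRecord, truth: GroundTruth,
                       image_size_px: int = DEFAULT_IMAGE_SIZE,
                       scale_mm_per_px: float | None = None,
                       seed: int = 0,
                       disc_fovea_distance_mm: float | None = None
                       ) -> tuple[np.ndarray, Annotation]:
    """Render one schematic fundus photograph plus its exact annotation."""
    if scale_mm_per_px is None:
        scale_mm_per_px = littmann_scale(subject.al).scale
    scale = float(scale_mm_per_px)
    if scale <= 0:
        raise ValueError("scale must be positive")
    h = w = int(image_size_px)
    rng = np.random.default_rng([seed, 977])

    if disc_fovea_distance_mm is None:
        disc_fovea_distance_mm = float(rng.uniform(4.40, 4.70))
    r_out = 3.0 / scale
    cx = r_out + 4.0
    cy = h / 2.0
    max_dfd = (w - 2.0 - cx) * scale
    if cy - r_out < 1.0 or cy + r_out > h - 2.0 or max_dfd < 3.3:
        raise ValueError("6-mm outer circle / fovea do not fit in the image")
    disc_fovea_distance_mm = min(disc_fovea_distance_mm, max_dfd)
    fx = cx + disc_fovea_distance_mm / scale
    fy = cy
    center = np.array([cx, cy])

    # fundus-colored background with mottled texture (choroidal pattern)
    L = np.full((h, w), 54.0) + rng.normal(0.0, 1.4, (h, w))
    A = np.full((h, w), 26.0) + rng.normal(0.0, 0.9, (h, w))
    B = np.full((h, w), 34.0) + rng.normal(0.0, 0.9, (h, w))

    # temporal texture field carrying the planted intensity parameters
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    r = np.hypot(dx, dy)
    ang = np.degrees(np.arctan2(dy, dx))
    temporal = (np.abs(ang) <= 45.5) & (r <= 3.05 / scale)
    u = rng.random(int(temporal.sum()))
    pat = u ** truth.gamma
    L[temporal] += truth.amp_l * pat
    A[temporal] -= truth.amp_a * pat
    B[temporal] -= truth.amp_b * pat

    a_px = truth.disc_a_mm / scale
    b_px = truth.disc_b_mm / scale
    disc_pts = _ellipse_contour(center, a_px, b_px, truth.torsion_deg)
    disc_mask = polygon2mask((h, w), np.column_stack([disc_pts[:, 1],
                                                      disc_pts[:, 0]]))

    ppa_pts = np.zeros((0, 2))
    if truth.ppa_area_mm2 > 0:
        ppa_pts = _solve_ppa_contour(disc_pts, center, a_px, b_px,
                                     truth.torsion_deg, truth.ppa_area_mm2,
                                     scale)
        ppa_mask = polygon2mask((h, w), np.column_stack([ppa_pts[:, 1],
                                                         ppa_pts[:, 0]]))
        ppa_mask &= ~disc_mask
        n_ppa = int(ppa_mask.sum())
        pat_ppa = rng.random(n_ppa) ** truth.gamma
        L[ppa_mask] = 58.0 + truth.amp_l * (0.4 + 0.6 * pat_ppa)
        A[ppa_mask] = 18.0 - truth.amp_a * pat_ppa
        B[ppa_mask] = 32.0 - truth.amp_b * pat_ppa

    L[disc_mask] = 76.0 + rng.normal(0.0, 1.8, int(disc_mask.sum()))
    A[disc_mask] = 14.0 + rng.normal(0.0, 1.0, int(disc_mask.sum()))
    B[disc_mask] = 42.0 + rng.normal(0.0, 1.0, int(disc_mask.sum()))

    vessel_mask = np.zeros((h, w), dtype=bool)
    n_vessels = int(rng.integers(4, 9))
    for k in range(n_vessels):
        base = rng.uniform(-np.pi, np.pi)
        curv = rng.uniform(-0.9, 0.9)
        width = rng.uniform(1.0, 2.5)
        r_max = rng.uniform(2.6, 3.4) / scale
        for s in np.linspace(0.02, 1.0, 160):
            angle = base + curv * s
            px = cx + s * r_max * np.cos(angle)
            py = cy + s * r_max * np.sin(angle)
            if 0 <= px < w and 0 <= py < h:
                rr, cc = disk((py, px), max(width * (1.0 - 0.4 * s), 0.6),
                              shape=(h, w))
                vessel_mask[rr, cc] = True
    L[vessel_mask] = 30.0
    A[vessel_mask] = 32.0
    B[vessel_mask] = 22.0

    lab = np.dstack([L, A, B])
    rgb = color.lab2rgb(lab)
    image = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)

    annotation = Annotation(
        disc_contour=disc_pts, ppa_contour=ppa_pts, fovea=(float(fx), float(fy)),
        vessel_mask=vessel_mask, eye="right",
    )
    return image, annotation


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def truths_to_frame(truths: list[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(t) for t in truths])


def generate_dataset(params: CohortParams, out_dir: str | Path,
                     image_size_px: int = DEFAULT_IMAGE_SIZE,
                     camera_constant: float | None = None) -> dict:
    """Write a full synthetic dataset (images, annotations, tables, manifest).

    Per-case pixel scale follows Littmann's correction for the subject's
    axial length at the given camera constant (defaulting to the nominal one
    for the requested resolution).  Deterministic: re-running with the same
    params yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if camera_constant is None:
        camera_constant = camera_constant_for(image_size_px)
    subjects, truths = sample_subjects(params)

    files: dict[str, str] = {}
    for i, (sub, tru) in enumerate(zip(subjects, truths)):
        scale = littmann_scale(sub.al, camera_constant).scale
        image, ann = render_fundus_case(
            sub, tru, image_size_px=image_size_px, scale_mm_per_px=scale,
            seed=params.seed * 100003 + i)
        img_path = out / f"{sub.id}.png"
        ann_path = out / f"{sub.id}.json"
        case_io.save_image(image, img_path)
        case_io.save_annotation(ann, ann_path)
        files[img_path.name] = case_io.sha256_of(img_path)
        files[ann_path.name] = case_io.sha256_of(ann_path)

    subj_path = out / "subjects.csv"
    case_io.subjects_to_frame(subjects).to_csv(subj_path, index=False,
                                               float_format="%.17g")
    files[subj_path.name] = case_io.sha256_of(subj_path)
    truth_path = out / "ground_truth.csv"
    truths_to_frame(truths).to_csv(truth_path, index=False,
                                   float_format="%.17g")
    files[truth_path.name] = case_io.sha256_of(truth_path)

    manifest = {
        "params": dataclasses.asdict(params),
        "image_size_px": image_size_px,
        "camera_constant": camera_constant,
        "n_cases": len(subjects),
        "files": dict(sorted(files.items())),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Tabular mode (fast large-n experiments without rendering)
# ---------------------------------------------------------------------------


def synthetic_feature_table(params: CohortParams, n_noise_features: int = 40
                            ) -> tuple[FeatureTable, pd.DataFrame]:
    """Feature table as the extraction stage would produce it, built directly
    from the planted ground truth plus small measurement noise and nuisance
    columns.

    Used for large-n / many-seed experiments on the selection and modeling
    stages where rendering every photograph would dominate the runtime.
    Returns (table, ground-truth frame).
    """
    subjects, truths = sample_subjects(params)
    rng = np.random.default_rng([params.seed, 555001])
    n = len(subjects)
    tf = truths_to_frame(truths)

    area = tf["ppa_area_mm2"].to_numpy()
    has_ppa = area > 0
    width = np.where(has_ppa,
                     0.45 * np.sqrt(np.maximum(area, 0.0))
                     * (1.0 + rng.normal(0.0, 0.08, n)), 0.0)
    perim = np.where(has_ppa,
                     (2.2 + 2.8 * np.sqrt(np.maximum(area, 0.0)))
                     * (1.0 + rng.normal(0.0, 0.05, n)), 0.0)

    amp_l = tf["amp_l"].to_numpy()
    amp_a = tf["amp_a"].to_numpy()
    amp_b = tf["amp_b"].to_numpy()
    data = {
        "ovality_index": tf["ovality"].to_numpy() + rng.normal(0.0, 0.01, n),
        "torsion_angle": tf["torsion_deg"].to_numpy() + rng.normal(0.0, 1.0, n),
        "ppa_area": np.maximum(area + rng.normal(0.0, 0.02, n) * has_ppa, 0.0),
        "ppa_perimeter": perim,
        "ppa_width": width,
        "disc_fovea_distance": rng.normal(4.55, 0.15, n),
        "IT_L_range": 2.55 * amp_l * (1.0 + rng.normal(0.0, 0.06, n)),
        "OT_L_range": 2.55 * amp_l * (1.0 + rng.normal(0.0, 0.06, n)),
        "OT_A_range": amp_a * (1.0 + rng.normal(0.0, 0.06, n)),
        "OT_B_range": amp_b * (1.0 + rng.normal(0.0, 0.06, n)),
        "OT_A_skewness": tf["skew_a"].to_numpy() + rng.normal(0.0, 0.08, n),
        "I_B_skewness": tf["skew_b"].to_numpy() + rng.normal(0.0, 0.08, n),
    }
    for k in range(n_noise_features):
        data[f"nuisance_{k:02d}"] = rng.standard_normal(n)
    data["mChT"] = tf["mcht_um"].to_numpy()
    data["pChT"] = tf["pcht_um"].to_numpy()

    df = pd.DataFrame(data, index=pd.Index([s.id for s in subjects],
                                           name="case_id"))
    units = {"ppa_area": "mm^2", "ppa_perimeter": "mm", "ppa_width": "mm",
             "disc_fovea_distance": "mm", "mChT": "um", "pChT": "um"}
    return FeatureTable(df, units), tf
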