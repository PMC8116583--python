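"""Radiomic feature pool over LAB channels of fundus photograph ROIs.

Implements the operator families used to build the feature pool: 19
first-order statistics, 24 GLCM, 16 GLRLM, 16 GLSZM, 5 NGTDM and 14 GLDM
texture features, plus 10 2D shape features per ROI.  Definitions follow the
public standard radiomics formulations (population moments; symmetric
distance-1 co-occurrence averaged over the four 2D directions; zones by
8-connectivity; Chebyshev-1 neighborhoods for NGTDM/GLDM).

Photographs are converted from sRGB to CIELAB (D65) and each channel is
affinely mapped to a nominal [0, 255] range (L * 2.55; A + 128; B + 128)
before statistics and fixed-bin-width discretization, so one bin width (25 by
default) is meaningful across channels.

Degenerate-region conventions (the flat-patch limit): skewness 0, kurtosis 0,
GLCM correlation 1, MCC 1, IMC1 0.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
from skimage import color, measure

from .case_io import Annotation, ValidationError
from .roi_geometry import (MagnificationModel, ROIMaskSet, disc_shape_metrics,
                           ppa_metrics)

DEFAULT_BIN_WIDTH = 25.0

_EPS = np.spacing(1.0)

CHANNELS = ("L", "A", "B")
ROIS = ("D", "I", "IT", "OT")

TEXTURE_FAMILIES = ("GLCM", "GLRLM", "GLSZM", "NGTDM", "GLDM")

#: operator-family cardinalities
N_FIRST_ORDER = 19
N_GLCM = 24
N_GLRLM = 16
N_GLSZM = 16
N_NGTDM = 5
N_GLDM = 14
N_SHAPE2D = 10

_OFFSETS_4DIR = ((0, 1), (1, 0), (1, 1), (1, -1))
_OFFSETS_8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1))


@dataclass
class ChannelImage:
    """One LAB channel as a scalar raster (after the fixed affine rescale)."""

    values: np.ndarray
    channel: str


# ---------------------------------------------------------------------------
# Color conversion
# ---------------------------------------------------------------------------


def rgb_to_lab(image: np.ndarray) -> dict[str, ChannelImage]:
    """sRGB (8-bit) -> CIELAB channels in native units (L 0-100, A/B signed)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError("image: 3-channel RGB input required")
    lab = color.rgb2lab(image)
    return {c: ChannelImage(lab[:, :, i].astype(float), c)
            for i, c in enumerate(CHANNELS)}


def lab_channels_rescaled(image: np.ndarray) -> dict[str, ChannelImage]:
    """LAB channels affinely mapped to a nominal [0, 255] scale.

    L: x * 2.55 (0-100 -> 0-255); A, B: x + 128.  A fixed affine (never a
    per-image min-max), so ranges and higher moments remain comparable across
    cases.
    """
    native = rgb_to_lab(image)
    out = {}
    for c, ch in native.items():
        vals = ch.values * 2.55 if c == "L" else ch.values + 128.0
        out[c] = ChannelImage(vals, c)
    return out


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


def discretize_channel(values: np.ndarray, mask: np.ndarray,
                       bin_width: float = DEFAULT_BIN_WIDTH
                       ) -> tuple[np.ndarray, int]:
    """Fixed-bin-width quantization of masked values, anchored at the minimum.

    Level ``i`` covers ``[min + (i-1)*w, min + i*w)``; returns an int raster
    (0 outside the mask) and the number of levels.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    values = np.asarray(values, dtype=float)
    lo = values[mask].min()
    levels = np.zeros(mask.shape, dtype=np.int32)
    levels[mask] = np.floor((values[mask] - lo) / bin_width).astype(np.int32) + 1
    return levels, int(levels.max())


# ---------------------------------------------------------------------------
# First-order statistics
# ---------------------------------------------------------------------------

FIRST_ORDER_NAMES = (
    "energy", "total_energy", "entropy", "minimum", "p10", "p90", "maximum",
    "mean", "median", "iqr", "range", "mad", "rmad", "rms", "std",
    "skewness", "kurtosis", "variance", "uniformity",
)


def first_order_features(values: np.ndarray, mask: np.ndarray,
                         bin_width: float = DEFAULT_BIN_WIDTH,
                         pixel_area_mm2: float = 1.0) -> OrderedDict:
    """The 19 first-order statistics of the masked intensities.

    Population (biased) moments; entropy and uniformity are computed on the
    fixed-bin-width histogram.  ``total_energy`` scales energy by the pixel
    area so it carries physical units.
    """
    mask = np.asarray(mask, dtype=bool)
    x = np.asarray(values, dtype=float)[mask]
    if x.size < 2:
        raise ValueError("first-order statistics require >= 2 masked pixels")
    mean = x.mean()
    diff = x - mean
    m2 = np.mean(diff ** 2)
    m3 = np.mean(diff ** 3)
    m4 = np.mean(diff ** 4)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    sub = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(sub - sub.mean()))) if sub.size else 0.0
    levels = np.floor((x - x.min()) / bin_width).astype(np.int64)
    p = np.bincount(levels).astype(float)
    p = p[p > 0] / x.size
    energy = float(np.sum(x ** 2))
    out = OrderedDict()
    out["energy"] = energy
    out["total_energy"] = energy * pixel_area_mm2
    out["entropy"] = float(-np.sum(p * np.log2(p)))
    out["minimum"] = float(x.min())
    out["p10"] = float(p10)
    out["p90"] = float(p90)
    out["maximum"] = float(x.max())
    out["mean"] = float(mean)
    out["median"] = float(p50)
    out["iqr"] = float(p75 - p25)
    out["range"] = float(x.max() - x.min())
    out["mad"] = float(np.mean(np.abs(diff)))
    out["rmad"] = rmad
    out["rms"] = float(np.sqrt(np.mean(x ** 2)))
    out["std"] = float(np.sqrt(m2))
    out["skewness"] = float(m3 / m2 ** 1.5) if m2 > 1e-15 else 0.0
    out["kurtosis"] = float(m4 / m2 ** 2) if m2 > 1e-15 else 0.0
    out["variance"] = float(m2)
    out["uniformity"] = float(np.sum(p ** 2))
    return out


# ---------------------------------------------------------------------------
# 2D shape features
# ---------------------------------------------------------------------------

SHAPE2D_NAMES = (
    "shape_mesh_surface", "shape_pixel_surface", "shape_perimeter",
    "shape_perimeter_surface_ratio", "shape_sphericity",
    "shape_spherical_disproportion", "shape_max_diameter",
    "shape_major_axis", "shape_minor_axis", "shape_elongation",
)


def shape2d_features(mask: np.ndarray, mag: MagnificationModel) -> OrderedDict:
    """The 10 standard 2D shape features of a binary mask, in mm units."""
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("shape features require a non-empty mask")
    s = mag.scale
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    signed_area = 0.0
    pts_all = []
    for c in contours:
        ys, xs = c[:, 0], c[:, 1]
        signed_area += 0.5 * np.sum(xs * np.roll(ys, -1) - np.roll(xs, -1) * ys)
        pts_all.append(np.column_stack([xs, ys]))
    mesh_area = abs(signed_area) * s * s
    # Crofton estimate: unbiased on smooth boundaries, where the raw
    # marching-squares polyline overestimates by the staircase factor
    perimeter = float(measure.perimeter_crofton(mask, directions=4)) * s
    if mesh_area <= 0:  # sub-pixel sliver; fall back to pixel counting
        mesh_area = n * s * s

    pts = np.concatenate(pts_all) if pts_all else np.zeros((0, 2))
    max_diam = _max_pairwise_distance(pts) * s

    rr, cc = np.nonzero(mask)
    coords = np.column_stack([cc, rr]).astype(float)
    cov = np.cov(coords, rowvar=False, bias=True) if n > 1 else np.zeros((2, 2))
    evals = np.sort(np.clip(np.linalg.eigvalsh(np.atleast_2d(cov)), 0, None))
    minor_l, major_l = 4.0 * np.sqrt(evals[0]) * s, 4.0 * np.sqrt(evals[-1]) * s

    out = OrderedDict()
    out["shape_mesh_surface"] = float(mesh_area)
    out["shape_pixel_surface"] = float(n * s * s)
    out["shape_perimeter"] = float(perimeter)
    out["shape_perimeter_surface_ratio"] = float(perimeter / mesh_area)
    sph = 2.0 * np.sqrt(np.pi * mesh_area) / perimeter if perimeter > 0 else 1.0
    out["shape_sphericity"] = float(sph)
    out["shape_spherical_disproportion"] = float(1.0 / sph) if sph > 0 else 0.0
    out["shape_max_diameter"] = float(max_diam)
    out["shape_major_axis"] = float(major_l)
    out["shape_minor_axis"] = float(minor_l)
    out["shape_elongation"] = (float(np.sqrt(evals[0] / evals[-1]))
                               if evals[-1] > 0 else 1.0)
    return out


def _max_pairwise_distance(pts: np.ndarray) -> float:
    if len(pts) < 2:
        return 0.0
    try:
        from scipy.spatial import ConvexHull

        if len(pts) > 3:
            pts = pts[ConvexHull(pts).vertices]
    except Exception:  # collinear points etc.
        pass
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

GLCM_NAMES = (
    "glcm_autocorrelation", "glcm_joint_average", "glcm_cluster_prominence",
    "glcm_cluster_shade", "glcm_cluster_tendency", "glcm_contrast",
    "glcm_correlation", "glcm_difference_average", "glcm_difference_entropy",
    "glcm_difference_variance", "glcm_id", "glcm_idm", "glcm_idmn",
    "glcm_idn", "glcm_imc1", "glcm_imc2", "glcm_inverse_variance",
    "glcm_joint_energy", "glcm_joint_entropy", "glcm_max_probability",
    "glcm_mcc", "glcm_sum_average", "glcm_sum_entropy", "glcm_sum_squares",
)


def glcm_matrix(levels: np.ndarray, mask: np.ndarray,
                offset: tuple[int, int]) -> np.ndarray:
    """Symmetric distance-1 co-occurrence counts for one direction."""
    mask = np.asarray(mask, dtype=bool)
    ng = int(levels[mask].max()) if mask.any() else 0
    dy, dx = offset
    h, w = levels.shape
    a_sl = (slice(max(0, -dy), h - max(0, dy)), slice(max(0, -dx), w - max(0, dx)))
    b_sl = (slice(max(0, dy), h - max(0, -dy)), slice(max(0, dx), w - max(0, -dx)))
    valid = mask[a_sl] & mask[b_sl]
    i = levels[a_sl][valid].astype(np.int64)
    j = levels[b_sl][valid].astype(np.int64)
    counts = np.bincount((i - 1) * ng + (j - 1),
                         minlength=ng * ng).reshape(ng, ng).astype(float)
    return counts + counts.T


def _glcm_features_from_p(P: np.ndarray) -> OrderedDict:
    ng = P.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sig_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    sig_y = float(np.sqrt(np.sum((i - mu_y) ** 2 * py)))

    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.array([P[(ii + jj) == k].sum() for k in k_sum])
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.array([P[np.abs(ii - jj) == k].sum() for k in k_diff])

    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hy = float(-np.sum(py[py > 0] * np.log2(py[py > 0])))
    hxy = float(-np.sum(P[P > 0] * np.log2(P[P > 0])))
    pxy = np.outer(px, py)
    nz = (P > 0) & (pxy > 0)
    hxy1 = float(-np.sum(P[nz] * np.log2(pxy[nz])))
    nz2 = pxy > 0
    hxy2 = float(-np.sum(pxy[nz2] * np.log2(pxy[nz2])))

    out = OrderedDict()
    out["glcm_autocorrelation"] = float(np.sum(ii * jj * P))
    out["glcm_joint_average"] = mu_x
    cp = ii + jj - mu_x - mu_y
    out["glcm_cluster_prominence"] = float(np.sum(cp ** 4 * P))
    out["glcm_cluster_shade"] = float(np.sum(cp ** 3 * P))
    out["glcm_cluster_tendency"] = float(np.sum(cp ** 2 * P))
    out["glcm_contrast"] = float(np.sum((ii - jj) ** 2 * P))
    if sig_x * sig_y > 1e-12:
        out["glcm_correlation"] = float(
            (np.sum(ii * jj * P) - mu_x * mu_y) / (sig_x * sig_y))
    else:
        out["glcm_correlation"] = 1.0
    da = float(np.sum(k_diff * p_diff))
    out["glcm_difference_average"] = da
    pd_nz = p_diff[p_diff > 0]
    out["glcm_difference_entropy"] = float(-np.sum(pd_nz * np.log2(pd_nz)))
    out["glcm_difference_variance"] = float(np.sum((k_diff - da) ** 2 * p_diff))
    absd = np.abs(ii - jj)
    out["glcm_id"] = float(np.sum(P / (1.0 + absd)))
    out["glcm_idm"] = float(np.sum(P / (1.0 + absd ** 2)))
    out["glcm_idmn"] = float(np.sum(P / (1.0 + (absd / ng) ** 2)))
    out["glcm_idn"] = float(np.sum(P / (1.0 + absd / ng)))
    denom = max(hx, hy)
    out["glcm_imc1"] = float((hxy - hxy1) / denom) if denom > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    out["glcm_imc2"] = float(np.sqrt(max(arg, 0.0)))
    off = absd > 0
    out["glcm_inverse_variance"] = float(np.sum(P[off] / absd[off] ** 2))
    out["glcm_joint_energy"] = float(np.sum(P ** 2))
    out["glcm_joint_entropy"] = hxy
    out["glcm_max_probability"] = float(P.max())
    out["glcm_mcc"] = _glcm_mcc(P, px, py)
    out["glcm_sum_average"] = float(np.sum(k_sum * p_sum))
    ps_nz = p_sum[p_sum > 0]
    out["glcm_sum_entropy"] = float(-np.sum(ps_nz * np.log2(ps_nz)))
    out["glcm_sum_squares"] = float(np.sum((i - mu_x) ** 2 * px))
    return out


def _glcm_mcc(P: np.ndarray, px: np.ndarray, py: np.ndarray) -> float:
    keep = px > 0
    if keep.sum() < 2:
        return 1.0
    Pk = P[np.ix_(keep, keep)]
    pxk = px[keep]
    pyk = py[keep]
    A = Pk / pyk[None, :]
    Q = (A @ Pk.T) / pxk[:, None]
    ev = np.sort(np.real(np.linalg.eigvals(Q)))
    return float(np.sqrt(max(ev[-2], 0.0)))


def glcm_features(levels: np.ndarray, mask: np.ndarray) -> OrderedDict:
    """The 24 GLCM statistics, averaged over the four 2D directions."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    per_dir = []
    for off in _OFFSETS_4DIR:
        counts = glcm_matrix(levels, mask, off)
        total = counts.sum()
        if total == 0:
            continue
        per_dir.append(_glcm_features_from_p(counts / total))
    if not per_dir:
        # isolated pixels: treat as a constant pairing of the first level
        l0 = int(levels[mask].flat[0])
        P = np.zeros((l0, l0))
        P[l0 - 1, l0 - 1] = 1.0
        per_dir.append(_glcm_features_from_p(P))
    return OrderedDict(
        (name, float(np.mean([d[name] for d in per_dir]))) for name in GLCM_NAMES)


# ---------------------------------------------------------------------------
# Run-length, size-zone, NGTDM, GLDM
# ---------------------------------------------------------------------------

GLRLM_NAMES = (
    "glrlm_sre", "glrlm_lre", "glrlm_gln", "glrlm_glnn", "glrlm_rln",
    "glrlm_rlnn", "glrlm_rp", "glrlm_glv", "glrlm_rv", "glrlm_re",
    "glrlm_lglre", "glrlm_hglre", "glrlm_srlgle", "glrlm_srhgle",
    "glrlm_lrlgle", "glrlm_lrhgle",
)

GLSZM_NAMES = (
    "glszm_sae", "glszm_lae", "glszm_gln", "glszm_glnn", "glszm_szn",
    "glszm_sznn", "glszm_zp", "glszm_glv", "glszm_zv", "glszm_ze",
    "glszm_lglze", "glszm_hglze", "glszm_salgle", "glszm_sahgle",
    "glszm_lalgle", "glszm_lahgle",
)

NGTDM_NAMES = ("ngtdm_coarseness", "ngtdm_contrast", "ngtdm_busyness",
               "ngtdm_complexity", "ngtdm_strength")

GLDM_NAMES = (
    "gldm_sde", "gldm_lde", "gldm_gln", "gldm_dn", "gldm_dnn", "gldm_glv",
    "gldm_dv", "gldm_de", "gldm_lgle", "gldm_hgle", "gldm_sdlgle",
    "gldm_sdhgle", "gldm_ldlgle", "gldm_ldhgle",
)


def _lines_for_direction(arr: np.ndarray, offset: tuple[int, int]) -> list:
    dy, dx = offset
    if (dy, dx) == (0, 1):
        return [arr[r] for r in range(arr.shape[0])]
    if (dy, dx) == (1, 0):
        return [arr[:, c] for c in range(arr.shape[1])]
    if (dy, dx) == (1, 1):
        return [arr.diagonal(k) for k in range(-arr.shape[0] + 1, arr.shape[1])]
    if (dy, dx) == (1, -1):
        f = np.fliplr(arr)
        return [f.diagonal(k) for k in range(-f.shape[0] + 1, f.shape[1])]
    raise ValueError(f"unsupported offset {offset}")


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray,
                 offset: tuple[int, int]) -> np.ndarray:
    """Run-length counts P(i, r) for one direction (runs broken by the mask)."""
    arr = np.where(np.asarray(mask, dtype=bool), levels, 0).astype(np.int64)
    ng = int(arr.max())
    lines = _lines_for_direction(arr, offset)
    sep = np.zeros(1, dtype=np.int64)
    seq = np.concatenate([np.concatenate([line, sep]) for line in lines]) \
        if lines else sep
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [seq.size]))
    vals = seq[starts]
    lens = ends - starts
    keep = vals > 0
    vals, lens = vals[keep], lens[keep]
    rmax = int(lens.max()) if lens.size else 1
    P = np.zeros((ng, rmax))
    np.add.at(P, (vals - 1, lens - 1), 1.0)
    return P


def _weighted_matrix_features(P: np.ndarray, prefix: str, n_pixels: int,
                              names: tuple[str, ...]) -> OrderedDict:
    """Shared GLRLM/GLSZM/GLDM feature formulas over a (level, size) matrix."""
    ns = P.sum()
    if ns <= 0:
        raise ValueError("empty texture matrix")
    ng, sm = P.shape
    i = np.arange(1, ng + 1, dtype=float)
    s = np.arange(1, sm + 1, dtype=float)
    ii, ss = np.meshgrid(i, s, indexing="ij")
    p = P / ns
    pi = P.sum(axis=1)
    ps = P.sum(axis=0)
    mu_i = float(np.sum(i * pi / ns))
    mu_s = float(np.sum(s * ps / ns))
    pnz = p[p > 0]
    vals = [
        float(np.sum(P / ss ** 2) / ns),               # small/short emphasis
        float(np.sum(P * ss ** 2) / ns),               # large/long emphasis
        float(np.sum(pi ** 2) / ns),                   # gray-level non-uniformity
        float(np.sum(pi ** 2) / ns ** 2),              # ... normalized
        float(np.sum(ps ** 2) / ns),                   # size non-uniformity
        float(np.sum(ps ** 2) / ns ** 2),              # ... normalized
        float(ns / n_pixels),                          # percentage
        float(np.sum(p * (ii - mu_i) ** 2)),           # gray-level variance
        float(np.sum(p * (ss - mu_s) ** 2)),           # size variance
        float(-np.sum(pnz * np.log2(pnz))),            # entropy
        float(np.sum(P / ii ** 2) / ns),               # low gray-level
        float(np.sum(P * ii ** 2) / ns),               # high gray-level
        float(np.sum(P / (ii ** 2 * ss ** 2)) / ns),   # small+low
        float(np.sum(P * ii ** 2 / ss ** 2) / ns),     # small+high
        float(np.sum(P * ss ** 2 / ii ** 2) / ns),     # large+low
        float(np.sum(P * ii ** 2 * ss ** 2) / ns),     # large+high
    ]
    return OrderedDict(zip(names, vals))


def _glrlm_features(levels: np.ndarray, mask: np.ndarray) -> OrderedDict:
    n_pixels = int(np.asarray(mask, dtype=bool).sum())
    per_dir = []
    for off in _OFFSETS_4DIR:
        P = glrlm_matrix(levels, mask, off)
        per_dir.append(_weighted_matrix_features(P, "glrlm", n_pixels,
                                                 GLRLM_NAMES))
    return OrderedDict(
        (n, float(np.mean([d[n] for d in per_dir]))) for n in GLRLM_NAMES)


def glszm_matrix(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Size-zone counts P(i, s); zones are 8-connected same-level components."""
    arr = np.where(np.asarray(mask, dtype=bool), levels, 0).astype(np.int64)
    ng = int(arr.max())
    entries: list[tuple[int, int]] = []
    smax = 1
    for lev in range(1, ng + 1):
        binary = arr == lev
        if not binary.any():
            continue
        lab, nlab = measure.label(binary, connectivity=2, return_num=True)
        sizes = np.bincount(lab.ravel())[1:]
        for sz in sizes:
            entries.append((lev, int(sz)))
            smax = max(smax, int(sz))
    P = np.zeros((ng, smax))
    for lev, sz in entries:
        P[lev - 1, sz - 1] += 1.0
    return P


def _glszm_features(levels: np.ndarray, mask: np.ndarray) -> OrderedDict:
    n_pixels = int(np.asarray(mask, dtype=bool).sum())
    P = glszm_matrix(levels, mask)
    return _weighted_matrix_features(P, "glszm", n_pixels, GLSZM_NAMES)


def _neighbor_stats(levels: np.ndarray, mask: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel count and sum of in-mask Chebyshev-1 neighbor levels."""
    mask = np.asarray(mask, dtype=bool)
    lm = np.where(mask, levels, 0).astype(float)
    mf = mask.astype(float)
    h, w = levels.shape
    nsum = np.zeros((h, w))
    ncnt = np.zeros((h, w))
    for dy, dx in _OFFSETS_8:
        a_sl = (slice(max(0, -dy), h - max(0, dy)),
                slice(max(0, -dx), w - max(0, dx)))
        b_sl = (slice(max(0, dy), h - max(0, -dy)),
                slice(max(0, dx), w - max(0, -dx)))
        nsum[a_sl] += lm[b_sl]
        ncnt[a_sl] += mf[b_sl]
    return ncnt, nsum


def _ngtdm_features(levels: np.ndarray, mask: np.ndarray) -> OrderedDict:
    mask = np.asarray(mask, dtype=bool)
    ncnt, nsum = _neighbor_stats(levels, mask)
    valid = mask & (ncnt > 0)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("NGTDM: no pixels with in-mask neighbors")
    lv = levels[valid].astype(np.int64)
    ng = int(lv.max())
    abar = nsum[valid] / ncnt[valid]
    dev = np.abs(lv - abar)
    n_i = np.bincount(lv, minlength=ng + 1)[1:].astype(float)
    s_i = np.bincount(lv, weights=dev, minlength=ng + 1)[1:]
    p_i = n_i / n
    i = np.arange(1, ng + 1, dtype=float)
    act = p_i > 0
    ngp = int(act.sum())
    ia, pa, sa = i[act], p_i[act], s_i[act]

    out = OrderedDict()
    den = float(np.sum(pa * sa))
    out["ngtdm_coarseness"] = float(1.0 / den) if den > 0 else 1e6
    if ngp > 1:
        dif2 = (ia[:, None] - ia[None, :]) ** 2
        out["ngtdm_contrast"] = float(
            np.sum(pa[:, None] * pa[None, :] * dif2) / (ngp * (ngp - 1))
            * np.sum(s_i) / n)
    else:
        out["ngtdm_contrast"] = 0.0
    bus_den = float(np.sum(np.abs(ia[:, None] * pa[:, None]
                                  - ia[None, :] * pa[None, :])))
    out["ngtdm_busyness"] = float(den / bus_den) if bus_den > 0 else 0.0
    absd = np.abs(ia[:, None] - ia[None, :])
    psum = pa[:, None] + pa[None, :]
    num = pa[:, None] * sa[:, None] + pa[None, :] * sa[None, :]
    out["ngtdm_complexity"] = float(np.sum(absd * num / psum) / n)
    s_tot = float(np.sum(sa))
    if s_tot > 0:
        out["ngtdm_strength"] = float(
            np.sum(psum * (ia[:, None] - ia[None, :]) ** 2) / s_tot)
    else:
        out["ngtdm_strength"] = 0.0
    return out


def gldm_matrix(levels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Dependence counts P(i, k): k = 1 + number of Chebyshev-1 in-mask
    neighbors with the same quantized level (alpha = 0)."""
    mask = np.asarray(mask, dtype=bool)
    h, w = levels.shape
    dep = np.zeros((h, w), dtype=np.int64)
    for dy, dx in _OFFSETS_8:
        a_sl = (slice(max(0, -dy), h - max(0, dy)),
                slice(max(0, -dx), w - max(0, dx)))
        b_sl = (slice(max(0, dy), h - max(0, -dy)),
                slice(max(0, dx), w - max(0, -dx)))
        same = (levels[a_sl] == levels[b_sl]) & mask[a_sl] & mask[b_sl]
        dep[a_sl] += same
    lv = levels[mask].astype(np.int64)
    k = dep[mask] + 1
    ng, kmax = int(lv.max()), int(k.max())
    P = np.zeros((ng, kmax))
    np.add.at(P, (lv - 1, k - 1), 1.0)
    return P


_GLDM_ROWMAP = {  # positions in the shared 16-feature formula block
    "gldm_sde": 0, "gldm_lde": 1, "gldm_gln": 2, "gldm_dn": 4, "gldm_dnn": 5,
    "gldm_glv": 7, "gldm_dv": 8, "gldm_de": 9, "gldm_lgle": 10,
    "gldm_hgle": 11, "gldm_sdlgle": 12, "gldm_sdhgle": 13,
    "gldm_ldlgle": 14, "gldm_ldhgle": 15,
}


def _gldm_features(levels: np.ndarray, mask: np.ndarray) -> OrderedDict:
    n_pixels = int(np.asarray(mask, dtype=bool).sum())
    P = gldm_matrix(levels, mask)
    shared = _weighted_matrix_features(P, "gldm", n_pixels,
                                       tuple(f"_{k}" for k in range(16)))
    vals = list(shared.values())
    return OrderedDict((name, vals[idx]) for name, idx in _GLDM_ROWMAP.items())


def texture_matrix_features(levels: np.ndarray, mask: np.ndarray,
                            family: str) -> OrderedDict:
    """Texture features of one family over quantized levels within a mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if family == "GLRLM":
        return _glrlm_features(levels, mask)
    if family == "GLSZM":
        return _glszm_features(levels, mask)
    if family == "NGTDM":
        return _ngtdm_features(levels, mask)
    if family == "GLDM":
        return _gldm_features(levels, mask)
    raise ValueError(f"unknown texture family {family!r}")


# ---------------------------------------------------------------------------
# Full per-case pool
# ---------------------------------------------------------------------------

GEOMETRY_FEATURES = ("ovality_index", "torsion_angle", "ppa_area",
                     "ppa_perimeter", "ppa_width", "disc_fovea_distance")

GEOMETRY_UNITS = {
    "ovality_index": "", "torsion_angle": "deg", "ppa_area": "mm^2",
    "ppa_perimeter": "mm", "ppa_width": "mm", "disc_fovea_distance": "mm",
}


def roi_channel_features(values: np.ndarray, mask: np.ndarray,
                         bin_width: float, pixel_area_mm2: float
                         ) -> OrderedDict:
    """All 94 intensity/texture features of one ROI x channel combination."""
    out = first_order_features(values, mask, bin_width, pixel_area_mm2)
    levels, _ = discretize_channel(values, mask, bin_width)
    out.update(glcm_features(levels, mask))
    for family in ("GLRLM", "GLSZM", "NGTDM", "GLDM"):
        out.update(texture_matrix_features(levels, mask, family))
    return out


def extract_pool(image: np.ndarray, annotation: Annotation,
                 masks: ROIMaskSet, mag: MagnificationModel,
                 bin_width: float = DEFAULT_BIN_WIDTH
                 ) -> tuple[OrderedDict, dict[str, str], list[str]]:
    """Assemble the complete per-case feature vector.

    Geometry block + per-ROI shape features + per-ROI x LAB-channel
    first-order and texture features, in a fixed deterministic order.
    Returns (features, units, flags); an empty ROI adds a flag (the case is
    never silently dropped) and NaNs for its features.
    """
    channels = lab_channels_rescaled(image)
    disc_geo = disc_shape_metrics(annotation, mag)
    ppa_geo = ppa_metrics(annotation, mag)

    features: OrderedDict = OrderedDict()
    features["ovality_index"] = disc_geo.ovality_index
    features["torsion_angle"] = disc_geo.torsion_deg
    features["ppa_area"] = ppa_geo.area_mm2
    features["ppa_perimeter"] = ppa_geo.perimeter_mm
    features["ppa_width"] = ppa_geo.width_mm
    features["disc_fovea_distance"] = ppa_geo.disc_fovea_distance_mm
    units = dict(GEOMETRY_UNITS)
    flags: list[str] = []

    pixel_area = mag.scale ** 2
    roi_masks = masks.as_dict()
    for roi in ROIS:
        mask = roi_masks[roi]
        empty = int(mask.sum()) < 2
        if empty:
            flags.append(f"{roi}:empty")
        if empty:
            shape_vals = OrderedDict((n, float("nan")) for n in SHAPE2D_NAMES)
        else:
            shape_vals = shape2d_features(mask, mag)
        for name, val in shape_vals.items():
            features[f"{roi}_{name}"] = val
        for ch in CHANNELS:
            if empty:
                block = OrderedDict()
                for n in FIRST_ORDER_NAMES + GLCM_NAMES + GLRLM_NAMES \
                        + GLSZM_NAMES + NGTDM_NAMES + GLDM_NAMES:
                    block[n] = float("nan")
            else:
                block = roi_channel_features(channels[ch].values, mask,
                                             bin_width, pixel_area)
            for name, val in block.items():
                features[f"{roi}_{ch}_{name}"] = float(val)
    return features, units, flags
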