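"""Independent brute-force oracles for the radiomic operator families.

Deliberately written as plain per-pixel / per-pair loops, sharing no code
with the package implementation, so agreement is a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------


def first_order_oracle(values, mask, bin_width=25.0, pixel_area=1.0) -> dict:
    xs = sorted(float(values[r][c]) for r, c in zip(*np.nonzero(mask)))
    n = len(xs)
    mean = sum(xs) / n
    m2 = sum((v - mean) ** 2 for v in xs) / n
    m3 = sum((v - mean) ** 3 for v in xs) / n
    m4 = sum((v - mean) ** 4 for v in xs) / n
    p10, p25, p50, p75, p90 = (float(np.percentile(xs, q))
                               for q in (10, 25, 50, 75, 90))
    sub = [v for v in xs if p10 <= v <= p90]
    sub_mean = sum(sub) / len(sub) if sub else 0.0
    hist: dict[int, int] = {}
    for v in xs:
        b = int(math.floor((v - xs[0]) / bin_width))
        hist[b] = hist.get(b, 0) + 1
    probs = [c / n for c in hist.values()]
    energy = sum(v * v for v in xs)
    return {
        "energy": energy,
        "total_energy": energy * pixel_area,
        "entropy": -sum(p * math.log2(p) for p in probs),
        "minimum": xs[0],
        "p10": p10,
        "p90": p90,
        "maximum": xs[-1],
        "mean": mean,
        "median": p50,
        "iqr": p75 - p25,
        "range": xs[-1] - xs[0],
        "mad": sum(abs(v - mean) for v in xs) / n,
        "rmad": (sum(abs(v - sub_mean) for v in sub) / len(sub)) if sub else 0.0,
        "rms": math.sqrt(energy / n),
        "std": math.sqrt(m2),
        "skewness": m3 / m2 ** 1.5 if m2 > 1e-15 else 0.0,
        "kurtosis": m4 / m2 ** 2 if m2 > 1e-15 else 0.0,
        "variance": m2,
        "uniformity": sum(p * p for p in probs),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def glcm_matrix_oracle(levels, mask, offset) -> np.ndarray:
    h, w = levels.shape
    ng = int(max(levels[r][c] for r, c in zip(*np.nonzero(mask))))
    P = np.zeros((ng, ng))
    dy, dx = offset
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dy, c + dx
            if 0 <= r2 < h and 0 <= c2 < w and mask[r, c] and mask[r2, c2]:
                i, j = int(levels[r, c]), int(levels[r2, c2])
                P[i - 1, j - 1] += 1
                P[j - 1, i - 1] += 1
    return P


def glcm_features_oracle(levels, mask) -> dict:
    dirs = [(0, 1), (1, 0), (1, 1), (1, -1)]
    per_dir = []
    for off in dirs:
        C = glcm_matrix_oracle(levels, mask, off)
        if C.sum() == 0:
            continue
        per_dir.append(_glcm_from_matrix(C / C.sum()))
    assert per_dir, "oracle needs at least one direction with pairs"
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


def _glcm_from_matrix(P: np.ndarray) -> dict:
    ng = P.shape[0]
    px = [sum(P[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sig_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sig_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))
    p_sum = {}
    p_diff = {}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + P[i, j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + P[i, j]
    hx = -sum(p * math.log2(p) for p in px if p > 0)
    hy = -sum(p * math.log2(p) for p in py if p > 0)
    hxy = -sum(P[i, j] * math.log2(P[i, j])
               for i in range(ng) for j in range(ng) if P[i, j] > 0)
    hxy1 = -sum(P[i, j] * math.log2(px[i] * py[j])
                for i in range(ng) for j in range(ng)
                if P[i, j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j])
                for i in range(ng) for j in range(ng) if px[i] * py[j] > 0)
    da = sum(k * v for k, v in p_diff.items())
    out = {}
    out["glcm_autocorrelation"] = sum((i + 1) * (j + 1) * P[i, j]
                                      for i in range(ng) for j in range(ng))
    out["glcm_joint_average"] = mu_x
    for name, power in (("glcm_cluster_prominence", 4),
                        ("glcm_cluster_shade", 3),
                        ("glcm_cluster_tendency", 2)):
        out[name] = sum((i + 1 + j + 1 - mu_x - mu_y) ** power * P[i, j]
                        for i in range(ng) for j in range(ng))
    out["glcm_contrast"] = sum((i - j) ** 2 * P[i, j]
                               for i in range(ng) for j in range(ng))
    if sig_x * sig_y > 1e-12:
        out["glcm_correlation"] = (out["glcm_autocorrelation"]
                                   - mu_x * mu_y) / (sig_x * sig_y)
    else:
        out["glcm_correlation"] = 1.0
    out["glcm_difference_average"] = da
    out["glcm_difference_entropy"] = -sum(v * math.log2(v)
                                          for v in p_diff.values() if v > 0)
    out["glcm_difference_variance"] = sum((k - da) ** 2 * v
                                          for k, v in p_diff.items())
    out["glcm_id"] = sum(P[i, j] / (1 + abs(i - j))
                         for i in range(ng) for j in range(ng))
    out["glcm_idm"] = sum(P[i, j] / (1 + (i - j) ** 2)
                          for i in range(ng) for j in range(ng))
    out["glcm_idmn"] = sum(P[i, j] / (1 + (abs(i - j) / ng) ** 2)
                           for i in range(ng) for j in range(ng))
    out["glcm_idn"] = sum(P[i, j] / (1 + abs(i - j) / ng)
                          for i in range(ng) for j in range(ng))
    denom = max(hx, hy)
    out["glcm_imc1"] = (hxy - hxy1) / denom if denom > 0 else 0.0
    out["glcm_imc2"] = math.sqrt(max(1.0 - math.exp(-2 * (hxy2 - hxy)), 0.0))
    out["glcm_inverse_variance"] = sum(P[i, j] / (i - j) ** 2
                                       for i in range(ng) for j in range(ng)
                                       if i != j)
    out["glcm_joint_energy"] = sum(P[i, j] ** 2
                                   for i in range(ng) for j in range(ng))
    out["glcm_joint_entropy"] = hxy
    out["glcm_max_probability"] = max(P[i, j] for i in range(ng)
                                      for j in range(ng))
    out["glcm_mcc"] = _mcc_oracle(P, px, py)
    out["glcm_sum_average"] = sum(k * v for k, v in p_sum.items())
    out["glcm_sum_entropy"] = -sum(v * math.log2(v)
                                   for v in p_sum.values() if v > 0)
    out["glcm_sum_squares"] = sum((i + 1 - mu_x) ** 2 * px[i]
                                  for i in range(ng))
    return out


def _mcc_oracle(P, px, py) -> float:
    ng = P.shape[0]
    keep = [i for i in range(ng) if px[i] > 0]
    if len(keep) < 2:
        return 1.0
    m = len(keep)
    Q = np.zeros((m, m))
    for a, i in enumerate(keep):
        for b, j in enumerate(keep):
            Q[a, b] = sum(P[i, k] * P[j, k] / (px[i] * py[k])
                          for k in keep if py[k] > 0)
    ev = sorted(np.real(np.linalg.eigvals(Q)))
    return math.sqrt(max(ev[-2], 0.0))


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------


def glrlm_matrix_oracle(levels, mask, offset) -> np.ndarray:
    h, w = levels.shape
    arr = np.where(mask, levels, 0)
    ng = int(arr.max())
    dy, dx = offset
    starts = []
    for r in range(h):
        for c in range(w):
            rp, cp = r - dy, c - dx
            if not (0 <= rp < h and 0 <= cp < w):
                starts.append((r, c))
    runs = []
    for r0, c0 in starts:
        line = []
        r, c = r0, c0
        while 0 <= r < h and 0 <= c < w:
            line.append(int(arr[r, c]))
            r, c = r + dy, c + dx
        cur, length = 0, 0
        for v in line + [0]:
            if v == cur and v > 0:
                length += 1
            else:
                if cur > 0:
                    runs.append((cur, length))
                cur, length = v, 1
    rmax = max((ln for _, ln in runs), default=1)
    P = np.zeros((ng, rmax))
    for lev, ln in runs:
        P[lev - 1, ln - 1] += 1
    return P


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------


def glszm_matrix_oracle(levels, mask) -> np.ndarray:
    h, w = levels.shape
    arr = np.where(mask, levels, 0)
    ng = int(arr.max())
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if arr[r, c] > 0 and not seen[r, c]:
                lev = int(arr[r, c])
                stack = [(r, c)]
                seen[r, c] = True
                size = 0
                while stack:
                    rr, cc = stack.pop()
                    size += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = rr + dr, cc + dc
                            if (0 <= r2 < h and 0 <= c2 < w
                                    and not seen[r2, c2]
                                    and arr[r2, c2] == lev):
                                seen[r2, c2] = True
                                stack.append((r2, c2))
                zones.append((lev, size))
    smax = max((s for _, s in zones), default=1)
    P = np.zeros((ng, smax))
    for lev, s in zones:
        P[lev - 1, s - 1] += 1
    return P


def sizezone_features_oracle(P: np.ndarray, n_pixels: int,
                             names: tuple) -> dict:
    """Shared GLRLM/GLSZM formula block computed with explicit loops."""
    ng, sm = P.shape
    ns = P.sum()
    pi = [sum(P[i, s] for s in range(sm)) for i in range(ng)]
    ps = [sum(P[i, s] for i in range(ng)) for s in range(sm)]
    mu_i = sum((i + 1) * pi[i] for i in range(ng)) / ns
    mu_s = sum((s + 1) * ps[s] for s in range(sm)) / ns
    ent = -sum(P[i, s] / ns * math.log2(P[i, s] / ns)
               for i in range(ng) for s in range(sm) if P[i, s] > 0)
    vals = [
        sum(P[i, s] / (s + 1) ** 2 for i in range(ng) for s in range(sm)) / ns,
        sum(P[i, s] * (s + 1) ** 2 for i in range(ng) for s in range(sm)) / ns,
        sum(v ** 2 for v in pi) / ns,
        sum(v ** 2 for v in pi) / ns ** 2,
        sum(v ** 2 for v in ps) / ns,
        sum(v ** 2 for v in ps) / ns ** 2,
        ns / n_pixels,
        sum(P[i, s] / ns * (i + 1 - mu_i) ** 2
            for i in range(ng) for s in range(sm)),
        sum(P[i, s] / ns * (s + 1 - mu_s) ** 2
            for i in range(ng) for s in range(sm)),
        ent,
        sum(P[i, s] / (i + 1) ** 2 for i in range(ng) for s in range(sm)) / ns,
        sum(P[i, s] * (i + 1) ** 2 for i in range(ng) for s in range(sm)) / ns,
        sum(P[i, s] / ((i + 1) ** 2 * (s + 1) ** 2)
            for i in range(ng) for s in range(sm)) / ns,
        sum(P[i, s] * (i + 1) ** 2 / (s + 1) ** 2
            for i in range(ng) for s in range(sm)) / ns,
        sum(P[i, s] * (s + 1) ** 2 / (i + 1) ** 2
            for i in range(ng) for s in range(sm)) / ns,
        sum(P[i, s] * (i + 1) ** 2 * (s + 1) ** 2
            for i in range(ng) for s in range(sm)) / ns,
    ]
    return dict(zip(names, vals))


def glrlm_features_oracle(levels, mask, names) -> dict:
    n_pixels = int(mask.sum())
    per_dir = [sizezone_features_oracle(
        glrlm_matrix_oracle(levels, mask, off), n_pixels, names)
        for off in ((0, 1), (1, 0), (1, 1), (1, -1))]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in names}


def glszm_features_oracle(levels, mask, names) -> dict:
    return sizezone_features_oracle(glszm_matrix_oracle(levels, mask),
                                    int(mask.sum()), names)


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------


def ngtdm_features_oracle(levels, mask) -> dict:
    h, w = levels.shape
    entries = []  # (level, |level - neighborhood mean|)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            nb = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]:
                        nb.append(int(levels[r2, c2]))
            if nb:
                entries.append((int(levels[r, c]),
                                abs(levels[r, c] - sum(nb) / len(nb))))
    n = len(entries)
    ng = max(lev for lev, _ in entries)
    n_i = [0.0] * (ng + 1)
    s_i = [0.0] * (ng + 1)
    for lev, dev in entries:
        n_i[lev] += 1
        s_i[lev] += dev
    p_i = [v / n for v in n_i]
    act = [i for i in range(1, ng + 1) if p_i[i] > 0]
    ngp = len(act)
    den = sum(p_i[i] * s_i[i] for i in act)
    out = {}
    out["ngtdm_coarseness"] = 1.0 / den if den > 0 else 1e6
    if ngp > 1:
        out["ngtdm_contrast"] = (
            sum(p_i[i] * p_i[j] * (i - j) ** 2 for i in act for j in act)
            / (ngp * (ngp - 1)) * sum(s_i[i] for i in act) / n)
    else:
        out["ngtdm_contrast"] = 0.0
    bus_den = sum(abs(i * p_i[i] - j * p_i[j]) for i in act for j in act)
    out["ngtdm_busyness"] = den / bus_den if bus_den > 0 else 0.0
    out["ngtdm_complexity"] = sum(
        abs(i - j) * (p_i[i] * s_i[i] + p_i[j] * s_i[j]) / (p_i[i] + p_i[j])
        for i in act for j in act) / n
    s_tot = sum(s_i[i] for i in act)
    out["ngtdm_strength"] = (sum((p_i[i] + p_i[j]) * (i - j) ** 2
                                 for i in act for j in act) / s_tot
                             if s_tot > 0 else 0.0)
    return out


# ---------------------------------------------------------------------------
# GLDM
# ---------------------------------------------------------------------------


def gldm_matrix_oracle(levels, mask) -> np.ndarray:
    h, w = levels.shape
    entries = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            dep = 1
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if (0 <= r2 < h and 0 <= c2 < w and mask[r2, c2]
                            and levels[r2, c2] == levels[r, c]):
                        dep += 1
            entries.append((int(levels[r, c]), dep))
    ng = max(lev for lev, _ in entries)
    kmax = max(k for _, k in entries)
    P = np.zeros((ng, kmax))
    for lev, k in entries:
        P[lev - 1, k - 1] += 1
    return P


def gldm_features_oracle(levels, mask, names) -> dict:
    P = gldm_matrix_oracle(levels, mask)
    shared = sizezone_features_oracle(P, int(mask.sum()),
                                      tuple(f"_{i}" for i in range(16)))
    vals = list(shared.values())
    rowmap = {"gldm_sde": 0, "gldm_lde": 1, "gldm_gln": 2, "gldm_dn": 4,
              "gldm_dnn": 5, "gldm_glv": 7, "gldm_dv": 8, "gldm_de": 9,
              "gldm_lgle": 10, "gldm_hgle": 11, "gldm_sdlgle": 12,
              "gldm_sdhgle": 13, "gldm_ldlgle": 14, "gldm_ldhgle": 15}
    return {name: vals[rowmap[name]] for name in names}
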