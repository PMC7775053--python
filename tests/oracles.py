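"""Independent brute-force oracles used by the test suite.

Everything here is written as directly as possible from the defining
formulas — explicit Python loops, no shared code with the package — so a
match between package and oracle is meaningful.
"""

from __future__ import annotations

import math

import numpy as np

ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_counts_brute(levels: np.ndarray, distance: int, angle: int, n_levels: int) -> np.ndarray:
    """Symmetrized pair counts by exhaustive enumeration (0 = unmasked)."""
    dr, dc = ANGLE_STEPS[angle]
    dr, dc = dr * distance, dc * distance
    rows, cols = levels.shape
    counts = np.zeros((n_levels, n_levels))
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols:
                a, b = levels[r, c], levels[r2, c2]
                if a > 0 and b > 0:
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
    return counts


def glcm_features_brute(p: np.ndarray) -> dict:
    n = p.shape[0]
    con = ene = hom = 0.0
    mu_i = mu_j = 0.0
    for i in range(n):
        for j in range(n):
            mu_i += (i + 1) * p[i, j]
            mu_j += (j + 1) * p[i, j]
    var_i = var_j = 0.0
    for i in range(n):
        for j in range(n):
            var_i += (i + 1 - mu_i) ** 2 * p[i, j]
            var_j += (j + 1 - mu_j) ** 2 * p[i, j]
    cor = 0.0
    for i in range(n):
        for j in range(n):
            con += abs(i - j) ** 2 * p[i, j]
            ene += p[i, j] ** 2
            hom += p[i, j] / (1 + abs(i - j))
            cor += (i + 1 - mu_i) * (j + 1 - mu_j) * p[i, j]
    if var_i > 0 and var_j > 0:
        cor /= math.sqrt(var_i * var_j)
    else:
        cor = float("nan")
    return {"CON": con, "COR": cor, "ENE": ene, "HOM": hom}


# ---------------------------------------------------------------------------
# GRLM
# ---------------------------------------------------------------------------

def grlm_runs_brute(levels: np.ndarray, angle: int):
    """All maximal runs by pixel-wise scanning: a run starts at a pixel with
    no same-level masked predecessor along the direction."""
    dr, dc = ANGLE_STEPS[angle]
    rows, cols = levels.shape
    runs = []
    for r in range(rows):
        for c in range(cols):
            v = levels[r, c]
            if v == 0:
                continue
            pr, pc = r - dr, c - dc
            if 0 <= pr < rows and 0 <= pc < cols and levels[pr, pc] == v:
                continue  # not a run start
            length = 0
            rr, cc = r, c
            while 0 <= rr < rows and 0 <= cc < cols and levels[rr, cc] == v:
                length += 1
                rr += dr
                cc += dc
            runs.append((int(v), length))
    return runs


def grlm_matrix_brute(levels: np.ndarray, angle: int, n_levels: int) -> np.ndarray:
    runs = grlm_runs_brute(levels, angle)
    n_r = max((ln for _, ln in runs), default=1)
    m = np.zeros((n_levels, n_r))
    for lev, ln in runs:
        m[lev - 1, ln - 1] += 1
    return m


def grlm_features_brute(m: np.ndarray, n_masked: int) -> dict:
    n_g, n_r = m.shape
    s = m.sum()
    vals = dict.fromkeys(
        ["SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
         "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GV", "RV", "RE"], 0.0)
    for i in range(1, n_g + 1):
        for j in range(1, n_r + 1):
            p = m[i - 1, j - 1]
            vals["SRE"] += p / j ** 2
            vals["LRE"] += p * j ** 2
            vals["LGRE"] += p / i ** 2
            vals["HGRE"] += p * i ** 2
            vals["SRLGE"] += p / (i ** 2 * j ** 2)
            vals["SRHGE"] += p * i ** 2 / j ** 2
            vals["LRLGE"] += p * j ** 2 / i ** 2
            vals["LRHGE"] += p * i ** 2 * j ** 2
    for key in ["SRE", "LRE", "LGRE", "HGRE", "SRLGE", "SRHGE", "LRLGE", "LRHGE"]:
        vals[key] /= s
    vals["GLN"] = sum(m[i, :].sum() ** 2 for i in range(n_g)) / s
    vals["RLN"] = sum(m[:, j].sum() ** 2 for j in range(n_r)) / s
    vals["RP"] = s / n_masked
    pn = m / s
    mu_i = sum((i + 1) * pn[i, j] for i in range(n_g) for j in range(n_r))
    mu_j = sum((j + 1) * pn[i, j] for i in range(n_g) for j in range(n_r))
    vals["GV"] = sum((i + 1 - mu_i) ** 2 * pn[i, j] for i in range(n_g) for j in range(n_r))
    vals["RV"] = sum((j + 1 - mu_j) ** 2 * pn[i, j] for i in range(n_g) for j in range(n_r))
    vals["RE"] = -sum(pn[i, j] * math.log2(pn[i, j])
                      for i in range(n_g) for j in range(n_r) if pn[i, j] > 0)
    return vals


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

def glszm_zones_brute(levels: np.ndarray):
    """8-connected equal-level zones by flood fill."""
    rows, cols = levels.shape
    seen = np.zeros_like(levels, dtype=bool)
    zones = []
    for r in range(rows):
        for c in range(cols):
            if levels[r, c] == 0 or seen[r, c]:
                continue
            v = levels[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < rows and 0 <= nc < cols
                                and not seen[nr, nc] and levels[nr, nc] == v):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
            zones.append((int(v), size))
    return zones


def glszm_matrix_brute(levels: np.ndarray, n_levels: int) -> np.ndarray:
    zones = glszm_zones_brute(levels)
    n_s = max((sz for _, sz in zones), default=1)
    m = np.zeros((n_levels, n_s))
    for lev, sz in zones:
        m[lev - 1, sz - 1] += 1
    return m


def glszm_features_brute(m: np.ndarray, n_masked: int) -> dict:
    n_g, n_s = m.shape
    nz = m.sum()
    vals = {}
    vals["SAE"] = sum(m[i, j] / (j + 1) ** 2 for i in range(n_g) for j in range(n_s)) / nz
    vals["LAE"] = sum(m[i, j] * (j + 1) ** 2 for i in range(n_g) for j in range(n_s)) / nz
    vals["GLN-SZ"] = sum(m[i, :].sum() ** 2 for i in range(n_g)) / nz
    vals["SZN"] = sum(m[:, j].sum() ** 2 for j in range(n_s)) / nz
    vals["ZP"] = nz / n_masked
    vals["LGZE"] = sum(m[i, j] / (i + 1) ** 2 for i in range(n_g) for j in range(n_s)) / nz
    vals["HGZE"] = sum(m[i, j] * (i + 1) ** 2 for i in range(n_g) for j in range(n_s)) / nz
    vals["SALGE"] = sum(m[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
                        for i in range(n_g) for j in range(n_s)) / nz
    vals["SAHGE"] = sum(m[i, j] * (i + 1) ** 2 / (j + 1) ** 2
                        for i in range(n_g) for j in range(n_s)) / nz
    vals["LALGE"] = sum(m[i, j] * (j + 1) ** 2 / (i + 1) ** 2
                        for i in range(n_g) for j in range(n_s)) / nz
    vals["LAHGE"] = sum(m[i, j] * (i + 1) ** 2 * (j + 1) ** 2
                        for i in range(n_g) for j in range(n_s)) / nz
    pn = m / nz
    mu_i = sum((i + 1) * pn[i, j] for i in range(n_g) for j in range(n_s))
    mu_j = sum((j + 1) * pn[i, j] for i in range(n_g) for j in range(n_s))
    vals["GV-SZ"] = sum((i + 1 - mu_i) ** 2 * pn[i, j] for i in range(n_g) for j in range(n_s))
    vals["ZV"] = sum((j + 1 - mu_j) ** 2 * pn[i, j] for i in range(n_g) for j in range(n_s))
    vals["ZE"] = -sum(pn[i, j] * math.log2(pn[i, j])
                      for i in range(n_g) for j in range(n_s) if pn[i, j] > 0)
    return vals


# ---------------------------------------------------------------------------
# misc oracles
# ---------------------------------------------------------------------------

def least_squares_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form normal-equations simple linear regression (slope, intercept)."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, sxy = (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def auc_pairwise(labels01: np.ndarray, scores: np.ndarray) -> float:
    """AUC as explicit pairwise probability with ties counting 1/2."""
    pos = scores[np.asarray(labels01) == 1]
    neg = scores[np.asarray(labels01) == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def points_in_polygon_brute(xs, zs, contour) -> np.ndarray:
    """Even-odd ray casting with on-edge points counted inside."""
    contour = np.asarray(contour, dtype=float)
    n = len(contour)
    out = np.zeros(len(xs), dtype=bool)
    for k, (x, z) in enumerate(zip(xs, zs)):
        inside = False
        on_edge = False
        for i in range(n):
            x1, z1 = contour[i]
            x2, z2 = contour[(i + 1) % n]
            # on-segment check
            cross = (x2 - x1) * (z - z1) - (z2 - z1) * (x - x1)
            if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 \
                    and min(z1, z2) - 1e-12 <= z <= max(z1, z2) + 1e-12:
                on_edge = True
                break
            if (z1 > z) != (z2 > z):
                x_int = x1 + (z - z1) * (x2 - x1) / (z2 - z1)
                if x < x_int:
                    inside = not inside
        out[k] = inside or on_edge
    return out
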