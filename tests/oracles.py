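"""Independent brute-force oracles for texture features.

Everything here is written as naive loops straight from the textbook
definitions — no shared code with the package implementation — so the
vectorized feature computations can be checked against it on small grids.
"""

from __future__ import annotations

import math

import numpy as np

from rpvkit.features.texture import DIRECTIONS_13


def in_bounds(idx, shape) -> bool:
    return all(0 <= i < s for i, s in zip(idx, shape))


def naive_glcm(levels: np.ndarray, ng: int, directions=DIRECTIONS_13) -> np.ndarray:
    counts = np.zeros((ng, ng))
    for d in directions:
        for idx in np.ndindex(levels.shape):
            j = tuple(a + b for a, b in zip(idx, d))
            if in_bounds(j, levels.shape):
                a, b = levels[idx], levels[j]
                if a > 0 and b > 0:
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
    return counts


def naive_glrlm(levels: np.ndarray, ng: int, directions=DIRECTIONS_13) -> np.ndarray:
    lmax = sum(levels.shape)
    counts = np.zeros((ng, lmax))
    for d in directions:
        for idx in np.ndindex(levels.shape):
            v = levels[idx]
            if v == 0:
                continue
            prev = tuple(a - b for a, b in zip(idx, d))
            if in_bounds(prev, levels.shape) and levels[prev] == v:
                continue  # not the start of a run
            length, cur = 1, idx
            while True:
                nxt = tuple(a + b for a, b in zip(cur, d))
                if in_bounds(nxt, levels.shape) and levels[nxt] == v:
                    length, cur = length + 1, nxt
                else:
                    break
            counts[v - 1, length - 1] += 1
    return counts


def naive_ngtdm(levels: np.ndarray, ng: int):
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    offsets = [
        tuple(o - 1 for o in off)
        for off in np.ndindex((3,) * levels.ndim)
        if any(o != 1 for o in off)
    ]
    for idx in np.ndindex(levels.shape):
        v = levels[idx]
        if v == 0:
            continue
        neighbors = []
        for d in offsets:
            j = tuple(a + b for a, b in zip(idx, d))
            if in_bounds(j, levels.shape) and levels[j] > 0:
                neighbors.append(levels[j])
        if neighbors:
            n_i[v - 1] += 1
            s_i[v - 1] += abs(v - sum(neighbors) / len(neighbors))
    return n_i, s_i


def _entropy(values) -> float:
    return -sum(q * math.log2(q) for q in values if q > 0)


def naive_glcm_stats(counts: np.ndarray) -> dict[str, float]:
    ng = counts.shape[0]
    p = counts / counts.sum()
    px = [sum(p[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(p[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    sd_x = math.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng)))
    sd_y = math.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng)))

    p_sum = {}
    p_diff = {}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + p[i, j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + p[i, j]

    def s2(f):
        return sum(f(i + 1, j + 1, p[i, j]) for i in range(ng) for j in range(ng))

    hxy = _entropy(p.ravel())
    hx, hy = _entropy(px), _entropy(py)
    hxy1 = -sum(
        p[i, j] * math.log2(px[i] * py[j])
        for i in range(ng)
        for j in range(ng)
        if px[i] * py[j] > 0 and p[i, j] > 0
    )
    hxy2 = _entropy([px[i] * py[j] for i in range(ng) for j in range(ng)])
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))) if hxy2 >= hxy else 0.0

    if ng > 1 and sd_x > 0 and sd_y > 0:
        q = np.zeros((ng, ng))
        for i in range(ng):
            for j in range(ng):
                q[i, j] = sum(
                    p[i, k] * p[j, k] / (px[i] * py[k])
                    for k in range(ng)
                    if px[i] * py[k] > 0
                )
        eig = sorted(abs(v) for v in np.linalg.eigvals(q))
        mcc = math.sqrt(max(0.0, eig[-2]))
    else:
        mcc = 1.0

    da = sum(k * v for k, v in p_diff.items())
    sa = sum(k * v for k, v in p_sum.items())
    corr = (
        (s2(lambda i, j, pij: i * j * pij) - mu_x * mu_y) / (sd_x * sd_y)
        if sd_x > 0 and sd_y > 0
        else 0.0
    )
    return {
        "autocorrelation": s2(lambda i, j, pij: i * j * pij),
        "joint_average": s2(lambda i, j, pij: i * pij),
        "joint_max": float(p.max()),
        "cluster_prominence": s2(lambda i, j, pij: (i + j - mu_x - mu_y) ** 4 * pij),
        "cluster_shade": s2(lambda i, j, pij: (i + j - mu_x - mu_y) ** 3 * pij),
        "cluster_tendency": s2(lambda i, j, pij: (i + j - mu_x - mu_y) ** 2 * pij),
        "contrast": s2(lambda i, j, pij: (i - j) ** 2 * pij),
        "correlation": corr,
        "difference_average": da,
        "difference_entropy": _entropy(p_diff.values()),
        "difference_variance": sum((k - da) ** 2 * v for k, v in p_diff.items()),
        "dissimilarity": s2(lambda i, j, pij: abs(i - j) * pij),
        "energy": s2(lambda i, j, pij: pij * pij),
        "entropy": hxy,
        "homogeneity": s2(lambda i, j, pij: pij / (1 + (i - j) ** 2)),
        "id": s2(lambda i, j, pij: pij / (1 + abs(i - j))),
        "idn": s2(lambda i, j, pij: pij / (1 + abs(i - j) / ng)),
        "idmn": s2(lambda i, j, pij: pij / (1 + (i - j) ** 2 / ng**2)),
        "inverse_variance": s2(lambda i, j, pij: pij / (i - j) ** 2 if i != j else 0.0),
        "imc1": imc1,
        "imc2": imc2,
        "sum_average": sa,
        "sum_entropy": _entropy(p_sum.values()),
        "sum_variance": sum((k - sa) ** 2 * v for k, v in p_sum.items()),
        "sum_squares": s2(lambda i, j, pij: (i - mu_x) ** 2 * pij),
        "mcc": mcc,
    }


def naive_glrlm_stats(counts: np.ndarray, n_voxels: int, n_directions: int) -> dict[str, float]:
    ng, lmax = counts.shape
    total = counts.sum()
    cells = [
        (i + 1, j + 1, counts[i, j])
        for i in range(ng)
        for j in range(lmax)
        if counts[i, j] > 0
    ]
    mu_i = sum(i * r for i, j, r in cells) / total
    mu_j = sum(j * r for i, j, r in cells) / total
    return {
        "SRE": sum(r / j**2 for i, j, r in cells) / total,
        "LRE": sum(r * j**2 for i, j, r in cells) / total,
        "GLN": sum(counts[i, :].sum() ** 2 for i in range(ng)) / total,
        "GLNN": sum(counts[i, :].sum() ** 2 for i in range(ng)) / total**2,
        "RLN": sum(counts[:, j].sum() ** 2 for j in range(lmax)) / total,
        "RLNN": sum(counts[:, j].sum() ** 2 for j in range(lmax)) / total**2,
        "RP": total / (n_directions * n_voxels),
        "LGLRE": sum(r / i**2 for i, j, r in cells) / total,
        "HGLRE": sum(r * i**2 for i, j, r in cells) / total,
        "SRLGLE": sum(r / (i**2 * j**2) for i, j, r in cells) / total,
        "SRHGLE": sum(r * i**2 / j**2 for i, j, r in cells) / total,
        "LRLGLE": sum(r * j**2 / i**2 for i, j, r in cells) / total,
        "LRHGLE": sum(r * i**2 * j**2 for i, j, r in cells) / total,
        "GLV": sum((r / total) * (i - mu_i) ** 2 for i, j, r in cells),
        "RLV": sum((r / total) * (j - mu_j) ** 2 for i, j, r in cells),
        "RE": _entropy([r / total for _, _, r in cells]),
    }


def naive_ngtdm_stats(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    ng = len(n_i)
    nv = n_i.sum()
    p = n_i / nv
    occ = [i for i in range(ng) if p[i] > 0]
    ngp = len(occ)
    ps = sum(p[i] * s_i[i] for i in range(ng))
    coarse = 1.0 / ps if ps > 0 else 1e6
    if ngp > 1:
        contrast = sum(
            p[i] * p[j] * (i - j) ** 2 for i in occ for j in occ
        ) / (ngp * (ngp - 1)) * (s_i.sum() / nv)
        denom = sum(abs((i + 1) * p[i] - (j + 1) * p[j]) for i in occ for j in occ)
        busy = ps / denom if denom > 0 else 0.0
        cplx = sum(
            abs(i - j) * (p[i] * s_i[i] + p[j] * s_i[j]) / (p[i] + p[j])
            for i in occ
            for j in occ
        ) / nv
        ssum = s_i.sum()
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in occ for j in occ) / ssum
            if ssum > 0
            else 0.0
        )
    else:
        contrast = busy = cplx = strength = 0.0
    return {
        "Coarse": coarse,
        "Contra": contrast,
        "Busy": busy,
        "Complex": cplx,
        "Strength": strength,
    }
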