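"""Second-order 3D texture features: GLCM, GLRLM and NGTDM.

All three operate on the fixed-bin-width gray levels (1..Ng) restricted to
the segmentation.  Co-occurrence and run-length matrices aggregate the 13
unique 3D directions at distance 1 by *matrix summation* before
normalization (run-conserving convention); the NGTDM neighborhood is
26-connected with neighbors restricted to the mask, and voxels with no
masked neighbor are excluded from the count Nv.

Degenerate single-level regions follow continuity limits: contrasts 0,
energy 1, correlation 0, entropies 0 — never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..preprocess import DiscretizedVolume

__all__ = [
    "DIRECTIONS_13",
    "GLCMatrix",
    "GLRLMatrix",
    "NGTDMatrix",
    "glcm_matrix",
    "glrlm_matrix",
    "ngtdm_matrix",
    "glcm_features",
    "glrlm_features",
    "ngtdm_features",
]

#: The 13 unique direction vectors of the 26-neighborhood (one per +/- pair),
#: first nonzero component positive, in (x, y, z) index order.
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)

_EPS = np.finfo(np.float64).tiny


@dataclass
class GLCMatrix:
    counts: np.ndarray  # (Ng, Ng) symmetric co-occurrence counts

    @property
    def probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts


@dataclass
class GLRLMatrix:
    counts: np.ndarray  # (Ng, Lmax) run counts r(i, j), j = run length
    n_voxels: int
    n_directions: int

    @property
    def total_runs(self) -> float:
        return float(self.counts.sum())


@dataclass
class NGTDMatrix:
    n_i: np.ndarray  # (Ng,) occurrence counts of voxels with >=1 masked neighbor
    s_i: np.ndarray  # (Ng,) summed absolute deviation from neighborhood mean

    @property
    def n_voxels(self) -> int:
        return int(self.n_i.sum())

    @property
    def p_i(self) -> np.ndarray:
        nv = self.n_i.sum()
        return self.n_i / nv if nv > 0 else self.n_i


def _shifted_views(arr: np.ndarray, d: tuple[int, int, int]):
    """Aligned (center, neighbor) views of ``arr`` offset by direction ``d``."""
    src = []
    dst = []
    for n, k in zip(arr.shape, d):
        if k == 0:
            src.append(slice(None))
            dst.append(slice(None))
        elif k > 0:
            src.append(slice(0, n - k))
            dst.append(slice(k, n))
        else:
            src.append(slice(-k, n))
            dst.append(slice(0, n + k))
    return arr[tuple(src)], arr[tuple(dst)]


def glcm_matrix(
    levels: np.ndarray,
    ng: int,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> GLCMatrix:
    """Symmetric distance-1 co-occurrence counts summed over directions."""
    counts = np.zeros((ng, ng), dtype=np.float64)
    for d in directions:
        a, b = _shifted_views(levels, d)
        valid = (a > 0) & (b > 0)
        i = a[valid] - 1
        j = b[valid] - 1
        flat = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng)
        counts += flat + flat.T  # symmetric accumulation
    return GLCMatrix(counts=counts)


def _shift2(arr: np.ndarray, offset: tuple[int, int], fill=0) -> np.ndarray:
    """out[y, z] = arr[y - dy, z - dz], out-of-range filled with ``fill``."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for n, k in zip(arr.shape, offset):
        if k >= 0:
            src.append(slice(0, n - k))
            dst.append(slice(k, n))
        else:
            src.append(slice(-k, n))
            dst.append(slice(0, n + k))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def glrlm_matrix(
    levels: np.ndarray,
    ng: int,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> GLRLMatrix:
    """Run counts r(i, j) summed over directions.

    For each direction a dynamic-programming scan along the leading axis
    computes, per voxel, the length of the run ending there; runs are
    recorded at their final voxel.  Conservation holds by construction:
    sum_ij r(i,j) * j = n_directions * (masked voxel count).
    """
    lmax = int(sum(levels.shape))
    counts = np.zeros((ng, lmax), dtype=np.float64)
    nv = int(np.count_nonzero(levels))
    for d in directions:
        axis = next(i for i, k in enumerate(d) if k != 0)
        lv = np.moveaxis(levels, axis, 0)  # leading component is +1
        rest = tuple(k for i, k in enumerate(d) if i != axis)

        n0 = lv.shape[0]
        runlen = np.zeros(lv.shape, dtype=np.int64)
        for t in range(n0):
            cur = lv[t]
            if t == 0:
                runlen[t] = (cur > 0).astype(np.int64)
                continue
            prev_lev = _shift2(lv[t - 1], rest)
            prev_len = _shift2(runlen[t - 1], rest)
            same = (cur > 0) & (prev_lev > 0) & (prev_lev == cur)
            runlen[t] = np.where(cur > 0, np.where(same, prev_len + 1, 1), 0)
        ends = lv > 0
        for t in range(n0 - 1):
            cur = lv[t]
            succ = _shift2(lv[t + 1], (-rest[0], -rest[1]))
            ends[t] &= ~((succ > 0) & (succ == cur))
        lev_end = lv[ends] - 1
        len_end = runlen[ends] - 1
        flat = np.bincount(lev_end * lmax + len_end, minlength=ng * lmax)
        counts += flat.reshape(ng, lmax)
    return GLRLMatrix(counts=counts, n_voxels=nv, n_directions=len(directions))


def ngtdm_matrix(levels: np.ndarray, ng: int) -> NGTDMatrix:
    """Neighborhood gray-tone difference matrix (26-connected, masked)."""
    m = levels > 0
    kernel = np.ones((3,) * levels.ndim, dtype=np.float64)
    kernel[(1,) * levels.ndim] = 0.0
    nsum = ndimage.convolve((levels * m).astype(np.float64), kernel, mode="constant")
    ncnt = ndimage.convolve(m.astype(np.float64), kernel, mode="constant")
    use = m & (ncnt > 0)
    abar = np.zeros_like(nsum)
    abar[use] = nsum[use] / ncnt[use]
    dev = np.abs(levels - abar)[use]
    lev = levels[use] - 1
    n_i = np.bincount(lev, minlength=ng).astype(np.float64)
    s_i = np.bincount(lev, weights=dev, minlength=ng)
    return NGTDMatrix(n_i=n_i, s_i=s_i)


# ---------------------------------------------------------------------------
# statistics


def glcm_features(
    disc: DiscretizedVolume | GLCMatrix,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> dict[str, float]:
    mat = disc if isinstance(disc, GLCMatrix) else glcm_matrix(disc.levels, disc.ng, directions)
    p = mat.probabilities
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    sd_x = float(np.sqrt(((i - mu_x) ** 2 * px).sum()))
    sd_y = float(np.sqrt(((i - mu_y) ** 2 * py).sum()))

    # p_{x+y}(k), k = 2..2Ng and p_{x-y}(k), k = 0..Ng-1
    ksum = (ii + jj).astype(int)
    kdiff = np.abs(ii - jj).astype(int)
    p_sum = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    p_diff = np.bincount(kdiff.ravel(), weights=p.ravel(), minlength=ng)
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    k_diff = np.arange(0, ng, dtype=np.float64)

    def ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum()) if q.size else 0.0

    joint_avg = float((ii * p).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0

    hxy = ent(p.ravel())
    hx, hy = ent(px), ent(py)
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore"):
        hxy1 = float(-(p[pxy > 0] * np.log2(pxy[pxy > 0])).sum())
        hxy2 = float(-(pxy[pxy > 0] * np.log2(pxy[pxy > 0])).sum())
    if max(hx, hy) > 0:
        imc1 = (hxy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    off = ii != jj
    inverse_variance = float((p[off] / (ii - jj)[off] ** 2).sum())

    da = float((k_diff * p_diff).sum())
    sa = float((k_sum * p_sum).sum())

    # MCC: second-largest eigenvalue of Q; 1 for degenerate distributions
    if ng > 1 and sd_x > 0 and sd_y > 0:
        denom = np.outer(px, py)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(denom > 0, p / np.where(denom > 0, denom, 1.0), 0.0)
        qmat = q @ p.T
        eig = np.sort(np.abs(np.linalg.eigvals(qmat)))
        mcc = float(np.sqrt(max(0.0, eig[-2]))) if eig.size >= 2 else 1.0
    else:
        mcc = 1.0

    return {
        "autocorrelation": float((ii * jj * p).sum()),
        "joint_average": joint_avg,
        "joint_max": float(p.max()),
        "cluster_prominence": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),
        "cluster_shade": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),
        "cluster_tendency": float(((ii + jj - mu_x - mu_y) ** 2 * p).sum()),
        "contrast": contrast,
        "correlation": correlation,
        "difference_average": da,
        "difference_entropy": ent(p_diff),
        "difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "energy": float((p * p).sum()),
        "entropy": hxy,
        "homogeneity": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "idmn": float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()),
        "inverse_variance": inverse_variance,
        "imc1": float(imc1),
        "imc2": imc2,
        "sum_average": sa,
        "sum_entropy": ent(p_sum),
        "sum_variance": float(((k_sum - sa) ** 2 * p_sum).sum()),
        "sum_squares": float(((ii - mu_x) ** 2 * p).sum()),
        "mcc": mcc,
    }


def glrlm_features(
    disc: DiscretizedVolume | GLRLMatrix,
    directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13,
) -> dict[str, float]:
    mat = disc if isinstance(disc, GLRLMatrix) else glrlm_matrix(disc.levels, disc.ng, directions)
    r = mat.counts
    total = mat.total_runs
    ng, lmax = r.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, lmax + 1, dtype=np.float64)[None, :]
    p = r / total
    r_i = r.sum(axis=1)
    r_j = r.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    pnz = p[p > 0]
    return {
        "SRE": float((r / j**2).sum() / total),
        "LRE": float((r * j**2).sum() / total),
        "GLN": float((r_i**2).sum() / total),
        "GLNN": float((r_i**2).sum() / total**2),
        "RLN": float((r_j**2).sum() / total),
        "RLNN": float((r_j**2).sum() / total**2),
        "RP": float(total / (mat.n_directions * mat.n_voxels)),
        "LGLRE": float((r / i**2).sum() / total),
        "HGLRE": float((r * i**2).sum() / total),
        "SRLGLE": float((r / (i**2 * j**2)).sum() / total),
        "SRHGLE": float((r * i**2 / j**2).sum() / total),
        "LRLGLE": float((r * j**2 / i**2).sum() / total),
        "LRHGLE": float((r * i**2 * j**2).sum() / total),
        "GLV": float((p * (i - mu_i) ** 2).sum()),
        "RLV": float((p * (j - mu_j) ** 2).sum()),
        "RE": float(-(pnz * np.log2(pnz)).sum()),
    }


#: cap for coarseness when the deviation sum is zero (perfectly uniform region)
COARSENESS_CAP = 1e6


def ngtdm_features(disc: DiscretizedVolume | NGTDMatrix) -> dict[str, float]:
    mat = disc if isinstance(disc, NGTDMatrix) else ngtdm_matrix(disc.levels, disc.ng)
    p = mat.p_i
    s = mat.s_i
    nv = mat.n_voxels
    ng = len(p)
    occ = p > 0
    ngp = int(occ.sum())
    i = np.arange(1, ng + 1, dtype=np.float64)

    ps = float((p * s).sum())
    coarseness = 1.0 / ps if ps > 0 else COARSENESS_CAP

    if ngp > 1 and nv > 0:
        ii, jj = np.meshgrid(i[occ], i[occ], indexing="ij")
        pi, pj = np.meshgrid(p[occ], p[occ], indexing="ij")
        contrast = float((pi * pj * (ii - jj) ** 2).sum()) / (ngp * (ngp - 1))
        contrast *= float(s.sum()) / nv
        denom_busy = float(np.abs(ii * pi - jj * pj).sum())
        busyness = ps / denom_busy if denom_busy > 0 else 0.0
        si, sj = np.meshgrid(s[occ], s[occ], indexing="ij")
        complexity = float((np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum()) / nv
        ssum = float(s.sum())
        strength = float(((pi + pj) * (ii - jj) ** 2).sum()) / ssum if ssum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarse": coarseness,
        "Contra": contrast,
        "Busy": busyness,
        "Complex": complexity,
        "Strength": strength,
    }
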