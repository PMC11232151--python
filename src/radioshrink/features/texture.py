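"""Gray-level texture matrices (GLCM, GLRLM, GLSZM, GLDM, NGTDM) and their
feature sets.

Conventions
-----------
* Gray levels are positive integers; 0 marks voxels outside the region.
* GLCM: 13 unique 3D direction offsets at distance 1, symmetric counts,
  normalized per direction and then averaged over directions.
* GLRLM: run counts per (level, run length) averaged over the 13 directions.
* GLSZM: zone counts with 26-connectivity.
* GLDM: dependence = 1 + number of 26-neighbours with identical level
  (similarity tolerance alpha = 0), so the dependence axis starts at 1.
* Feature formulas follow the IBSI-consistent definitions used by the
  mainstream extractors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_EPS = np.finfo(float).tiny


@dataclass(frozen=True)
class DiscretizationSpec:
    """How raw intensities map to integer gray levels.

    ``fixed_bin_count`` spans [min, max] of the region with ``value`` bins;
    ``fixed_bin_width`` assigns level floor((v - min)/width) + 1.
    """

    mode: str = "fixed_bin_count"
    value: float = 32

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_bin_count", "fixed_bin_width"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.value <= 0:
            raise ValueError("discretization value must be positive")
        if self.mode == "fixed_bin_count" and int(self.value) != self.value:
            raise ValueError("bin count must be an integer")


def discretize(volume: np.ndarray, mask: np.ndarray,
               spec: DiscretizationSpec) -> np.ndarray:
    """Discretize intensities inside ``mask`` into gray levels >= 1.

    Returns an integer volume with 0 outside the mask. A constant region
    maps to a single level (not an error).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot discretize an empty region")
    v = np.asarray(volume, dtype=float)
    out = np.zeros(v.shape, dtype=np.int32)
    inside = v[mask]
    lo = inside.min()
    if spec.mode == "fixed_bin_count":
        n = int(spec.value)
        hi = inside.max()
        if np.isclose(hi, lo):
            out[mask] = 1
            return out
        lev = np.floor((inside - lo) / (hi - lo) * n).astype(np.int32) + 1
        lev[lev > n] = n  # v == max lands in the top bin
    else:
        lev = np.floor((inside - lo) / spec.value).astype(np.int32) + 1
    out[mask] = lev
    return out


# ---------------------------------------------------------------------------
# offsets and shifting helpers

def _unique_directions() -> list[tuple[int, int, int]]:
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                if (dx, dy, dz) > (-dx, -dy, -dz):
                    dirs.append((dx, dy, dz))
    assert len(dirs) == 13
    return dirs


DIRECTIONS_13 = _unique_directions()
OFFSETS_26 = DIRECTIONS_13 + [(-a, -b, -c) for a, b, c in DIRECTIONS_13]


def _shift(arr: np.ndarray, d: tuple[int, int, int], fill=0) -> np.ndarray:
    """result[x] = arr[x + d], zero-filled at the borders."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for ax, step in enumerate(d):
        n = arr.shape[ax]
        if step >= 0:
            src.append(slice(step, n))
            dst.append(slice(0, n - step))
        else:
            src.append(slice(0, n + step))
            dst.append(slice(-step, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# matrices

def glcm_matrix(levels: np.ndarray) -> np.ndarray:
    """Direction-averaged, symmetric, normalized co-occurrence matrix."""
    ng = int(levels.max())
    if ng == 0:
        raise ValueError("no voxels in region")
    acc = np.zeros((ng, ng))
    n_dirs = 0
    for d in DIRECTIONS_13:
        nb = _shift(levels, d)
        valid = (levels > 0) & (nb > 0)
        if not valid.any():
            continue
        counts = np.zeros((ng, ng))
        np.add.at(counts, (levels[valid] - 1, nb[valid] - 1), 1.0)
        counts = counts + counts.T
        acc += counts / counts.sum()
        n_dirs += 1
    if n_dirs == 0:
        # single isolated voxel: degenerate all-mass-in-one-cell matrix
        acc[levels.max() - 1, levels.max() - 1] = 1.0
        return acc
    return acc / n_dirs


def glrlm_matrix(levels: np.ndarray) -> np.ndarray:
    """Run-length counts per (gray level, run length), averaged over the 13
    directions. Entries may be fractional because of the averaging."""
    ng = int(levels.max())
    if ng == 0:
        raise ValueError("no voxels in region")
    max_len = max(levels.shape) * 2  # diagonal runs cannot exceed this
    acc = np.zeros((ng, max_len))
    in_mask = levels > 0
    for d in DIRECTIONS_13:
        nb = _shift(levels, d)
        match = in_mask & (nb == levels) & (nb > 0)
        prev = _shift(levels, (-d[0], -d[1], -d[2]))
        start = in_mask & ~((prev == levels) & (prev > 0))
        run_len = np.ones(levels.shape, dtype=np.int64)
        prod = match.astype(np.int64)
        shifted = match
        while prod.any():
            run_len += prod
            shifted = _shift(shifted, d)
            prod = prod * shifted
        np.add.at(acc, (levels[start] - 1, run_len[start] - 1), 1.0)
    acc /= len(DIRECTIONS_13)
    last = np.nonzero(acc.sum(axis=0))[0]
    return acc[:, : last[-1] + 1]


def glszm_matrix(levels: np.ndarray) -> np.ndarray:
    """Zone counts per (gray level, zone size), 26-connected."""
    ng = int(levels.max())
    if ng == 0:
        raise ValueError("no voxels in region")
    structure = np.ones((3, 3, 3), dtype=int)
    rows, cols, zone_sizes = [], [], []
    for lvl in range(1, ng + 1):
        binary = levels == lvl
        if not binary.any():
            continue
        lab, n = ndimage.label(binary, structure=structure)
        sizes = ndimage.sum_labels(binary, lab, index=np.arange(1, n + 1)).astype(int)
        rows.extend([lvl - 1] * n)
        cols.extend((sizes - 1).tolist())
        zone_sizes.extend(sizes.tolist())
    max_size = max(zone_sizes)
    mat = np.zeros((ng, max_size))
    np.add.at(mat, (np.array(rows), np.array(cols)), 1.0)
    return mat


def gldm_matrix(levels: np.ndarray) -> np.ndarray:
    """Dependence counts per (gray level, 1 + #identical 26-neighbours)."""
    ng = int(levels.max())
    if ng == 0:
        raise ValueError("no voxels in region")
    in_mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in OFFSETS_26:
        nb = _shift(levels, d)
        dep += (in_mask & (nb == levels) & (nb > 0)).astype(np.int64)
    mat = np.zeros((ng, 27))
    np.add.at(mat, (levels[in_mask] - 1, dep[in_mask]), 1.0)
    last = np.nonzero(mat.sum(axis=0))[0]
    return mat[:, : last[-1] + 1]


def ngtdm_table(levels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """NGTDM ingredients: per gray level i, the voxel count n_i and the
    summed absolute difference s_i between i and the mean level of each
    voxel's in-mask 26-neighbourhood."""
    ng = int(levels.max())
    if ng == 0:
        raise ValueError("no voxels in region")
    in_mask = levels > 0
    nb_sum = np.zeros(levels.shape, dtype=np.float64)
    nb_cnt = np.zeros(levels.shape, dtype=np.int64)
    for d in OFFSETS_26:
        nb = _shift(levels, d)
        hit = (nb > 0)
        nb_sum += np.where(hit, nb, 0)
        nb_cnt += hit.astype(np.int64)
    counts = np.zeros(ng)
    s = np.zeros(ng)
    has_nb = in_mask & (nb_cnt > 0)
    diffs = np.abs(levels - nb_sum / np.maximum(nb_cnt, 1))
    np.add.at(counts, levels[has_nb] - 1, 1.0)
    np.add.at(s, levels[has_nb] - 1, diffs[has_nb])
    return counts, s


# ---------------------------------------------------------------------------
# features

def glcm_features(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = float((px * i).sum())
    mu_y = float((py * i).sum())
    sig_x = float(np.sqrt((px * (i - mu_x) ** 2).sum()))
    sig_y = float(np.sqrt((py * (i - mu_y) ** 2).sum()))

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(0, ng)
    p_diff = np.array([P[np.abs(I - J) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([P[(I + J) == k].sum() for k in k_sum])

    def ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum()) if p.size else 0.0

    hxy = ent(P.ravel())
    pxy_prod = np.outer(px, py)
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy1 = float(-np.nansum(np.where(P > 0, P * np.log2(pxy_prod + _EPS), 0.0)))
    hxy2 = ent(pxy_prod.ravel())
    hx, hy = ent(px), ent(py)

    da = float((p_diff * k_diff).sum())
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    if sig_x > 0 and sig_y > 0:
        corr = (float((P * I * J).sum()) - mu_x * mu_y) / (sig_x * sig_y)
    else:
        corr = 1.0

    off_diag = np.abs(I - J) > 0
    inv_var = float((P[off_diag] / (I - J)[off_diag] ** 2).sum())

    # MCC: second largest eigenvalue of the Markov-like transition matrix Q
    if ng > 1 and np.all(px > 0):
        Q = np.einsum("ik,jk->ij", P, P / (px[:, None] * py[None, :] + _EPS))
        eig = np.sort(np.abs(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(max(0.0, eig[-2].real))) if len(eig) > 1 else 1.0
    else:
        mcc = 1.0

    return {
        "Autocorrelation": float((P * I * J).sum()),
        "JointAverage": mu_x,
        "ClusterProminence": float((P * (I + J - mu_x - mu_y) ** 4).sum()),
        "ClusterShade": float((P * (I + J - mu_x - mu_y) ** 3).sum()),
        "ClusterTendency": float((P * (I + J - mu_x - mu_y) ** 2).sum()),
        "Contrast": float((P * (I - J) ** 2).sum()),
        "Correlation": float(corr),
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(p_diff),
        "DifferenceVariance": float((p_diff * (k_diff - da) ** 2).sum()),
        "JointEnergy": float((P ** 2).sum()),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float((P / (1.0 + (I - J) ** 2)).sum()),
        "Idmn": float((P / (1.0 + ((I - J) / ng) ** 2)).sum()),
        "Id": float((P / (1.0 + np.abs(I - J))).sum()),
        "Idn": float((P / (1.0 + np.abs(I - J) / ng)).sum()),
        "InverseVariance": inv_var,
        "MaximumProbability": float(P.max()),
        "SumAverage": float((p_sum * k_sum).sum()),
        "SumEntropy": ent(p_sum),
        "SumSquares": float((P * (I - mu_x) ** 2).sum()),
        "MCC": mcc,
    }


def _weighted_stats(mat: np.ndarray):
    """Shared machinery of the run/zone/dependence families."""
    ns = mat.sum()
    p = mat / ns
    ng, nl = mat.shape
    i = np.arange(1, ng + 1)
    j = np.arange(1, nl + 1)
    I, J = np.meshgrid(i, j, indexing="ij")
    return ns, p, I, J


def glrlm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr, p, I, J = _weighted_stats(mat)
    pg = p.sum(axis=1)
    pl = p.sum(axis=0)
    mu_i = (p * I).sum()
    mu_j = (p * J).sum()
    pz = p[p > 0]
    return {
        "ShortRunEmphasis": float((p / J ** 2).sum()),
        "LongRunEmphasis": float((p * J ** 2).sum()),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg ** 2).sum()),
        "RunLengthNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pl ** 2).sum()),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float((p * (I - mu_i) ** 2).sum()),
        "RunVariance": float((p * (J - mu_j) ** 2).sum()),
        "RunEntropy": float(-(pz * np.log2(pz)).sum()),
        "LowGrayLevelRunEmphasis": float((p / I ** 2).sum()),
        "HighGrayLevelRunEmphasis": float((p * I ** 2).sum()),
        "ShortRunLowGrayLevelEmphasis": float((p / (I ** 2 * J ** 2)).sum()),
        "ShortRunHighGrayLevelEmphasis": float((p * I ** 2 / J ** 2).sum()),
        "LongRunLowGrayLevelEmphasis": float((p * J ** 2 / I ** 2).sum()),
        "LongRunHighGrayLevelEmphasis": float((p * I ** 2 * J ** 2).sum()),
    }


def glszm_features(mat: np.ndarray, n_voxels: int) -> dict[str, float]:
    nz, p, I, J = _weighted_stats(mat)
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_i = (p * I).sum()
    mu_j = (p * J).sum()
    pzz = p[p > 0]
    return {
        "SmallAreaEmphasis": float((p / J ** 2).sum()),
        "LargeAreaEmphasis": float((p * J ** 2).sum()),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg ** 2).sum()),
        "SizeZoneNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ps ** 2).sum()),
        "ZonePercentage": float(nz / n_voxels),
        "GrayLevelVariance": float((p * (I - mu_i) ** 2).sum()),
        "ZoneVariance": float((p * (J - mu_j) ** 2).sum()),
        "ZoneEntropy": float(-(pzz * np.log2(pzz)).sum()),
        "LowGrayLevelZoneEmphasis": float((p / I ** 2).sum()),
        "HighGrayLevelZoneEmphasis": float((p * I ** 2).sum()),
        "SmallAreaLowGrayLevelEmphasis": float((p / (I ** 2 * J ** 2)).sum()),
        "SmallAreaHighGrayLevelEmphasis": float((p * I ** 2 / J ** 2).sum()),
        "LargeAreaLowGrayLevelEmphasis": float((p * J ** 2 / I ** 2).sum()),
        "LargeAreaHighGrayLevelEmphasis": float((p * I ** 2 * J ** 2).sum()),
    }


def gldm_features(mat: np.ndarray) -> dict[str, float]:
    nz, p, I, J = _weighted_stats(mat)
    pg = p.sum(axis=1)
    pd = p.sum(axis=0)
    mu_i = (p * I).sum()
    mu_j = (p * J).sum()
    pzz = p[p > 0]
    return {
        "SmallDependenceEmphasis": float((p / J ** 2).sum()),
        "LargeDependenceEmphasis": float((p * J ** 2).sum()),
        "GrayLevelNonUniformity": float((mat.sum(axis=1) ** 2).sum() / nz),
        "DependenceNonUniformity": float((mat.sum(axis=0) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pd ** 2).sum()),
        "GrayLevelVariance": float((p * (I - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (J - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(pzz * np.log2(pzz)).sum()),
        "LowGrayLevelEmphasis": float((p / I ** 2).sum()),
        "HighGrayLevelEmphasis": float((p * I ** 2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (I ** 2 * J ** 2)).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * I ** 2 / J ** 2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * J ** 2 / I ** 2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * I ** 2 * J ** 2).sum()),
    }


def compute_ngtdm_busyness(levels: np.ndarray) -> float | None:
    """NGTDM busyness; ``None`` (undefined) when the region has < 2 levels."""
    counts, s = ngtdm_table(levels)
    present = counts > 0
    if present.sum() < 2:
        return None
    n = counts.sum()
    p = counts / n
    i = np.arange(1, len(counts) + 1)
    num = float((p[present] * s[present]).sum())
    ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
    pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
    denom = float(np.abs(ii * pi - jj * pj).sum())
    if denom == 0:
        return None
    return num / denom


def texture_features(levels: np.ndarray, family: str) -> dict[str, float]:
    """Dispatch: matrix construction plus the family's feature formulas."""
    n_voxels = int((levels > 0).sum())
    if family == "glcm":
        return glcm_features(glcm_matrix(levels))
    if family == "glrlm":
        return glrlm_features(glrlm_matrix(levels), n_voxels)
    if family == "glszm":
        return glszm_features(glszm_matrix(levels), n_voxels)
    if family == "gldm":
        return gldm_features(gldm_matrix(levels))
    raise ValueError(f"unknown texture family {family!r}")
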