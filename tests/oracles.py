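"""Independent brute-force oracles used by the test suite.

Everything here is written as plain-Python enumeration: texture matrices by
explicit neighbour walking, features by direct double sums, AUC by exhaustive
pair counting, Kaplan-Meier by the hand product-limit recipe, and the
hypergeometric tail by binomial-coefficient enumeration. These oracles are
deliberately slow, simple and independent of the package's vectorized code.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

DIRS_13 = [d for d in itertools.product((-1, 0, 1), repeat=3)
           if d != (0, 0, 0) and d > tuple(-x for x in d)]
DIRS_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def _inside(shape, p):
    return all(0 <= c < s for c, s in zip(p, shape))


def _voxels(levels):
    return [p for p in itertools.product(*map(range, levels.shape))
            if levels[p] > 0]


def glcm_oracle(levels: np.ndarray) -> np.ndarray:
    ng = int(levels.max())
    acc = np.zeros((ng, ng))
    used = 0
    for d in DIRS_13:
        counts = np.zeros((ng, ng))
        for p in _voxels(levels):
            q = tuple(a + b for a, b in zip(p, d))
            if _inside(levels.shape, q) and levels[q] > 0:
                counts[levels[p] - 1, levels[q] - 1] += 1
                counts[levels[q] - 1, levels[p] - 1] += 1
        if counts.sum() > 0:
            acc += counts / counts.sum()
            used += 1
    if used == 0:
        acc[int(levels.max()) - 1, int(levels.max()) - 1] = 1.0
        return acc
    return acc / used


def glrlm_oracle(levels: np.ndarray) -> np.ndarray:
    ng = int(levels.max())
    runs = []
    for d in DIRS_13:
        for p in _voxels(levels):
            prev = tuple(a - b for a, b in zip(p, d))
            if _inside(levels.shape, prev) and levels[prev] == levels[p]:
                continue  # not a run start
            length = 1
            q = tuple(a + b for a, b in zip(p, d))
            while _inside(levels.shape, q) and levels[q] == levels[p]:
                length += 1
                q = tuple(a + b for a, b in zip(q, d))
            runs.append((levels[p], length))
    max_len = max(r[1] for r in runs)
    mat = np.zeros((ng, max_len))
    for lvl, length in runs:
        mat[lvl - 1, length - 1] += 1
    return mat / len(DIRS_13)


def glszm_oracle(levels: np.ndarray) -> np.ndarray:
    ng = int(levels.max())
    seen = set()
    zones = []
    for start in _voxels(levels):
        if start in seen:
            continue
        lvl = levels[start]
        stack, zone = [start], {start}
        while stack:
            p = stack.pop()
            for d in DIRS_26:
                q = tuple(a + b for a, b in zip(p, d))
                if (_inside(levels.shape, q) and q not in zone
                        and levels[q] == lvl):
                    zone.add(q)
                    stack.append(q)
        seen |= zone
        zones.append((lvl, len(zone)))
    max_size = max(z[1] for z in zones)
    mat = np.zeros((ng, max_size))
    for lvl, size in zones:
        mat[lvl - 1, size - 1] += 1
    return mat


def gldm_oracle(levels: np.ndarray) -> np.ndarray:
    ng = int(levels.max())
    entries = []
    for p in _voxels(levels):
        dep = 0
        for d in DIRS_26:
            q = tuple(a + b for a, b in zip(p, d))
            if _inside(levels.shape, q) and levels[q] == levels[p]:
                dep += 1
        entries.append((levels[p], dep + 1))
    max_dep = max(e[1] for e in entries)
    mat = np.zeros((ng, max_dep))
    for lvl, dep in entries:
        mat[lvl - 1, dep - 1] += 1
    return mat


def ngtdm_oracle(levels: np.ndarray):
    ng = int(levels.max())
    counts = np.zeros(ng)
    s = np.zeros(ng)
    for p in _voxels(levels):
        nb = []
        for d in DIRS_26:
            q = tuple(a + b for a, b in zip(p, d))
            if _inside(levels.shape, q) and levels[q] > 0:
                nb.append(levels[q])
        if nb:
            counts[levels[p] - 1] += 1
            s[levels[p] - 1] += abs(levels[p] - sum(nb) / len(nb))
    return counts, s


def busyness_oracle(levels: np.ndarray):
    counts, s = ngtdm_oracle(levels)
    present = [i for i in range(len(counts)) if counts[i] > 0]
    if len(present) < 2:
        return None
    n = counts.sum()
    num = sum(counts[i] / n * s[i] for i in present)
    denom = sum(abs((i + 1) * counts[i] / n - (j + 1) * counts[j] / n)
                for i in present for j in present)
    if denom == 0:
        return None
    return num / denom


# --- texture feature formulas by direct summation --------------------------

def glcm_features_oracle(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    cells = [(i, j) for i in range(1, ng + 1) for j in range(1, ng + 1)]
    p = lambda i, j: P[i - 1, j - 1]
    px = [sum(p(i, j) for j in range(1, ng + 1)) for i in range(1, ng + 1)]
    py = [sum(p(i, j) for i in range(1, ng + 1)) for j in range(1, ng + 1)]
    mux = sum(i * px[i - 1] for i in range(1, ng + 1))
    muy = sum(j * py[j - 1] for j in range(1, ng + 1))
    sigx = math.sqrt(sum(px[i - 1] * (i - mux) ** 2 for i in range(1, ng + 1)))
    sigy = math.sqrt(sum(py[j - 1] * (j - muy) ** 2 for j in range(1, ng + 1)))
    pdiff = [sum(p(i, j) for i, j in cells if abs(i - j) == k) for k in range(ng)]
    psum = [sum(p(i, j) for i, j in cells if i + j == k) for k in range(2, 2 * ng + 1)]

    def ent(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    hxy = ent([p(i, j) for i, j in cells])
    hxy1 = -sum(p(i, j) * math.log2(px[i - 1] * py[j - 1])
                for i, j in cells if p(i, j) > 0 and px[i - 1] * py[j - 1] > 0)
    hxy2 = ent([px[i - 1] * py[j - 1] for i, j in cells])
    hx, hy = ent(px), ent(py)
    da = sum(k * pdiff[k] for k in range(ng))
    denom = max(hx, hy)
    out = {
        "Autocorrelation": sum(p(i, j) * i * j for i, j in cells),
        "JointAverage": mux,
        "ClusterProminence": sum(p(i, j) * (i + j - mux - muy) ** 4 for i, j in cells),
        "ClusterShade": sum(p(i, j) * (i + j - mux - muy) ** 3 for i, j in cells),
        "ClusterTendency": sum(p(i, j) * (i + j - mux - muy) ** 2 for i, j in cells),
        "Contrast": sum(p(i, j) * (i - j) ** 2 for i, j in cells),
        "Correlation": ((sum(p(i, j) * i * j for i, j in cells) - mux * muy)
                        / (sigx * sigy)) if sigx > 0 and sigy > 0 else 1.0,
        "DifferenceAverage": da,
        "DifferenceEntropy": ent(pdiff),
        "DifferenceVariance": sum(pdiff[k] * (k - da) ** 2 for k in range(ng)),
        "JointEnergy": sum(p(i, j) ** 2 for i, j in cells),
        "JointEntropy": hxy,
        "Imc1": (hxy - hxy1) / denom if denom > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
        if hxy2 >= hxy else 0.0,
        "Idm": sum(p(i, j) / (1 + (i - j) ** 2) for i, j in cells),
        "Idmn": sum(p(i, j) / (1 + ((i - j) / ng) ** 2) for i, j in cells),
        "Id": sum(p(i, j) / (1 + abs(i - j)) for i, j in cells),
        "Idn": sum(p(i, j) / (1 + abs(i - j) / ng) for i, j in cells),
        "InverseVariance": sum(p(i, j) / (i - j) ** 2 for i, j in cells if i != j),
        "MaximumProbability": max(p(i, j) for i, j in cells),
        "SumAverage": sum(k * psum[k - 2] for k in range(2, 2 * ng + 1)),
        "SumEntropy": ent(psum),
        "SumSquares": sum(p(i, j) * (i - mux) ** 2 for i, j in cells),
    }
    # MCC via the same Q-matrix definition, dense loops
    if ng > 1 and all(v > 0 for v in px):
        Q = np.zeros((ng, ng))
        for i, j in cells:
            Q[i - 1, j - 1] = sum(
                p(i, k) * p(j, k) / (px[i - 1] * py[k - 1])
                for k in range(1, ng + 1) if py[k - 1] > 0)
        eig = sorted(abs(np.linalg.eigvals(Q)))
        out["MCC"] = math.sqrt(max(0.0, eig[-2].real)) if ng > 1 else 1.0
    else:
        out["MCC"] = 1.0
    return out


def _rlm_style_oracle(mat: np.ndarray, n_voxels: int, names: dict[str, str]
                      ) -> dict[str, float]:
    """Direct sums for the run/zone/dependence families; ``names`` maps the
    generic statistic to the family's feature name ('' to skip)."""
    ng, nl = mat.shape
    ns = mat.sum()
    cells = [(i, j) for i in range(1, ng + 1) for j in range(1, nl + 1)]
    p = lambda i, j: mat[i - 1, j - 1] / ns
    mui = sum(p(i, j) * i for i, j in cells)
    muj = sum(p(i, j) * j for i, j in cells)
    gen = {
        "sre": sum(p(i, j) / j ** 2 for i, j in cells),
        "lre": sum(p(i, j) * j ** 2 for i, j in cells),
        "gln": sum(sum(mat[i - 1, j - 1] for j in range(1, nl + 1)) ** 2
                   for i in range(1, ng + 1)) / ns,
        "glnn": sum(sum(p(i, j) for j in range(1, nl + 1)) ** 2
                    for i in range(1, ng + 1)),
        "rln": sum(sum(mat[i - 1, j - 1] for i in range(1, ng + 1)) ** 2
                   for j in range(1, nl + 1)) / ns,
        "rlnn": sum(sum(p(i, j) for i in range(1, ng + 1)) ** 2
                    for j in range(1, nl + 1)),
        "rp": ns / n_voxels,
        "glv": sum(p(i, j) * (i - mui) ** 2 for i, j in cells),
        "rv": sum(p(i, j) * (j - muj) ** 2 for i, j in cells),
        "rent": -sum(p(i, j) * math.log2(p(i, j)) for i, j in cells if p(i, j) > 0),
        "lgle": sum(p(i, j) / i ** 2 for i, j in cells),
        "hgle": sum(p(i, j) * i ** 2 for i, j in cells),
        "srlgle": sum(p(i, j) / (i ** 2 * j ** 2) for i, j in cells),
        "srhgle": sum(p(i, j) * i ** 2 / j ** 2 for i, j in cells),
        "lrlgle": sum(p(i, j) * j ** 2 / i ** 2 for i, j in cells),
        "lrhgle": sum(p(i, j) * i ** 2 * j ** 2 for i, j in cells),
    }
    return {feat: gen[key] for key, feat in names.items() if feat}


def glrlm_features_oracle(mat, n_voxels):
    return _rlm_style_oracle(mat, n_voxels, {
        "sre": "ShortRunEmphasis", "lre": "LongRunEmphasis",
        "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
        "rln": "RunLengthNonUniformity", "rlnn": "RunLengthNonUniformityNormalized",
        "rp": "RunPercentage", "glv": "GrayLevelVariance", "rv": "RunVariance",
        "rent": "RunEntropy", "lgle": "LowGrayLevelRunEmphasis",
        "hgle": "HighGrayLevelRunEmphasis", "srlgle": "ShortRunLowGrayLevelEmphasis",
        "srhgle": "ShortRunHighGrayLevelEmphasis", "lrlgle": "LongRunLowGrayLevelEmphasis",
        "lrhgle": "LongRunHighGrayLevelEmphasis"})


def glszm_features_oracle(mat, n_voxels):
    return _rlm_style_oracle(mat, n_voxels, {
        "sre": "SmallAreaEmphasis", "lre": "LargeAreaEmphasis",
        "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
        "rln": "SizeZoneNonUniformity", "rlnn": "SizeZoneNonUniformityNormalized",
        "rp": "ZonePercentage", "glv": "GrayLevelVariance", "rv": "ZoneVariance",
        "rent": "ZoneEntropy", "lgle": "LowGrayLevelZoneEmphasis",
        "hgle": "HighGrayLevelZoneEmphasis", "srlgle": "SmallAreaLowGrayLevelEmphasis",
        "srhgle": "SmallAreaHighGrayLevelEmphasis", "lrlgle": "LargeAreaLowGrayLevelEmphasis",
        "lrhgle": "LargeAreaHighGrayLevelEmphasis"})


def gldm_features_oracle(mat):
    return _rlm_style_oracle(mat, 1, {
        "sre": "SmallDependenceEmphasis", "lre": "LargeDependenceEmphasis",
        "gln": "GrayLevelNonUniformity", "rln": "DependenceNonUniformity",
        "rlnn": "DependenceNonUniformityNormalized", "glv": "GrayLevelVariance",
        "rv": "DependenceVariance", "rent": "DependenceEntropy",
        "lgle": "LowGrayLevelEmphasis", "hgle": "HighGrayLevelEmphasis",
        "srlgle": "SmallDependenceLowGrayLevelEmphasis",
        "srhgle": "SmallDependenceHighGrayLevelEmphasis",
        "lrlgle": "LargeDependenceLowGrayLevelEmphasis",
        "lrhgle": "LargeDependenceHighGrayLevelEmphasis"})


def first_order_oracle(values, levels, voxvol=1.0) -> dict[str, float]:
    v = sorted(float(x) for x in values)
    n = len(v)
    mean = sum(v) / n
    arr = np.array(v)
    p10, q1, med, q3, p90 = (np.percentile(arr, q) for q in (10, 25, 50, 75, 90))
    from collections import Counter
    cnt = Counter(int(l) for l in levels)
    probs = [c / n for c in cnt.values()]
    robust = [x for x in v if p10 <= x <= p90]
    var = sum((x - mean) ** 2 for x in v) / n
    sd = math.sqrt(var)
    out = {
        "Energy": sum(x ** 2 for x in v),
        "TotalEnergy": voxvol * sum(x ** 2 for x in v),
        "Entropy": -sum(p * math.log2(p) for p in probs if p > 0),
        "Minimum": v[0], "Maximum": v[-1],
        "10Percentile": float(p10), "90Percentile": float(p90),
        "Mean": mean, "Median": float(med),
        "InterquartileRange": float(q3 - q1), "Range": v[-1] - v[0],
        "MeanAbsoluteDeviation": sum(abs(x - mean) for x in v) / n,
        "RobustMeanAbsoluteDeviation":
            sum(abs(x - sum(robust) / len(robust)) for x in robust) / len(robust)
            if robust else 0.0,
        "RootMeanSquared": math.sqrt(sum(x ** 2 for x in v) / n),
        "Variance": var,
        "Uniformity": sum(p ** 2 for p in probs),
    }
    if sd > 0:
        out["Skewness"] = (sum((x - mean) ** 3 for x in v) / n) / sd ** 3
        out["Kurtosis"] = (sum((x - mean) ** 4 for x in v) / n) / sd ** 4
    else:
        out["Skewness"] = 0.0
        out["Kurtosis"] = 0.0
    return out


# --- statistics oracles ----------------------------------------------------

def auc_pair_counting(scores, labels) -> float:
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def km_hand(records) -> list[tuple[float, float]]:
    """(time, survival) after each distinct observed time, product-limit with
    simultaneous-death ties."""
    recs = sorted(records)  # (time, event)
    out = []
    s = 1.0
    i = 0
    n = len(recs)
    while i < n:
        t = recs[i][0]
        d = sum(1 for tt, ee in recs if tt == t and ee == 1)
        at_risk = sum(1 for tt, _ in recs if tt >= t)
        if d > 0:
            s *= 1 - d / at_risk
        out.append((t, s))
        while i < n and recs[i][0] == t:
            i += 1
    return out


def hypergeom_tail(k, N, K, n) -> float:
    """P(X >= k) for drawing n from N with K successes, by enumeration."""
    total = math.comb(N, n)
    return sum(math.comb(K, x) * math.comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / total


def logrank_two_group_hand(g1, g2) -> float:
    """Two-group log-rank chi-square by direct O-E/V accumulation."""
    events = sorted({t for t, e in g1 + g2 if e == 1})
    O = E = V = 0.0
    for t in events:
        n1 = sum(1 for tt, _ in g1 if tt >= t)
        n2 = sum(1 for tt, _ in g2 if tt >= t)
        d1 = sum(1 for tt, ee in g1 if tt == t and ee == 1)
        d2 = sum(1 for tt, ee in g2 if tt == t and ee == 1)
        n, d = n1 + n2, d1 + d2
        if n <= 1 or d == 0:
            continue
        O += d1
        E += d * n1 / n
        V += d * (n - d) * n1 * n2 / (n ** 2 * (n - 1))
    return (O - E) ** 2 / V
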