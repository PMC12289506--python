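"""Gray-level texture matrices and features with a 2.5-D merge strategy.

Five families are computed from a 16-level discretized volume (level 0
marks voxels outside the retained ROI): co-occurrence (GLCM), run length
(GLRLM), size zone (GLSZM), dependence (GLDM) and neighbouring gray tone
difference (NGTDM). Matrices are built per axial slice — GLCM and GLRLM
over the four in-plane directions at distance 1, the zone/dependence/
neighbourhood families with 8-connected in-plane neighbourhoods — and
MERGED by summation across slices (and directions) before any feature is
computed, i.e. one feature value per family statistic. Feature formulas
follow the IBSI definitions; entropies are in bits.

Feature counts: 24 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM (75 total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

N_GRAY = 16

_GLCM_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))
_EIGHT_NEIGHBORS = (
    (0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1),
)


def _shift2d(a: np.ndarray, di: int, dj: int) -> np.ndarray:
    """Shift with zero fill (level 0 = outside ROI)."""
    out = np.zeros_like(a)
    H, W = a.shape
    si = slice(max(di, 0), H + min(di, 0))
    sj = slice(max(dj, 0), W + min(dj, 0))
    ti = slice(max(-di, 0), H + min(-di, 0))
    tj = slice(max(-dj, 0), W + min(-dj, 0))
    out[ti, tj] = a[si, sj]
    return out


def glcm_slice(lv: np.ndarray, n_gray: int = N_GRAY, offsets=_GLCM_OFFSETS) -> np.ndarray:
    """Symmetrized distance-1 co-occurrence counts, merged over ``offsets``."""
    m = np.zeros((n_gray, n_gray))
    for di, dj in offsets:
        b = _shift2d(lv, di, dj)
        valid = (lv > 0) & (b > 0)
        np.add.at(m, (lv[valid] - 1, b[valid] - 1), 1.0)
    return m + m.T


def _runs_from_rows(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(levels, lengths) of maximal constant runs within each row; 0 ignored."""
    flat = np.concatenate([arr, np.zeros((arr.shape[0], 1), dtype=arr.dtype)], axis=1).ravel()
    change = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [flat.size]])
    vals = flat[starts]
    keep = vals > 0
    return vals[keep], (ends - starts)[keep]


def glrlm_slice(lv: np.ndarray, n_gray: int = N_GRAY) -> np.ndarray:
    """Run-length counts over the 4 in-plane directions, merged.

    Returns a (n_gray, max_run_length) matrix for this slice.
    """
    H, W = lv.shape
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    s45 = np.zeros((H, W + H - 1), dtype=lv.dtype)
    s45[rows, cols - rows + H - 1] = lv
    s135 = np.zeros((H, W + H - 1), dtype=lv.dtype)
    s135[rows, cols + rows] = lv
    maxlen = max(H, W)
    m = np.zeros((n_gray, maxlen))
    for lines in (lv, lv.T, s45.T, s135.T):
        vals, lens = _runs_from_rows(np.ascontiguousarray(lines))
        np.add.at(m, (vals - 1, lens - 1), 1.0)
    return m


def glszm_slice(lv: np.ndarray, n_gray: int = N_GRAY) -> np.ndarray:
    """Zone-size counts (8-connected in-plane zones) for this slice."""
    sizes: list[tuple[int, int]] = []
    maxsize = 1
    for g in np.unique(lv[lv > 0]):
        lbl, nz = measure.label(lv == g, connectivity=2, return_num=True)
        if nz:
            counts = np.bincount(lbl.ravel())[1:]
            for s in counts:
                sizes.append((int(g), int(s)))
                maxsize = max(maxsize, int(s))
    m = np.zeros((n_gray, maxsize))
    for g, s in sizes:
        m[g - 1, s - 1] += 1.0
    return m


def gldm_slice(lv: np.ndarray, n_gray: int = N_GRAY) -> np.ndarray:
    """Dependence counts: (level, 1 + #equal 8-neighbours) per ROI pixel."""
    dep = np.zeros(lv.shape, dtype=np.int64)
    for di, dj in _EIGHT_NEIGHBORS:
        b = _shift2d(lv, di, dj)
        dep += ((b == lv) & (b > 0)).astype(np.int64)
    m = np.zeros((n_gray, 9))
    valid = lv > 0
    np.add.at(m, (lv[valid] - 1, dep[valid]), 1.0)
    return m


def ngtdm_slice(lv: np.ndarray, n_gray: int = N_GRAY) -> tuple[np.ndarray, np.ndarray]:
    """(n_i, s_i): counts and summed absolute differences to the
    neighbourhood mean, per gray level, for pixels with >= 1 ROI neighbour."""
    vsum = np.zeros(lv.shape, dtype=float)
    vcnt = np.zeros(lv.shape, dtype=np.int64)
    for di, dj in _EIGHT_NEIGHBORS:
        b = _shift2d(lv, di, dj)
        vsum += b
        vcnt += (b > 0).astype(np.int64)
    valid = (lv > 0) & (vcnt > 0)
    diff = np.abs(lv[valid] - vsum[valid] / vcnt[valid])
    g = lv[valid] - 1
    n_i = np.bincount(g, minlength=n_gray).astype(float)
    s_i = np.bincount(g, weights=diff, minlength=n_gray)
    return n_i, s_i


def _pad_to(m: np.ndarray, width: int) -> np.ndarray:
    if m.shape[1] == width:
        return m
    out = np.zeros((m.shape[0], width))
    out[:, : m.shape[1]] = m
    return out


@dataclass
class TextureMatrixSet:
    """Per-slice raw matrices and their 2.5-D merged aggregates."""

    glcm: np.ndarray
    glrlm: np.ndarray
    glszm: np.ndarray
    gldm: np.ndarray
    ngtdm_n: np.ndarray
    ngtdm_s: np.ndarray
    n_voxels: int
    n_gray: int = N_GRAY
    per_slice: dict[str, list] = field(default_factory=dict)


def texture_matrices(levels: np.ndarray, n_gray: int = N_GRAY, keep_slices: bool = False) -> TextureMatrixSet:
    """Build merged texture matrices from a discretized label volume.

    ``levels`` is 3-D with values 0 (outside retained ROI) or 1..n_gray;
    axial slices are taken along the last axis. Slices without ROI pixels
    are skipped; an empty ROI raises.
    """
    levels = np.asarray(levels)
    slices = [levels[:, :, k] for k in range(levels.shape[2]) if (levels[:, :, k] > 0).any()]
    if not slices:
        raise ValueError("ROI is empty: no slice contains retained voxels")
    per: dict[str, list] = {k: [] for k in ("glcm", "glrlm", "glszm", "gldm", "ngtdm")}
    for sl in slices:
        per["glcm"].append(glcm_slice(sl, n_gray))
        per["glrlm"].append(glrlm_slice(sl, n_gray))
        per["glszm"].append(glszm_slice(sl, n_gray))
        per["gldm"].append(gldm_slice(sl, n_gray))
        per["ngtdm"].append(ngtdm_slice(sl, n_gray))
    wl = max(m.shape[1] for m in per["glrlm"])
    ws = max(m.shape[1] for m in per["glszm"])
    ts = TextureMatrixSet(
        glcm=sum(per["glcm"]),
        glrlm=sum(_pad_to(m, wl) for m in per["glrlm"]),
        glszm=sum(_pad_to(m, ws) for m in per["glszm"]),
        gldm=sum(per["gldm"]),
        ngtdm_n=sum(n for n, _ in per["ngtdm"]),
        ngtdm_s=sum(s for _, s in per["ngtdm"]),
        n_voxels=int((levels > 0).sum()),
        n_gray=n_gray,
        per_slice=per if keep_slices else {},
    )
    return ts


# ---------------------------------------------------------------------------
# Feature formulas
# ---------------------------------------------------------------------------


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features(counts: np.ndarray) -> dict[str, float]:
    Ng = counts.shape[0]
    total = counts.sum()
    if total == 0:
        raise ValueError("empty GLCM")
    p = counts / total
    i = np.arange(1, Ng + 1)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((I * p).sum())  # == mu_y by symmetry
    sigma2 = float(((I - mu) ** 2 * p).sum())
    sigma = np.sqrt(sigma2)

    k_diff = np.arange(Ng)
    p_diff = np.array([p[np.abs(I - J) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * Ng + 1)
    p_sum = np.array([p[(I + J) == k].sum() for k in k_sum])

    da = float((k_diff * p_diff).sum())
    hx = float(-_xlog2(px).sum())
    hxy = float(-_xlog2(p).sum())
    pxpy = np.outer(px, px)
    mask = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[mask] * np.log2(pxpy[mask])).sum())
    hxy2 = float(-_xlog2(pxpy).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))) if hxy2 >= hxy else 0.0

    nz = px > 0
    if nz.sum() > 1:
        # Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) px(k)); MCC = sqrt(second eigenvalue)
        pk = px[nz]
        q = np.einsum("ik,jk->ij", p[np.ix_(nz, nz)] / pk[:, None], p[np.ix_(nz, nz)] / pk[None, :])
        ev = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, ev[-2]))) if ev.size > 1 else 1.0
    else:
        mcc = 1.0

    off = I != J
    corr = float(((I * J * p).sum() - mu * mu) / sigma2) if sigma2 > 0 else 1.0
    return {
        "Autocorrelation": float((I * J * p).sum()),
        "JointAverage": mu,
        "ClusterProminence": float(((I + J - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float(((I + J - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float(((I + J - 2 * mu) ** 2 * p).sum()),
        "Contrast": float(((I - J) ** 2 * p).sum()),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(-_xlog2(p_diff).sum()),
        "DifferenceVariance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "Id": float((p / (1.0 + np.abs(I - J))).sum()),
        "Idm": float((p / (1.0 + (I - J) ** 2)).sum()),
        "Idmn": float((p / (1.0 + ((I - J) / Ng) ** 2)).sum()),
        "Idn": float((p / (1.0 + np.abs(I - J) / Ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": float((p[off] / (I - J)[off] ** 2).sum()),
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": float((k_sum * p_sum).sum()),
        "SumEntropy": float(-_xlog2(p_sum).sum()),
        "SumSquares": sigma2,
    }


def _rl_family(counts: np.ndarray, n_pixels: int, prefix: str, runs_word: str, n_directions: int = 1) -> dict[str, float]:
    """Shared formulas of the run-length and size-zone families."""
    Nr = counts.sum()
    if Nr == 0:
        raise ValueError(f"empty {prefix} matrix")
    Ng, Nl = counts.shape
    i = np.arange(1, Ng + 1)[:, None]
    l = np.arange(1, Nl + 1)[None, :]
    p = counts / Nr
    mu_g = float((i * p).sum())
    mu_l = float((l * p).sum())
    return {
        f"Short{runs_word}Emphasis": float((counts / l**2).sum() / Nr),
        f"Long{runs_word}Emphasis": float((counts * l**2).sum() / Nr),
        "GrayLevelNonUniformity": float((counts.sum(axis=1) ** 2).sum() / Nr),
        "GrayLevelNonUniformityNormalized": float((counts.sum(axis=1) ** 2).sum() / Nr**2),
        f"{runs_word}LengthNonUniformity" if runs_word == "Run" else "SizeZoneNonUniformity": float(
            (counts.sum(axis=0) ** 2).sum() / Nr
        ),
        f"{runs_word}LengthNonUniformityNormalized"
        if runs_word == "Run"
        else "SizeZoneNonUniformityNormalized": float((counts.sum(axis=0) ** 2).sum() / Nr**2),
        f"{runs_word}Percentage" if runs_word == "Run" else "ZonePercentage": float(
            Nr / (n_pixels * n_directions)
        ),
        "GrayLevelVariance": float(((i - mu_g) ** 2 * p).sum()),
        f"{runs_word}Variance" if runs_word == "Run" else "ZoneVariance": float(
            ((l - mu_l) ** 2 * p).sum()
        ),
        f"{runs_word}Entropy" if runs_word == "Run" else "ZoneEntropy": float(-_xlog2(p).sum()),
        f"LowGrayLevel{runs_word}Emphasis": float((counts / i**2).sum() / Nr),
        f"HighGrayLevel{runs_word}Emphasis": float((counts * i**2).sum() / Nr),
        f"Short{runs_word}LowGrayLevelEmphasis": float((counts / (i**2 * l**2)).sum() / Nr),
        f"Short{runs_word}HighGrayLevelEmphasis": float((counts * i**2 / l**2).sum() / Nr),
        f"Long{runs_word}LowGrayLevelEmphasis": float((counts * l**2 / i**2).sum() / Nr),
        f"Long{runs_word}HighGrayLevelEmphasis": float((counts * i**2 * l**2).sum() / Nr),
    }


def glrlm_features(counts: np.ndarray, n_pixels: int) -> dict[str, float]:
    return _rl_family(counts, n_pixels, "GLRLM", "Run", n_directions=len(_GLCM_OFFSETS))


def glszm_features(counts: np.ndarray, n_pixels: int) -> dict[str, float]:
    out = _rl_family(counts, n_pixels, "GLSZM", "Zone", n_directions=1)
    # Conventional GLSZM names use "Area" for the size emphases.
    rename = {
        "ShortZoneEmphasis": "SmallAreaEmphasis",
        "LongZoneEmphasis": "LargeAreaEmphasis",
        "LowGrayLevelZoneEmphasis": "LowGrayLevelZoneEmphasis",
        "HighGrayLevelZoneEmphasis": "HighGrayLevelZoneEmphasis",
        "ShortZoneLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
        "ShortZoneHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
        "LongZoneLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
        "LongZoneHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
    }
    return {rename.get(k, k): v for k, v in out.items()}


def gldm_features(counts: np.ndarray) -> dict[str, float]:
    Nz = counts.sum()
    if Nz == 0:
        raise ValueError("empty GLDM")
    Ng, Nd = counts.shape
    i = np.arange(1, Ng + 1)[:, None]
    j = np.arange(1, Nd + 1)[None, :]
    p = counts / Nz
    mu_g = float((i * p).sum())
    mu_d = float((j * p).sum())
    return {
        "SmallDependenceEmphasis": float((counts / j**2).sum() / Nz),
        "LargeDependenceEmphasis": float((counts * j**2).sum() / Nz),
        "GrayLevelNonUniformity": float((counts.sum(axis=1) ** 2).sum() / Nz),
        "DependenceNonUniformity": float((counts.sum(axis=0) ** 2).sum() / Nz),
        "DependenceNonUniformityNormalized": float((counts.sum(axis=0) ** 2).sum() / Nz**2),
        "GrayLevelVariance": float(((i - mu_g) ** 2 * p).sum()),
        "DependenceVariance": float(((j - mu_d) ** 2 * p).sum()),
        "DependenceEntropy": float(-_xlog2(p).sum()),
        "LowGrayLevelEmphasis": float((counts / i**2).sum() / Nz),
        "HighGrayLevelEmphasis": float((counts * i**2).sum() / Nz),
        "SmallDependenceLowGrayLevelEmphasis": float((counts / (i**2 * j**2)).sum() / Nz),
        "SmallDependenceHighGrayLevelEmphasis": float((counts * i**2 / j**2).sum() / Nz),
        "LargeDependenceLowGrayLevelEmphasis": float((counts * j**2 / i**2).sum() / Nz),
        "LargeDependenceHighGrayLevelEmphasis": float((counts * i**2 * j**2).sum() / Nz),
    }


_COARSENESS_CAP = 1e6


def ngtdm_features(n_i: np.ndarray, s_i: np.ndarray) -> dict[str, float]:
    N = n_i.sum()
    if N == 0:
        raise ValueError("empty NGTDM")
    p = n_i / N
    levels = np.arange(1, n_i.size + 1, dtype=float)
    nz = p > 0
    Ngp = int(nz.sum())
    ps, lv, si = p[nz], levels[nz], s_i[nz]

    denom = float((ps * si).sum())
    coarseness = 1.0 / denom if denom > 0 else _COARSENESS_CAP

    if Ngp > 1:
        dl = lv[:, None] - lv[None, :]
        contrast = float((ps[:, None] * ps[None, :] * dl**2).sum() / (Ngp * (Ngp - 1)) * si.sum() / N)
        bus_den = float(np.abs(lv[:, None] * ps[:, None] - lv[None, :] * ps[None, :]).sum())
        busyness = float((ps * si).sum() / bus_den) if bus_den > 0 else 0.0
        complexity = float(
            (np.abs(dl) * (ps[:, None] * si[:, None] + ps[None, :] * si[None, :])
             / (ps[:, None] + ps[None, :])).sum() / N
        )
        strength_num = float(((ps[:, None] + ps[None, :]) * dl**2).sum())
        strength = strength_num / si.sum() if si.sum() > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def texture_features(levels: np.ndarray, n_gray: int = N_GRAY) -> dict[str, float]:
    """All 75 texture features of a discretized ROI volume, 2.5-D merged."""
    ts = texture_matrices(levels, n_gray)
    out: dict[str, float] = {}
    for fam, feats in (
        ("glcm", glcm_features(ts.glcm)),
        ("glrlm", glrlm_features(ts.glrlm, ts.n_voxels)),
        ("glszm", glszm_features(ts.glszm, ts.n_voxels)),
        ("gldm", gldm_features(ts.gldm)),
        ("ngtdm", ngtdm_features(ts.ngtdm_n, ts.ngtdm_s)),
    ):
        for k, v in feats.items():
            out[f"{fam}_{k}"] = v
    return out
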