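"""First-order (histogram) radiomics features, IBSI definitions.

Nineteen statistics are implemented; the default feature set exposes 18
(standard deviation is omitted by default because it is the square root
of variance, matching common radiomics-tool behaviour) and can be
extended with ``include_std=True``.

Conventions: variance uses the population estimator (ddof=0); kurtosis
is non-excess (Pearson; a normal distribution scores 3); entropy and
uniformity are computed on a 16-level equal-width discretization of the
input values, entropy in bits (log base 2).
"""

from __future__ import annotations

import warnings

import numpy as np

from .preprocess import discretize_fixed_bins

FIRST_ORDER_NAMES = (
    "Mean",
    "Median",
    "Minimum",
    "Maximum",
    "10Percentile",
    "90Percentile",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Uniformity",
    "Variance",
    "Skewness",
    "Kurtosis",
)


def first_order(
    intensities: np.ndarray,
    voxel_volume: float = 1.0,
    n_bins: int = 16,
    include_std: bool = False,
) -> dict[str, float]:
    """Compute first-order statistics of a voxel intensity sample.

    Parameters
    ----------
    intensities
        1-D array of (at least two) voxel values.
    voxel_volume
        mm^3 per voxel; only TotalEnergy depends on it.
    n_bins
        Discretization levels for Entropy/Uniformity.
    include_std
        Append ``StandardDeviation`` to the returned map.
    """
    x = np.asarray(intensities, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"first-order features need >= 2 voxels, got {x.size}")
    n = x.size
    mean = x.mean()
    var = x.var()  # population
    sd = np.sqrt(var)
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    energy = float(np.sum(x**2))

    if var == 0:
        warnings.warn("zero-variance input: skewness/kurtosis set to 0", stacklevel=2)
        skew = kurt = 0.0
        entropy, uniformity = 0.0, 1.0
    else:
        skew = float(np.mean((x - mean) ** 3) / sd**3)
        kurt = float(np.mean((x - mean) ** 4) / var**2)  # non-excess
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            levels = discretize_fixed_bins(x, n_bins)
        p = np.bincount(levels, minlength=n_bins + 1)[1:] / n
        nz = p[p > 0]
        entropy = float(-np.sum(nz * np.log2(nz)))
        uniformity = float(np.sum(p**2))

    out = {
        "Mean": float(mean),
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(np.mean(np.abs(robust - robust.mean())))
        if robust.size
        else 0.0,
        "RootMeanSquared": float(np.sqrt(energy / n)),
        "Energy": energy,
        "TotalEnergy": energy * float(voxel_volume),
        "Entropy": entropy,
        "Uniformity": uniformity,
        "Variance": float(var),
        "Skewness": skew,
        "Kurtosis": kurt,
    }
    if include_std:
        out["StandardDeviation"] = float(sd)
    return out


def volume_features(n_voxels: int, voxel_volume: float, n_total: int | None = None) -> dict[str, float]:
    """Volume (mm^3) and, for habitat scopes, the volume ratio.

    ``n_total`` is the whole-tumor retained voxel count; when given,
    ``VolumeRatio = n_voxels / n_total``.
    """
    if n_voxels < 0:
        raise ValueError("negative voxel count")
    out = {"Volume": float(n_voxels) * float(voxel_volume)}
    if n_total is not None:
        out["VolumeRatio"] = n_voxels / n_total if n_total else 0.0
    return out
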