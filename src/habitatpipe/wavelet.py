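"""Wavelet-filtered first-order features (coif1, stationary transform).

A single-level 3-D stationary (undecimated) wavelet decomposition with
the coif1 filter yields 8 subbands (LLL..HHH, letters ordered by axis);
first-order statistics are then computed on each subband restricted to
the retained ROI voxels. The transform is undecimated, so subband voxels
stay in register with the input grid. Subband values are unnormalized
(the lowpass filter sums to sqrt(2) per axis, so the LLL local mean is
~2^(3/2) times the image mean).
"""

from __future__ import annotations

import numpy as np
import pywt

from .firstorder import first_order

WAVELET = "coif1"
#: Lowpass gain per axis of the unnormalized SWT.
LOWPASS_GAIN = float(np.sum(pywt.Wavelet(WAVELET).dec_lo))

_SUBBAND_ORDER = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def swt_subbands(volume: np.ndarray) -> dict[str, np.ndarray]:
    """Level-1 stationary coif1 decomposition -> {'LLL': array, ...}.

    Odd axis lengths are reflect-padded to even before the transform and
    the pad is cropped afterwards, so each subband matches the input
    shape.
    """
    vol = np.asarray(volume, dtype=float)
    pad = [(0, s % 2) for s in vol.shape]
    padded = np.pad(vol, pad, mode="reflect") if any(p[1] for p in pad) else vol
    coeffs = pywt.swtn(padded, WAVELET, level=1)[0]
    out = {}
    for key, arr in coeffs.items():
        name = key.upper().replace("A", "L").replace("D", "H")
        out[name] = arr[: vol.shape[0], : vol.shape[1], : vol.shape[2]]
    return {name: out[name] for name in _SUBBAND_ORDER}


def wavelet_first_order(
    volume: np.ndarray,
    roi_indices: np.ndarray,
    voxel_volume: float = 1.0,
    margin: int = 4,
) -> dict[str, float]:
    """First-order features of each coif1 subband over the ROI.

    The decomposition runs on the ROI bounding box padded by ``margin``
    voxels (reflect-padded to at least 8 per axis) rather than the whole
    grid, which is equivalent away from image borders and much cheaper.
    Feature names are ``wavelet-<subband>_<statistic>``.
    """
    vol = np.asarray(volume, dtype=float)
    ijk = np.unravel_index(np.asarray(roi_indices), vol.shape)
    if ijk[0].size == 0:
        raise ValueError("empty ROI for wavelet features")
    lo = [max(0, int(a.min()) - margin) for a in ijk]
    hi = [min(s, int(a.max()) + margin + 1) for a, s in zip(ijk, vol.shape)]
    box = vol[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    need = [max(0, 8 - s) for s in box.shape]
    if any(need):
        box = np.pad(box, [(0, n) for n in need], mode="reflect")
    local = tuple(a - l for a, l in zip(ijk, lo))
    out: dict[str, float] = {}
    for name, band in swt_subbands(box).items():
        vals = band[local]
        feats = first_order(vals, voxel_volume=voxel_volume)
        for stat, v in feats.items():
            out[f"wavelet-{name}_{stat}"] = v
    return out
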