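"""Intensity preprocessing for tumor ROIs.

The fixed stage order is: Z-score normalization (T2 only, whole image)
-> 3-sigma re-segmentation of the tumor ROI (jointly over both
modalities) -> fixed-bin-count discretization (16 bins over the retained
ROI range). Each stage records provenance on the :class:`ROIVoxelSet`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume import ImageVolume

log = logging.getLogger(__name__)

N_BINS_DEFAULT = 16


def zscore_normalize(volume: ImageVolume, mask_scope=None) -> ImageVolume:
    """Z-score an image: subtract the mean, divide by the population SD.

    ``mask_scope`` is ``None`` (whole image) or a boolean array selecting
    the voxels over which mean/SD are computed; the affine transform is
    then applied to the whole volume either way.
    """
    vals = volume.values.astype(float)
    scope = vals if mask_scope is None else vals[np.asarray(mask_scope, bool)]
    if scope.size < 2:
        raise ValueError("z-score scope needs at least 2 voxels")
    mu = float(scope.mean())
    sd = float(scope.std())  # population SD (ddof=0)
    if sd == 0:
        raise ValueError("z-score scope has zero variance")
    return ImageVolume(values=(vals - mu) / sd, spacing=volume.spacing, affine=volume.affine.copy())


@dataclass
class ROIVoxelSet:
    """Retained tumor voxels after re-segmentation, with provenance.

    ``indices`` are flat (raveled, C-order) indices into the case grid of
    the voxels retained inside the tumor; ``intensities`` maps modality
    name -> per-retained-voxel values; ``excluded_by_3sigma`` flags, per
    *original* ROI voxel (in ``original_indices`` order), whether the
    3-sigma rule removed it.
    """

    indices: np.ndarray
    intensities: dict[str, np.ndarray]
    original_indices: np.ndarray
    excluded_by_3sigma: np.ndarray
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    discretized: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return int(self.indices.size)

    def coords(self) -> tuple[np.ndarray, ...]:
        """(i, j, k) arrays of the retained voxels."""
        return np.unravel_index(self.indices, self.shape)

    def label_volume(self, labels: np.ndarray) -> np.ndarray:
        """Scatter per-retained-voxel labels back into a full grid (0 = background)."""
        out = np.zeros(self.shape, dtype=np.int16)
        out.ravel()[self.indices] = labels
        return out


def resegment_3sigma(
    intensities: dict[str, np.ndarray],
    indices: np.ndarray,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ROIVoxelSet:
    """Apply the 3-sigma re-segmentation rule within the tumor ROI.

    For every modality, mean and SD are computed over the *original* ROI;
    a voxel is retained only if its intensity lies in [mu - 3 sigma,
    mu + 3 sigma] in every modality. With SD 0 the interval degenerates
    to {mu} and nothing is excluded.
    """
    indices = np.asarray(indices)
    n = indices.size
    if n < 10:
        raise ValueError(f"ROI too small for re-segmentation ({n} voxels)")
    keep = np.ones(n, dtype=bool)
    for name, x in intensities.items():
        x = np.asarray(x, dtype=float)
        if x.size != n:
            raise ValueError(f"modality {name!r} has {x.size} values for {n} ROI voxels")
        mu, sd = float(x.mean()), float(x.std())
        keep &= (x >= mu - 3 * sd) & (x <= mu + 3 * sd)
    if not keep.any():
        raise ValueError("3-sigma re-segmentation excluded every ROI voxel")
    return ROIVoxelSet(
        indices=indices[keep],
        intensities={k: np.asarray(v, float)[keep] for k, v in intensities.items()},
        original_indices=indices,
        excluded_by_3sigma=~keep,
        shape=shape,
        spacing=spacing,
    )


def roi_from_case(t2: ImageVolume, adc: ImageVolume, mask: ImageVolume) -> ROIVoxelSet:
    """Build the retained ROI voxel set for a case (normalize + 3-sigma).

    T2 is z-scored over the whole image first (ADC is already quantitative
    and stays in native scale); then both channels pass through the joint
    3-sigma rule over the mask foreground.
    """
    fg = mask.values.astype(bool)
    idx = np.flatnonzero(fg.ravel())
    t2n = zscore_normalize(t2)
    return resegment_3sigma(
        {"t2": t2n.values.ravel()[idx], "adc": adc.values.astype(float).ravel()[idx]},
        idx,
        t2.shape,
        spacing=t2.spacing,
    )


def discretize_fixed_bins(intensities: np.ndarray, n_bins: int = N_BINS_DEFAULT) -> np.ndarray:
    """Discretize intensities into ``n_bins`` equal-width bins -> levels 1..n_bins.

    Bin edges are uniform over [min, max] of the input. Bins are
    half-open [lo, hi) with the last bin closed, so a value exactly on an
    interior edge goes to the higher bin and the maximum maps to level
    ``n_bins``. A constant input collapses to level 1 with a warning.
    """
    x = np.asarray(intensities, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        warnings.warn("constant intensities: all voxels assigned bin 1", stacklevel=2)
        return np.ones(x.shape, dtype=np.int64)
    levels = np.floor((x - lo) / (hi - lo) * n_bins).astype(np.int64) + 1
    return np.clip(levels, 1, n_bins)
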