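"""3-D image volumes, NIfTI round-tripping, and grid resampling.

An :class:`ImageVolume` is the in-memory raster for one modality of one
patient: a scalar array plus the voxel spacing (mm) and a NIfTI affine.
All habitat-pipeline stages operate on these; NIfTI-1 (.nii/.nii.gz) is
the only on-disk volume format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


def _affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    """RAS affine with the given voxel spacing and origin at zero."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class ImageVolume:
    """A 3-D scalar grid with voxel spacing in mm and an affine.

    Parameters
    ----------
    values
        3-D float array of intensities (or integer labels for masks).
    spacing
        Voxel size per axis in mm, strictly positive.
    affine
        4x4 voxel-to-world matrix; defaults to a diagonal RAS affine
        built from ``spacing``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _affine_from_spacing(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ImageVolume") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def read_volume(path) -> ImageVolume:
    """Read a NIfTI volume; spacing is taken from the header zooms."""
    img = nib.load(str(path))
    values = np.asanyarray(img.dataobj).astype(np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(values=values, spacing=spacing, affine=np.asarray(img.affine))


def write_volume(volume: ImageVolume, path) -> None:
    """Write a volume as NIfTI-1, float32 for intensities, uint8 for masks."""
    vals = volume.values
    if vals.dtype.kind in "ui" or set(np.unique(vals)) <= {0.0, 1.0}:
        data = vals.astype(np.uint8) if _is_binary(vals) else vals.astype(np.int16)
    else:
        data = vals.astype(np.float32)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def _is_binary(values: np.ndarray) -> bool:
    u = np.unique(values)
    return u.size <= 2 and set(u.tolist()) <= {0, 1}


def validate_mask(mask: ImageVolume) -> ImageVolume:
    """Check a mask is strictly {0, 1}; returns it with uint8 values."""
    u = np.unique(mask.values)
    if not set(u.tolist()) <= {0, 1}:
        raise ValueError(f"mask must be binary {{0,1}}, found values {u[:10]}")
    mask.values = mask.values.astype(np.uint8)
    return mask


def resample_to(volume: ImageVolume, reference: ImageVolume, kind: str = "linear") -> ImageVolume:
    """Resample ``volume`` onto the grid of ``reference``.

    ``kind`` is ``"linear"`` for intensities and ``"nearest"`` for masks
    and label maps. Resampling is explicit plumbing: nothing in the
    pipeline calls it implicitly.
    """
    if kind not in ("linear", "nearest"):
        raise ValueError(f"unknown resampling kind {kind!r}")
    order = 1 if kind == "linear" else 0
    # Map reference voxel centers into source voxel coordinates.
    zoom = [rs / vs for rs, vs in zip(reference.spacing, volume.spacing)]
    idx = np.indices(reference.shape, dtype=float)
    coords = [idx[a] * zoom[a] for a in range(3)]
    out = ndimage.map_coordinates(
        volume.values.astype(float), coords, order=order, mode="nearest"
    )
    return ImageVolume(values=out, spacing=reference.spacing, affine=reference.affine.copy())


def check_case_grids(t2: ImageVolume, adc: ImageVolume, mask: ImageVolume) -> None:
    """Raise if the three rasters of a case do not share one grid."""
    if not (t2.same_grid(adc) and t2.same_grid(mask)):
        raise ValueError(
            "grid mismatch: t2 %s %s, adc %s %s, mask %s %s (use resample_to)"
            % (t2.shape, t2.spacing, adc.shape, adc.spacing, mask.shape, mask.spacing)
        )
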