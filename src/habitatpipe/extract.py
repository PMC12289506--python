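"""Per-case radiomics feature extraction (whole tumor).

Feature names encode provenance as
``{modality}_{filter}_{family}_{statistic}``, e.g.
``t2_original_firstorder_Mean``, ``adc_original_glcm_Contrast``,
``t2_wavelet-LHH_firstorder_Skewness``. Per modality the default set is
18 first-order + 1 volume + 75 texture + 144 wavelet first-order = 238
features; the realized composition is recorded in the feature manifest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .firstorder import first_order, volume_features
from .phantom import Cohort, PatientCase
from .preprocess import ROIVoxelSet, discretize_fixed_bins, roi_from_case, zscore_normalize
from .texture import texture_features
from .volume import ImageVolume, check_case_grids
from .wavelet import wavelet_first_order

MODALITIES = ("t2", "adc")


def preprocess_case(case: PatientCase) -> tuple[dict[str, ImageVolume], ROIVoxelSet]:
    """Normalize (T2 only), re-segment, and return full volumes + ROI set."""
    check_case_grids(case.t2, case.adc, case.mask)
    roi = roi_from_case(case.t2, case.adc, case.mask)
    volumes = {"t2": zscore_normalize(case.t2), "adc": case.adc}
    return volumes, roi


def extract_case_features(case: PatientCase, include_texture: bool = True, include_wavelet: bool = True) -> dict[str, float]:
    """Whole-tumor radiomics feature vector for one case."""
    volumes, roi = preprocess_case(case)
    vv = float(np.prod(roi.spacing))
    out: dict[str, float] = {}
    for m in MODALITIES:
        x = roi.intensities[m]
        for stat, v in first_order(x, voxel_volume=vv).items():
            out[f"{m}_original_firstorder_{stat}"] = v
        out[f"{m}_original_shape_Volume"] = volume_features(roi.n_voxels, vv)["Volume"]
        if include_texture:
            levels = roi.label_volume(discretize_fixed_bins(x))
            roi.discretized[m] = levels.ravel()[roi.indices]
            for name, v in texture_features(levels).items():
                out[f"{m}_original_{name}"] = v
        if include_wavelet:
            for name, v in wavelet_first_order(volumes[m].values, roi.indices, voxel_volume=vv).items():
                band, stat = name.split("_", 1)
                out[f"{m}_{band}_firstorder_{stat}"] = v
    return out


def extract_cohort_features(cohort: Cohort, **kwargs) -> pd.DataFrame:
    """Patients x features table for a cohort (deterministic ordering)."""
    rows = {c.id: extract_case_features(c, **kwargs) for c in cohort.cases}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df


def feature_manifest(columns) -> dict:
    """Summarize a feature table's composition by modality/filter/family."""
    comp: dict[str, int] = {}
    for name in columns:
        modality, filt, family = name.split("_")[:3]
        prefix = f"{modality}|{filt}|{family}"
        comp[prefix] = comp.get(prefix, 0) + 1
    return {"n_features": len(list(columns)), "composition": comp}
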