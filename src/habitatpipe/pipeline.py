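"""End-to-end orchestration: simulate -> preprocess -> features ->
habitats -> fit -> evaluate.

Every protocol constant (16 bins, ICC 0.75, Pearson 0.9, 7:3
stratified split, 10 CV folds, K range 2..6) surfaces as a
:class:`PipelineConfig` default. A single pipeline seed expands
deterministically to every stage; rerunning an identical config yields
byte-identical artifacts. Inter-rater feature stability is emulated by
re-extracting features on slightly perturbed masks (random one-voxel
erosion/dilation) for a reproducibility subset of training cases.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .extract import extract_case_features, feature_manifest
from .habitat import CHResult, _case_seed, build_voxel_matrix, decompose_case, habitat_features, select_K
from .metrics import emit_report
from .modeling import fit_five_models, icc_table, predict_model
from .phantom import Cohort, PatientCase, PhantomConfig, generate_cohort
from .preprocess import roi_from_case
from .volume import ImageVolume, write_volume

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one full pipeline run."""

    n_cases: int = 181
    seed: int = 7
    split_ratio: float = 0.7
    stratified: bool = True
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_bins: int = 16
    icc_threshold: float = 0.75
    pearson_threshold: float = 0.9
    cv_folds: int = 10
    icc_subset: int = 30
    include_texture: bool = True
    include_wavelet: bool = True
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    outdir: str = "results/pipeline"

    def __post_init__(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValueError("split ratio must lie strictly in (0, 1)")
        if isinstance(self.phantom, dict):
            self.phantom = PhantomConfig(**self.phantom)
        self.phantom.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phantom"] = self.phantom.to_dict()
        return d


def split_cohort(cohort: Cohort, ratio: float = 0.7, stratified: bool = True, seed: int = 0):
    """Stratified random train/test split (e.g. 181 with 60 positives at
    0.7 -> 127 train / 54 test with 42 / 18 positives)."""
    if not 0 < ratio < 1:
        raise ValueError("split ratio must lie strictly in (0, 1)")
    labels = cohort.labels
    if min((labels == 1).sum(), (labels == 0).sum()) < 5:
        raise ValueError("each class needs at least 5 cases to split")
    rng = np.random.default_rng([seed, 3])
    idx = np.arange(len(cohort))
    train_idx: list[int] = []
    if stratified:
        for cls in (1, 0):
            members = idx[labels == cls]
            n_tr = int(round(ratio * members.size))
            train_idx.extend(rng.permutation(members)[:n_tr].tolist())
    else:
        n_tr = int(round(ratio * idx.size))
        train_idx = rng.permutation(idx)[:n_tr].tolist()
    train_set = sorted(train_idx)
    test_set = sorted(set(idx.tolist()) - set(train_set))
    train = Cohort([cohort.cases[i] for i in train_set], dict(cohort.generation_manifest))
    test = Cohort([cohort.cases[i] for i in test_set], dict(cohort.generation_manifest))
    return train, test


def _perturb_mask(mask: ImageVolume, seed: int) -> ImageVolume:
    """Second-rater surrogate: one-voxel erosion or dilation of the mask."""
    rng = np.random.default_rng([seed, 11])
    m = mask.values.astype(bool)
    if rng.random() < 0.5:
        new = ndimage.binary_erosion(m)
        if new.sum() < 200:
            new = m
    else:
        new = ndimage.binary_dilation(m)
    return ImageVolume(new.astype(np.uint8), mask.spacing, mask.affine.copy())


@dataclass
class PipelineResult:
    cohort: Cohort
    train: Cohort
    test: Cohort
    radiomics: pd.DataFrame
    habitat_feats: pd.DataFrame
    ch_result: CHResult
    models: dict
    report: dict
    icc_radiomics: pd.Series | None = None
    icc_habitat: pd.Series | None = None
    habitat_maps: dict | None = None


def _habitat_table(cases: list[PatientCase], rois: dict, K: int, seed: int, id_to_index: dict) -> tuple[pd.DataFrame, dict]:
    rows, maps = {}, {}
    for c in cases:
        hmap = decompose_case(rois[c.id], K, seed=_case_seed(seed, id_to_index[c.id]))
        rows[c.id] = habitat_features(c, rois[c.id], hmap)
        maps[c.id] = hmap
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df, maps


def run_all(config: PipelineConfig, cohort: Cohort | None = None, write: bool = True) -> PipelineResult:
    """Run the full pipeline; optionally persist all artifacts."""
    if cohort is None:
        log.info("simulating cohort of %d cases", config.n_cases)
        cohort = generate_cohort(config.n_cases, config.phantom)
    train, test = split_cohort(cohort, config.split_ratio, config.stratified, config.seed)
    id_to_index = {c.id: i for i, c in enumerate(cohort.cases)}

    log.info("extracting whole-tumor features")
    kwargs = dict(include_texture=config.include_texture, include_wavelet=config.include_wavelet)
    radiomics = pd.DataFrame.from_dict(
        {c.id: extract_case_features(c, **kwargs) for c in cohort.cases}, orient="index"
    )
    radiomics.index.name = "id"

    log.info("selecting K by mean Calinski-Harabasz over training cases")
    rois = {c.id: roi_from_case(c.t2, c.adc, c.mask) for c in cohort.cases}
    train_matrices = [build_voxel_matrix(rois[c.id]) for c in train.cases]
    ch = select_K(train_matrices, k_range=config.k_range, seed=config.seed)
    if len(config.k_range) == 1:
        log.info("K range has a single value; selection skipped, K fixed at %d", ch.selected_k)

    habitat_feats, maps = _habitat_table(cohort.cases, rois, ch.selected_k, config.seed, id_to_index)

    icc_rad = icc_hab = None
    if config.icc_subset and config.icc_subset >= 3:
        sub = train.cases[: min(config.icc_subset, len(train.cases))]
        log.info("ICC reproducibility pass on %d training cases", len(sub))
        r2_rad, r2_hab = {}, {}
        for c in sub:
            pc = PatientCase(
                id=c.id, t2=c.t2, adc=c.adc,
                mask=_perturb_mask(c.mask, id_to_index[c.id]),
                clinical=c.clinical, label=c.label, truth=c.truth,
            )
            r2_rad[c.id] = extract_case_features(pc, **kwargs)
            roi2 = roi_from_case(pc.t2, pc.adc, pc.mask)
            hmap2 = decompose_case(roi2, ch.selected_k, seed=_case_seed(config.seed, id_to_index[c.id]))
            r2_hab[c.id] = habitat_features(pc, roi2, hmap2)
        sub_ids = [c.id for c in sub]
        icc_rad = icc_table(radiomics.loc[sub_ids], pd.DataFrame.from_dict(r2_rad, orient="index"))
        icc_hab = icc_table(habitat_feats.loc[sub_ids], pd.DataFrame.from_dict(r2_hab, orient="index"))

    log.info("fitting the five models on the training cohort")
    train_ids = [c.id for c in train.cases]
    test_ids = [c.id for c in test.cases]
    clinical = cohort.clinical_frame()
    y_train = clinical.loc[train_ids, "label"].to_numpy()
    y_test = clinical.loc[test_ids, "label"].to_numpy()
    models = fit_five_models(
        radiomics.loc[train_ids],
        habitat_feats.loc[train_ids],
        clinical.loc[train_ids],
        y_train,
        seed=config.seed,
        icc_radiomics=icc_rad,
        icc_habitat=icc_hab,
        folds=config.cv_folds,
    )

    model_scores = {}
    for mid, model in models.items():
        model_scores[mid] = {
            "train": (
                predict_model(model, radiomics.loc[train_ids], habitat_feats.loc[train_ids], clinical.loc[train_ids]).to_numpy(),
                y_train,
            ),
            "test": (
                predict_model(model, radiomics.loc[test_ids], habitat_feats.loc[test_ids], clinical.loc[test_ids]).to_numpy(),
                y_test,
            ),
        }
    report = emit_report(model_scores, {mid: m.threshold for mid, m in models.items()})
    report["scores"] = model_scores

    result = PipelineResult(
        cohort=cohort, train=train, test=test, radiomics=radiomics,
        habitat_feats=habitat_feats, ch_result=ch, models=models, report=report,
        icc_radiomics=icc_rad, icc_habitat=icc_hab, habitat_maps=maps,
    )
    if write:
        write_artifacts(result, config)
    return result


def _model_record(model) -> dict:
    rec = {
        "model_id": model.model_id,
        "terms": list(model.terms),
        "coefficients": {k: float(v) for k, v in model.params.items()},
        "threshold": model.threshold,
    }
    if model.signature is not None:
        rec["signature"] = {
            "features": list(model.signature.features),
            "weights": [float(w) for w in model.signature.weights],
            "intercept": model.signature.intercept,
            "lambda": model.signature.lam,
            "empty": model.signature.empty,
        }
    if model.aic is not None:
        rec["aic"] = model.aic
    return rec


def write_artifacts(result: PipelineResult, config: PipelineConfig) -> dict:
    """Persist all pipeline artifacts; returns the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.radiomics.to_csv(out / "features.csv")
    result.habitat_feats.to_csv(out / "habitat_features.csv")
    (out / "feature_manifest.json").write_text(
        json.dumps(feature_manifest(result.radiomics.columns), indent=2)
    )
    (out / "ch_scores.json").write_text(
        json.dumps(
            {
                "mean_scores": {str(k): v for k, v in result.ch_result.mean_scores.items()},
                "selected_k": result.ch_result.selected_k,
                "low_confidence": result.ch_result.low_confidence,
            },
            indent=2,
        )
    )
    (out / "models.json").write_text(
        json.dumps({mid: _model_record(m) for mid, m in result.models.items()}, indent=2)
    )
    result.report["table"].to_csv(out / "report.csv", index=False)
    (out / "dca").mkdir(exist_ok=True)
    for mid, curve in result.report["dca"].items():
        curve.frame().to_csv(out / "dca" / f"{mid.replace('+', '_')}.csv", index=False)
    for split, mat in result.report["delong"].items():
        mat.to_csv(out / f"delong_matrix_{split}.csv")
    if result.icc_radiomics is not None:
        pd.DataFrame({"radiomics": result.icc_radiomics}).to_csv(out / "icc_radiomics.csv")
        pd.DataFrame({"habitat": result.icc_habitat}).to_csv(out / "icc_habitat.csv")
    if result.habitat_maps:
        hdir = out / "habitat_maps"
        hdir.mkdir(exist_ok=True)
        for cid, hmap in result.habitat_maps.items():
            case = next(c for c in result.cohort.cases if c.id == cid)
            write_volume(
                ImageVolume(hmap.label_volume.astype(np.int16), case.mask.spacing, case.mask.affine),
                hdir / f"{cid}_habitat.nii.gz",
            )
    manifest = {
        "config": config.to_dict(),
        "train_ids": [c.id for c in result.train.cases],
        "test_ids": [c.id for c in result.test.cases],
        "selected_k": result.ch_result.selected_k,
        "hashes": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json"))
            if p.name != "run_manifest.json"
        },
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
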