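"""Synthetic multiparametric tumor phantoms with planted habitat structure.

Each phantom is an ellipsoidal tumor on a 3-D grid carrying two
co-registered channels (a T2-like signal and an ADC-like map). The tumor
is partitioned into spatially contiguous intensity habitats by seeded
competitive region growth, with habitat volume fractions drawn from a
Dirichlet distribution. The canonical three-habitat semantics are:

* habitat 1 — high T2 signal (viable, vascular/edematous tissue),
* habitat 2 — low T2 / high ADC (necrotic, low cellularity),
* habitat 3 — low T2 / low ADC (viable, densely cellular).

Treatment-response labels are Bernoulli draws from a logistic model on
the habitat volume fractions (high-T2 and low-T2/low-ADC fractions
favour response, low-T2/high-ADC opposes it) plus clinical covariates;
the intercept is auto-calibrated by bisection to hit a target prevalence
of good responders. Clinical covariates are sampled from marginals
matching a locally-advanced rectal cancer cohort (~181 patients, ~33%
good responders). Hidden ground truth (habitat labels, fractions, linear
predictor) is retained on every case for testing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .volume import ImageVolume, read_volume, validate_mask, write_volume

# (T2, ADC) habitat means in arbitrary units / 1e-3 mm^2/s, ordered by
# canonical part: high-T2, low-T2/high-ADC, low-T2/low-ADC.
DEFAULT_HABITAT_MEANS = ((180.0, 1.1), (80.0, 1.8), (90.0, 0.8))
DEFAULT_HABITAT_SDS = ((15.0, 0.15), (15.0, 0.15), (15.0, 0.15))
DEFAULT_BACKGROUND = ((40.0, 10.0), (0.4, 0.1))  # (mean, sd) per channel

#: Default label-model coefficients. Keys matching clinical fields are
#: applied to those covariates (continuous ones centered at their
#: population mean); ``frac_*`` keys hit the true habitat fractions.
DEFAULT_RESPONSE_COEFFICIENTS: dict[str, float] = {
    "frac_high_t2": 3.0,
    "frac_low_t2_high_adc": -3.0,
    "frac_low_t2_low_adc": 2.0,
    "tumor_length": -0.02,
    "mrf": -0.8,
    "cea_positive": -0.6,
    "therapy_with_radiation": 0.5,
    "n_stage_n2": -0.5,
}


@dataclass
class PhantomConfig:
    """Generation parameters for one phantom cohort."""

    grid_size: int = 64
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_habitats: int = 3
    habitat_intensity_means: tuple = DEFAULT_HABITAT_MEANS
    habitat_intensity_sds: tuple = DEFAULT_HABITAT_SDS
    background: tuple = DEFAULT_BACKGROUND
    dirichlet_alpha: tuple = (2.0, 2.0, 2.0)
    radius_range: tuple[float, float] = (8.0, 20.0)
    response_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RESPONSE_COEFFICIENTS)
    )
    prevalence_target: float = 0.33
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_habitats < 2:
            raise ValueError("n_habitats must be >= 2")
        if not 0 < self.prevalence_target < 1:
            raise ValueError("prevalence_target must lie in (0, 1)")
        means = np.asarray(self.habitat_intensity_means, float)
        sds = np.asarray(self.habitat_intensity_sds, float)
        if means.shape != (self.n_habitats, 2) or sds.shape != (self.n_habitats, 2):
            raise ValueError("need one (T2, ADC) mean/sd pair per habitat")
        if np.any(sds < 0):
            raise ValueError("habitat intensity SDs must be non-negative")
        for a in range(self.n_habitats):
            for b in range(a + 1, self.n_habitats):
                if np.allclose(means[a], means[b]):
                    raise ValueError(f"habitat means {a} and {b} coincide")
        if len(self.dirichlet_alpha) != self.n_habitats:
            raise ValueError("dirichlet_alpha length must equal n_habitats")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["habitat_intensity_means"] = np.asarray(self.habitat_intensity_means).tolist()
        d["habitat_intensity_sds"] = np.asarray(self.habitat_intensity_sds).tolist()
        return d


@dataclass
class ClinicalRecord:
    """Baseline clinical covariates of one patient."""

    age: float
    sex: str  # "male" / "female"
    tumor_length: float  # mm
    tumor_thickness: float  # mm
    location: str  # low / median / high
    mri_t_stage: str  # T3 / T4
    mri_n_stage: str  # N0 / N1 / N2
    emvi: int
    mrf: int
    cea_positive: int
    therapy_with_radiation: int
    afp: float
    ca125: float
    ca724: float
    ca199: float

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"bad sex {self.sex!r}")
        if self.location not in ("low", "median", "high"):
            raise ValueError(f"bad location {self.location!r}")
        if self.mri_t_stage not in ("T3", "T4"):
            raise ValueError(f"bad T stage {self.mri_t_stage!r}")
        if self.mri_n_stage not in ("N0", "N1", "N2"):
            raise ValueError(f"bad N stage {self.mri_n_stage!r}")
        for name in ("age", "tumor_length", "tumor_thickness", "afp", "ca125", "ca724", "ca199"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")


@dataclass
class GroundTruth:
    """Hidden generation truth, kept for testing only."""

    habitat_labels: np.ndarray  # full grid, 0 background, 1..K inside mask
    fractions: np.ndarray  # realized habitat voxel-count fractions
    linear_predictor: float | None = None


@dataclass
class PatientCase:
    id: str
    t2: ImageVolume
    adc: ImageVolume
    mask: ImageVolume
    clinical: ClinicalRecord | None = None
    label: int | None = None
    truth: GroundTruth | None = None


@dataclass
class Cohort:
    cases: list[PatientCase]
    generation_manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.cases)

    @property
    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.cases])

    def clinical_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cases:
            d = dataclasses.asdict(c.clinical)
            d["id"] = c.id
            d["label"] = c.label
            rows.append(d)
        return pd.DataFrame(rows).set_index("id")


_NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer targets summing to ``total`` with proportions ``fractions``."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


def _grow_habitats(mask: np.ndarray, fractions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Partition mask foreground into contiguous regions of given fractions.

    Seeded competitive region growth: each habitat starts from a random
    foreground seed and claims unassigned 6-connected neighbors; at every
    step the habitat with the largest remaining deficit (relative to its
    target count) grows, so realized counts track the targets closely
    while regions stay connected by construction.
    """
    K = fractions.size
    fg = np.flatnonzero(mask.ravel())
    targets = _largest_remainder(fractions, fg.size)
    labels = np.zeros(mask.size, dtype=np.int16)
    shape = mask.shape
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    offsets = _NEIGHBOR_OFFSETS @ strides
    inside = np.zeros(mask.size, dtype=bool)
    inside[fg] = True

    seeds = rng.choice(fg, size=K, replace=False)
    frontiers: list[list[int]] = [[int(s)] for s in seeds]
    counts = np.zeros(K, dtype=int)
    assigned = 0
    while assigned < fg.size:
        deficit = np.where(targets > 0, (targets - counts) / np.maximum(targets, 1), -1.0)
        live = [h for h in range(K) if frontiers[h]]
        if not live:
            # Frontiers exhausted (habitat walled in): restart remaining
            # growth for the neediest habitat from a fresh unassigned seed.
            h = int(np.argmax(targets - counts))
            rest = fg[labels[fg] == 0]
            frontiers[h].append(int(rng.choice(rest)))
            live = [h]
        h = max(live, key=lambda i: deficit[i])
        fr = frontiers[h]
        j = rng.integers(len(fr))
        fr[j], fr[-1] = fr[-1], fr[j]
        v = fr.pop()
        if labels[v]:
            continue
        labels[v] = h + 1
        counts[h] += 1
        assigned += 1
        if counts[h] >= targets[h] and deficit[h] <= 0:
            pass  # keep frontier; habitat may still be called on if others stall
        for off in offsets:
            w = v + off
            if 0 <= w < labels.size and inside[w] and not labels[w]:
                fr.append(int(w))
    return labels.reshape(shape)


def generate_phantom(config: PhantomConfig, case_seed: int) -> PatientCase:
    """Generate one phantom case (no clinical record or label yet).

    Deterministic in ``(config.seed, case_seed)``. The ellipsoidal mask is
    redrawn (new internal seed) if it ends up below 200 voxels; after 10
    attempts an error is raised.
    """
    n = config.grid_size
    for attempt in range(10):
        rng = np.random.default_rng([config.seed, case_seed, attempt])
        center = n / 2 + rng.uniform(-2, 2, size=3)
        radii = rng.uniform(*config.radius_range, size=3)
        grid = np.indices((n, n, n), dtype=float)
        d2 = sum(((grid[a] - center[a]) / radii[a]) ** 2 for a in range(3))
        mask = (d2 <= 1.0).astype(np.uint8)
        if mask.sum() >= 200:
            break
    else:
        raise RuntimeError(f"mask below 200 voxels after 10 attempts (seed {case_seed})")

    K = config.n_habitats
    fractions = rng.dirichlet(np.asarray(config.dirichlet_alpha, float))
    habitat_labels = _grow_habitats(mask.astype(bool), fractions, rng)

    means = np.asarray(config.habitat_intensity_means, float)
    sds = np.asarray(config.habitat_intensity_sds, float)
    (bg_t2_mu, bg_t2_sd), (bg_adc_mu, bg_adc_sd) = config.background
    t2 = rng.normal(bg_t2_mu, bg_t2_sd, size=(n, n, n))
    adc = rng.normal(bg_adc_mu, bg_adc_sd, size=(n, n, n))
    for h in range(K):
        sel = habitat_labels == h + 1
        cnt = int(sel.sum())
        t2[sel] = means[h, 0] + sds[h, 0] * rng.standard_normal(cnt)
        adc[sel] = means[h, 1] + sds[h, 1] * rng.standard_normal(cnt)
    adc = np.maximum(adc, 1e-6)  # ADC is physically non-negative

    fg_count = int(mask.sum())
    realized = np.array([(habitat_labels == h + 1).sum() / fg_count for h in range(K)])
    sp = config.voxel_spacing
    return PatientCase(
        id=f"case{case_seed:04d}",
        t2=ImageVolume(t2, sp),
        adc=ImageVolume(adc, sp),
        mask=ImageVolume(mask, sp),
        truth=GroundTruth(habitat_labels=habitat_labels, fractions=realized),
    )


def _sample_clinical(rng: np.random.Generator) -> ClinicalRecord:
    """Sample covariates from marginals typical of a LARC cohort."""
    return ClinicalRecord(
        age=float(np.clip(rng.normal(60.0, 10.0), 25, 90)),
        sex="male" if rng.random() < 0.66 else "female",
        tumor_length=float(np.clip(rng.normal(51.0, 18.0), 10, 140)),
        tumor_thickness=float(np.clip(rng.normal(18.9, 7.2), 4, 50)),
        location=["low", "median", "high"][rng.choice(3, p=[0.31, 0.55, 0.14])],
        mri_t_stage="T4" if rng.random() < 0.39 else "T3",
        mri_n_stage=["N0", "N1", "N2"][rng.choice(3, p=[0.12, 0.26, 0.62])],
        emvi=int(rng.random() < 0.62),
        mrf=int(rng.random() < 0.63),
        cea_positive=int(rng.random() < 0.52),
        therapy_with_radiation=int(rng.random() < 0.50),
        afp=float(np.clip(rng.lognormal(0.9, 0.5), 0.2, 30)),
        ca125=float(np.clip(rng.normal(11.4, 5.9), 1, 60)),
        ca724=float(np.clip(rng.lognormal(0.8, 1.1), 0.1, 150)),
        ca199=float(np.clip(rng.lognormal(2.6, 1.4), 0.5, 2500)),
    )


_CENTERING = {"tumor_length": 51.0, "tumor_thickness": 18.9, "age": 60.0}


def _case_linear_predictor(case: PatientCase, coefficients: dict[str, float]) -> float:
    """Linear predictor without the intercept."""
    frac = case.truth.fractions
    frac_terms = {
        "frac_high_t2": frac[0] if frac.size > 0 else 0.0,
        "frac_low_t2_high_adc": frac[1] if frac.size > 1 else 0.0,
        "frac_low_t2_low_adc": frac[2] if frac.size > 2 else 0.0,
    }
    lp = 0.0
    for name, coef in coefficients.items():
        if name == "intercept":
            lp += coef
        elif name in frac_terms:
            lp += coef * frac_terms[name]
        elif name == "n_stage_n2":
            lp += coef * (case.clinical.mri_n_stage == "N2")
        else:
            v = getattr(case.clinical, name)
            lp += coef * (float(v) - _CENTERING.get(name, 0.0))
    if not np.isfinite(lp):
        raise ValueError(f"non-finite linear predictor for case {case.id}")
    return lp


def calibrate_intercept(lps: np.ndarray, target: float) -> float:
    """Bisection for c with mean(sigmoid(lp + c)) = target."""
    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if expit(lps + mid).mean() < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_labels(
    cases: list[PatientCase],
    coefficients: dict[str, float] | None = None,
    seed: int = 0,
    prevalence_target: float = 0.33,
) -> list[PatientCase]:
    """Draw Bernoulli response labels (1 = good response, TRG 0-1).

    The intercept is auto-calibrated so the expected prevalence matches
    ``prevalence_target``; an explicit ``intercept`` coefficient is an
    additional fixed offset.
    """
    coefficients = dict(DEFAULT_RESPONSE_COEFFICIENTS if coefficients is None else coefficients)
    lps = np.array([_case_linear_predictor(c, coefficients) for c in cases])
    c0 = calibrate_intercept(lps, prevalence_target)
    rng = np.random.default_rng([seed, 2])
    probs = expit(lps + c0)
    labels = (rng.random(len(cases)) < probs).astype(int)
    for case, lp, y in zip(cases, lps + c0, labels):
        case.label = int(y)
        case.truth.linear_predictor = float(lp)
    return cases


def generate_cohort(n: int, config: PhantomConfig | None = None) -> Cohort:
    """Generate a full phantom cohort: volumes, covariates, and labels."""
    if n < 10:
        raise ValueError("cohort size must be >= 10")
    config = config or PhantomConfig()
    cases = []
    for i in range(n):
        case = generate_phantom(config, case_seed=i)
        case.clinical = _sample_clinical(np.random.default_rng([config.seed, i, 101]))
        cases.append(case)
    generate_labels(
        cases,
        config.response_coefficients or None,
        seed=config.seed,
        prevalence_target=config.prevalence_target,
    )
    prev = float(np.mean([c.label for c in cases]))
    manifest = {"n": n, "config": config.to_dict(), "realized_prevalence": prev}
    return Cohort(cases=cases, generation_manifest=manifest)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write NIfTI volumes, ``clinical.csv`` and ``manifest.json``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for c in cohort.cases:
        write_volume(c.t2, out / f"{c.id}_t2.nii.gz")
        write_volume(c.adc, out / f"{c.id}_adc.nii.gz")
        write_volume(c.mask, out / f"{c.id}_mask.nii.gz")
    cohort.clinical_frame().to_csv(out / "clinical.csv")
    (out / "manifest.json").write_text(json.dumps(cohort.generation_manifest, indent=2))


def read_cohort(indir) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (truth is not persisted)."""
    from pathlib import Path

    ind = Path(indir)
    clin = pd.read_csv(ind / "clinical.csv", index_col="id")
    cases = []
    for cid, row in clin.iterrows():
        kw = row.drop("label").to_dict()
        cases.append(
            PatientCase(
                id=str(cid),
                t2=read_volume(ind / f"{cid}_t2.nii.gz"),
                adc=read_volume(ind / f"{cid}_adc.nii.gz"),
                mask=validate_mask(read_volume(ind / f"{cid}_mask.nii.gz")),
                clinical=ClinicalRecord(**kw),
                label=int(row["label"]),
            )
        )
    manifest = {}
    mpath = ind / "manifest.json"
    if mpath.exists():
        manifest = json.loads(mpath.read_text())
    return Cohort(cases=cases, generation_manifest=manifest)
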