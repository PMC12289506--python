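"""Feature selection and the five response models.

The model-building chain mirrors standard radiomics practice: features
unstable across raters (ICC(2,1) < 0.75) are excluded; features are
z-scored on the training set; collinear pairs (|Pearson r| > 0.9) are
greedily pruned; an L1-penalized logistic regression with 10-fold
cross-validated lambda yields a sparse signature whose linear predictor
is the Radscore; clinical covariates enter a bidirectional stepwise
logistic regression driven by AIC. Five models result:

* Clinic            — stepwise-AIC clinical logistic regression
* Radiomics         — LASSO signature on whole-tumor features (Radscore)
* Habitat           — LASSO signature on per-habitat features
* Clinic+Radiomics  — plain logistic on clinical selected terms + Radscore
* Clinic+Habitat    — plain logistic on clinical selected terms + habitat score

The combined models deliberately perform NO second feature selection.
All fitting consumes training rows only; every fitted model carries the
training-cohort Youden threshold used for test-set classification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .metrics import youden_threshold

log = logging.getLogger(__name__)

ICC_THRESHOLD = 0.75
PEARSON_THRESHOLD = 0.9


# ---------------------------------------------------------------------------
# ICC stability filter
# ---------------------------------------------------------------------------


def icc_2way_random_absolute(measurements: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``measurements`` is an (n cases x k raters) table. From the two-way
    ANOVA decomposition: ICC = (MSR - MSE) / (MSR + (k-1) MSE +
    k (MSC - MSE) / n). Zero total variance is defined as ICC 1.
    """
    x = np.asarray(measurements, dtype=float)
    n, k = x.shape
    if n < 3 or k < 2:
        raise ValueError(f"ICC needs >= 3 cases and >= 2 raters, got {x.shape}")
    grand = x.mean()
    if np.allclose(x, grand):
        warnings.warn("zero total variance: ICC defined as 1", stacklevel=2)
        return 1.0
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def icc_table(rater1: pd.DataFrame, rater2: pd.DataFrame) -> pd.Series:
    """Per-feature ICC(2,1) from two raters' feature tables (same cases)."""
    common = rater1.index.intersection(rater2.index)
    out = {}
    for col in rater1.columns:
        out[col] = icc_2way_random_absolute(
            np.column_stack([rater1.loc[common, col], rater2.loc[common, col]])
        )
    return pd.Series(out)


def filter_stability(features: list[str], icc_values: pd.Series, threshold: float = ICC_THRESHOLD) -> list[str]:
    """Keep features with ICC >= threshold (boundary value retained)."""
    kept = [f for f in features if icc_values.get(f, np.nan) >= threshold]
    log.info("ICC filter: %d/%d features retained at %.2f", len(kept), len(features), threshold)
    return kept


# ---------------------------------------------------------------------------
# Collinearity pruning
# ---------------------------------------------------------------------------


def pearson_prune(table: pd.DataFrame, threshold: float = PEARSON_THRESHOLD) -> list[str]:
    """Greedy collinearity elimination; returns the retained column names.

    While any pair exceeds |r| > threshold, the member of the worst pair
    with the larger mean absolute correlation to all remaining features
    is dropped (ties -> the later name alphabetically). Constant columns
    are dropped first with a warning. Deterministic.
    """
    cols = list(table.columns)
    const = [c for c in cols if table[c].std() == 0]
    if const:
        warnings.warn(f"dropping {len(const)} constant feature(s): {const[:5]}", stacklevel=2)
        cols = [c for c in cols if c not in const]
    if len(cols) < 2:
        return cols
    corr = table[cols].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    names = list(cols)
    while True:
        mx = corr.max()
        if mx <= threshold or len(names) < 2:
            break
        a, b = np.unravel_index(np.argmax(corr), corr.shape)
        mean_a = corr[a].sum() / (len(names) - 1)
        mean_b = corr[b].sum() / (len(names) - 1)
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = a if names[a] > names[b] else b
        names.pop(drop)
        corr = np.delete(np.delete(corr, drop, axis=0), drop, axis=1)
    return names


# ---------------------------------------------------------------------------
# LASSO logistic signature
# ---------------------------------------------------------------------------


@dataclass
class Signature:
    """A sparse linear radiomics signature: Radscore = beta + sum w_i x_i."""

    features: list[str]
    weights: np.ndarray
    intercept: float
    lam: float
    lambda_path: np.ndarray = field(default_factory=lambda: np.array([]))
    cv_deviance: np.ndarray = field(default_factory=lambda: np.array([]))
    nonzero_path: np.ndarray = field(default_factory=lambda: np.array([]))
    empty: bool = False


def fit_l1_at_lambda(X: np.ndarray, y: np.ndarray, lam: float, model: LogisticRegression | None = None):
    """L1-penalized logistic fit at penalty ``lam`` (glmnet scale).

    The objective is mean binomial deviance / 2 + lam * ||w||_1, i.e.
    scikit-learn's C = 1 / (n * lam). ``lam = 0`` fits the unpenalized
    maximum-likelihood model. Returns (coef vector, intercept, model)
    where ``model`` can be passed back in for warm starts.
    """
    n = X.shape[0]
    if lam == 0:
        m = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000, tol=1e-10)
        m.fit(X, y)
        return m.coef_[0].copy(), float(m.intercept_[0]), None
    C = 1.0 / (n * lam)
    if model is None:
        # liblinear with a large intercept_scaling leaves the intercept
        # effectively unpenalized, matching the glmnet convention.
        model = LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", max_iter=2000, tol=1e-8,
            intercept_scaling=1e4, random_state=0,
        )
    else:
        model.C = C
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model.coef_[0].copy(), float(model.intercept_[0]), model


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lasso_logistic_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 40,
    lambda_min_ratio: float = 1e-3,
    rule: str = "1se",
) -> Signature:
    """LASSO logistic regression with stratified K-fold CV over a lambda path.

    ``rule="min"`` takes the lambda minimizing mean cross-validated
    binomial deviance (ties -> the larger, sparser lambda);
    ``rule="1se"`` (default) takes the largest lambda whose mean
    deviance is within one standard error of that minimum — the sparser,
    selection-consistent choice. The features with nonzero coefficients
    in the full-data refit at the chosen lambda form the signature.
    Deterministic given ``seed``. If nothing survives, an empty
    signature with intercept logit(prevalence) is returned, flagged.
    """
    if rule not in ("min", "1se"):
        raise ValueError(f"unknown lambda rule {rule!r}")
    names = list(X.columns)
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = Xa.shape[0]
    if n < 20:
        raise ValueError("LASSO CV needs at least 20 samples")
    prev = y.mean()
    lam_max = np.abs(Xa.T @ (y - prev)).max() / n
    if lam_max == 0:
        lam_max = 1e-3
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, n_lambdas))
    for f, (tr, va) in enumerate(skf.split(Xa, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            raise ValueError("a CV fold lost one of the classes; reduce folds")
        model = None
        for j, lam in enumerate(lambdas):
            w, b, model = fit_l1_at_lambda(Xa[tr], y[tr], lam, model)
            p = expit(Xa[va] @ w + b)
            dev[f, j] = _binomial_deviance(y[va], p)
    mean_dev = dev.mean(axis=0)
    best = int(np.flatnonzero(mean_dev == mean_dev.min())[0])  # path is sparse->dense
    if rule == "1se":
        se_min = float(dev[:, best].std(ddof=1) / np.sqrt(folds))
        best = int(np.flatnonzero(mean_dev <= mean_dev[best] + se_min)[0])
    lam_best = float(lambdas[best])

    nonzero_path = np.zeros(n_lambdas, dtype=int)
    model = None
    weights = intercept = None
    for j, lam in enumerate(lambdas):
        w, b, model = fit_l1_at_lambda(Xa, y, lam, model)
        nonzero_path[j] = int(np.sum(w != 0))
        if j == best:
            weights, intercept = w, b

    nz = np.flatnonzero(weights != 0)
    if nz.size == 0:
        log.warning("LASSO selected no features; falling back to intercept-only signature")
        return Signature(
            features=[],
            weights=np.array([]),
            intercept=float(logit(np.clip(prev, 1e-6, 1 - 1e-6))),
            lam=lam_best,
            lambda_path=lambdas,
            cv_deviance=mean_dev,
            nonzero_path=nonzero_path,
            empty=True,
        )
    return Signature(
        features=[names[i] for i in nz],
        weights=weights[nz].copy(),
        intercept=float(intercept),
        lam=lam_best,
        lambda_path=lambdas,
        cv_deviance=mean_dev,
        nonzero_path=nonzero_path,
    )


def radscore(x, signature: Signature) -> float:
    """Radscore = beta + sum_i w_i x_i for one patient's feature mapping."""
    total = signature.intercept
    for name, w in zip(signature.features, signature.weights):
        try:
            v = x[name]
        except KeyError as exc:
            raise KeyError(f"feature {name!r} required by signature is missing") from exc
        total += w * float(v)
    return float(total)


def radscore_table(X: pd.DataFrame, signature: Signature) -> pd.Series:
    missing = [f for f in signature.features if f not in X.columns]
    if missing:
        raise KeyError(f"features required by signature are missing: {missing}")
    if not signature.features:
        return pd.Series(signature.intercept, index=X.index)
    return X[signature.features] @ pd.Series(signature.weights, index=signature.features) + signature.intercept


# ---------------------------------------------------------------------------
# Clinical design matrix + stepwise AIC
# ---------------------------------------------------------------------------

CLINICAL_CONTINUOUS = ("age", "tumor_length", "tumor_thickness", "afp", "ca125", "ca724", "ca199")
CLINICAL_BINARY = ("emvi", "mrf", "cea_positive", "therapy_with_radiation")


def clinical_design(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix from the clinical covariate table.

    Categorical covariates become treatment-coded dummies (reference:
    female, low location, T3, N0); column order is fixed.
    """
    d = pd.DataFrame(index=clinical.index)
    for c in CLINICAL_CONTINUOUS:
        d[c] = clinical[c].astype(float)
    for c in CLINICAL_BINARY:
        d[c] = clinical[c].astype(float)
    d["sex_male"] = (clinical["sex"] == "male").astype(float)
    d["location_median"] = (clinical["location"] == "median").astype(float)
    d["location_high"] = (clinical["location"] == "high").astype(float)
    d["t_stage_T4"] = (clinical["mri_t_stage"] == "T4").astype(float)
    d["n_stage_N1"] = (clinical["mri_n_stage"] == "N1").astype(float)
    d["n_stage_N2"] = (clinical["mri_n_stage"] == "N2").astype(float)
    return d


_SEPARATION_CAP = 20.0


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    """Plain logistic fit -> (params incl. const, aic). Warns on separation."""
    design = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
        except Exception:
            res = sm.Logit(y, design).fit(disp=0, maxiter=500, method="bfgs")
    params = res.params
    if np.abs(params).max() > _SEPARATION_CAP:
        warnings.warn("possible separation: coefficient magnitude exceeds cap", stacklevel=2)
    return params, float(res.aic), res


@dataclass
class StepwiseResult:
    terms: list[str]
    params: pd.Series
    aic: float
    trace: list[tuple[str, str, float]] = field(default_factory=list)


def stepwise_aic_logistic(design: pd.DataFrame, y: np.ndarray) -> StepwiseResult:
    """Bidirectional stepwise logistic regression minimizing AIC.

    Starts from the full model; at each step evaluates every single drop
    and every single add and applies the best AIC improvement. Ties
    prefer drops, then the alphabetically first term. Deterministic for
    a given input table.
    """
    y = np.asarray(y, dtype=int)
    if len(y) <= 10 * design.shape[1]:
        log.info("stepwise: n=%d is below 10x candidate count (%d)", len(y), design.shape[1])
    current = sorted(design.columns)
    _, best_aic, _ = _fit_logit(design[current], y)
    trace: list[tuple[str, str, float]] = [("start", "", best_aic)]
    while True:
        moves = []
        for c in sorted(current):
            cols = [t for t in current if t != c]
            _, aic, _ = _fit_logit(design[cols], y)
            moves.append((aic, 0, c, "drop"))
        for c in sorted(set(design.columns) - set(current)):
            _, aic, _ = _fit_logit(design[current + [c]], y)
            moves.append((aic, 1, c, "add"))
        if not moves:
            break
        moves.sort(key=lambda t: (t[0], t[1], t[2]))
        aic, _, term, action = moves[0]
        if aic >= best_aic - 1e-9:
            break
        best_aic = aic
        current = [t for t in current if t != term] if action == "drop" else sorted(current + [term])
        trace.append((action, term, aic))
    params, aic, _ = _fit_logit(design[current], y)
    return StepwiseResult(terms=current, params=params, aic=aic, trace=trace)


# ---------------------------------------------------------------------------
# The five models
# ---------------------------------------------------------------------------

MODEL_IDS = ("Clinic", "Radiomics", "Habitat", "Clinic+Radiomics", "Clinic+Habitat")


@dataclass
class FittedModel:
    """One of the five response models, with its training threshold."""

    model_id: str
    terms: list[str]
    params: pd.Series  # includes 'const'
    threshold: float  # training-cohort Youden threshold on probabilities
    signature: Signature | None = None
    feature_means: pd.Series | None = None
    feature_sds: pd.Series | None = None
    candidate_features: list[str] | None = None
    aic: float | None = None

    def _score_frame(self, features: pd.DataFrame | None, clinical: pd.DataFrame | None) -> pd.DataFrame:
        cols = {}
        if self.signature is not None:
            z = (features[self.candidate_features] - self.feature_means) / self.feature_sds
            cols["score"] = radscore_table(z, self.signature)
        for t in self.terms:
            if t != "score":
                cols[t] = clinical_design(clinical)[t] if t in _ALL_CLINICAL_COLS(clinical) else features[t]
        idx = (clinical if clinical is not None else features).index
        return pd.DataFrame(cols, index=idx)[self.terms]

    def predict_proba(self, features: pd.DataFrame | None = None, clinical: pd.DataFrame | None = None) -> pd.Series:
        """Response probability for new cases (training transforms applied)."""
        d = self._score_frame(features, clinical)
        design = sm.add_constant(d, has_constant="add")
        lp = design @ self.params.reindex(design.columns).fillna(0.0)
        return pd.Series(expit(lp), index=d.index)


def _ALL_CLINICAL_COLS(clinical: pd.DataFrame | None) -> set:
    if clinical is None:
        return set()
    return set(clinical_design(clinical).columns)


def _signature_model(
    model_id: str,
    features: pd.DataFrame,
    y: np.ndarray,
    seed: int,
    icc_values: pd.Series | None,
    folds: int = 10,
) -> FittedModel:
    cols = list(features.columns)
    if icc_values is not None:
        cols = filter_stability(cols, icc_values)
    sub = features[cols]
    mu = sub.mean()
    sd = sub.std(ddof=0).replace(0.0, 1.0)
    z = (sub - mu) / sd
    kept = pearson_prune(z)
    sig = lasso_logistic_cv(z[kept], y, folds=folds, seed=seed)
    # Probability via the penalized fit's own linear predictor (= Radscore).
    probs = expit(radscore_table(z, sig))
    thr = youden_threshold(probs.to_numpy(), y)
    model = FittedModel(
        model_id=model_id,
        terms=["score"],
        params=pd.Series({"const": 0.0, "score": 1.0}),
        threshold=float(thr),
        signature=sig,
        feature_means=mu,
        feature_sds=sd,
        candidate_features=list(sub.columns),
    )
    return model


def _combined_model(
    model_id: str,
    clinic_terms: list[str],
    base: FittedModel,
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    y: np.ndarray,
) -> FittedModel:
    z = (features[base.candidate_features] - base.feature_means) / base.feature_sds
    d = clinical_design(clinical)[clinic_terms].copy()
    d["score"] = radscore_table(z, base.signature)
    params, aic, _ = _fit_logit(d, y)
    probs = pd.Series(expit(sm.add_constant(d, has_constant="add") @ params), index=d.index)
    thr = youden_threshold(probs.to_numpy(), np.asarray(y))
    return FittedModel(
        model_id=model_id,
        terms=clinic_terms + ["score"],
        params=params,
        threshold=float(thr),
        signature=base.signature,
        feature_means=base.feature_means,
        feature_sds=base.feature_sds,
        candidate_features=base.candidate_features,
        aic=aic,
    )


def fit_five_models(
    radiomics: pd.DataFrame,
    habitat: pd.DataFrame,
    clinical: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    icc_radiomics: pd.Series | None = None,
    icc_habitat: pd.Series | None = None,
    folds: int = 10,
) -> dict[str, FittedModel]:
    """Fit Clinic, Radiomics, Habitat and the two combined models.

    All inputs are TRAINING rows only. Combined models reuse the clinical
    model's selected variables plus the corresponding score, with no
    re-selection.
    """
    y = np.asarray(y, dtype=int)

    design = clinical_design(clinical)
    step = stepwise_aic_logistic(design, y)
    clin_probs = pd.Series(
        expit(sm.add_constant(design[step.terms], has_constant="add") @ step.params),
        index=design.index,
    )
    clinic = FittedModel(
        model_id="Clinic",
        terms=list(step.terms),
        params=step.params,
        threshold=float(youden_threshold(clin_probs.to_numpy(), y)),
        aic=step.aic,
    )

    radm = _signature_model("Radiomics", radiomics, y, seed, icc_radiomics, folds)
    habm = _signature_model("Habitat", habitat, y, seed, icc_habitat, folds)
    comb_r = _combined_model("Clinic+Radiomics", clinic.terms, radm, radiomics, clinical, y)
    comb_h = _combined_model("Clinic+Habitat", clinic.terms, habm, habitat, clinical, y)
    return {
        "Clinic": clinic,
        "Radiomics": radm,
        "Habitat": habm,
        "Clinic+Radiomics": comb_r,
        "Clinic+Habitat": comb_h,
    }


def predict_model(
    model: FittedModel,
    radiomics: pd.DataFrame | None = None,
    habitat: pd.DataFrame | None = None,
    clinical: pd.DataFrame | None = None,
) -> pd.Series:
    """Dispatch prediction with the right feature table per model."""
    if model.model_id == "Clinic":
        return model.predict_proba(clinical=clinical)
    feats = radiomics if "Radiomics" in model.model_id else habitat
    if model.model_id in ("Radiomics", "Habitat"):
        return model.predict_proba(features=feats, clinical=None)
    return model.predict_proba(features=feats, clinical=clinical)
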