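"""Voxel-wise habitat decomposition of tumors in joint (T2, ADC) space.

Each tumor is clustered on its own retained ROI voxels with K-means
(Lloyd, k-means++ init, 10 restarts) after per-patient z-scoring of both
channels; the number of clusters K is chosen globally as the argmax of
the mean Calinski-Harabasz score over training cases. Cross-patient
comparability is restored by canonical centroid labeling:

* part 1 — highest T2 centroid,
* part 2 — of the remaining two, higher ADC (low T2 / high ADC),
* part 3 — lower ADC (low T2 / low ADC).

For K != 3 labeling falls back to lexicographic ordering by (-T2, -ADC)
and is flagged. Per-habitat features are volume, volume ratio, and
first-order statistics per modality.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .firstorder import FIRST_ORDER_NAMES, first_order, volume_features
from .phantom import PatientCase
from .preprocess import ROIVoxelSet

log = logging.getLogger(__name__)

K_RANGE_DEFAULT = (2, 3, 4, 5, 6)


@dataclass
class VoxelFeatureMatrix:
    """Retained ROI voxels x (z-scored T2, z-scored ADC)."""

    X: np.ndarray  # (n_voxels, 2)
    indices: np.ndarray  # flat indices into the case grid

    def __post_init__(self) -> None:
        assert self.X.shape[0] == self.indices.size


@dataclass
class HabitatMap:
    """Integer habitat partition of one tumor's retained ROI."""

    labels: np.ndarray  # per retained voxel, canonical parts 1..K
    label_volume: np.ndarray  # full grid, 0 background
    K: int
    centroids: np.ndarray  # (K, 2), canonical order, z-scored (T2, ADC)
    canonical_names: tuple[str, ...]
    canonical_fallback: bool = False


@dataclass
class CHResult:
    """Mean CH score per candidate K and the selected K."""

    k_values: tuple[int, ...]
    mean_scores: dict[int, float]
    selected_k: int
    per_case: dict[int, list] = field(default_factory=dict)
    low_confidence: bool = False


def build_voxel_matrix(roi: ROIVoxelSet) -> VoxelFeatureMatrix:
    """Z-score both channels within the retained ROI (population SD)."""
    if roi.n_voxels < 30:
        raise ValueError(f"retained ROI too small for clustering ({roi.n_voxels} voxels)")
    cols = []
    for name in ("t2", "adc"):
        x = roi.intensities[name].astype(float)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"zero within-ROI variance in channel {name!r}")
        cols.append((x - x.mean()) / sd)
    return VoxelFeatureMatrix(X=np.column_stack(cols), indices=roi.indices)


def kmeans_cluster(X: np.ndarray, K: int, seed: int, n_init: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd K-means with k-means++ init and ``n_init`` restarts.

    Returns (labels 0..K-1, centroids). Deterministic given ``seed``;
    empty clusters are re-seeded from the farthest point internally.
    """
    X = np.asarray(X, float)
    if K >= X.shape[0]:
        raise ValueError(f"K={K} must be below the voxel count {X.shape[0]}")
    km = KMeans(n_clusters=K, init="k-means++", n_init=n_init, algorithm="lloyd", random_state=seed)
    with warnings.catch_warnings():
        # duplicate voxels (noiseless inputs) legitimately yield < K distinct clusters
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        labels = km.fit_predict(X)
    return labels, km.cluster_centers_


def ch_score(X: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz criterion: [B/(K-1)] / [W/(n-K)].

    B is the size-weighted squared distance of cluster centroids to the
    grand mean; W the within-cluster sum of squares. A degenerate W = 0
    is reported as +inf with a warning.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    K, n = uniq.size, X.shape[0]
    if K < 2:
        raise ValueError("CH score needs at least 2 clusters")
    grand = X.mean(axis=0)
    B = W = 0.0
    for u in uniq:
        xs = X[labels == u]
        c = xs.mean(axis=0)
        B += xs.shape[0] * float(((c - grand) ** 2).sum())
        W += float(((xs - c) ** 2).sum())
    if W == 0:
        warnings.warn("zero within-cluster variance: CH score is infinite", stacklevel=2)
        return np.inf
    return (B / (K - 1)) / (W / (n - K))


def _case_seed(pipeline_seed: int, case_index: int) -> int:
    """Deterministic expansion of one pipeline seed to per-case seeds."""
    return int(np.random.SeedSequence([pipeline_seed, case_index]).generate_state(1)[0] % (2**31))


def select_K(
    voxel_matrices: list[VoxelFeatureMatrix],
    k_range=K_RANGE_DEFAULT,
    seed: int = 0,
) -> CHResult:
    """Pick K maximizing the mean per-case CH score (ties -> smaller K)."""
    if len(voxel_matrices) < 5:
        raise ValueError("K selection needs at least 5 training cases")
    per_case: dict[int, list] = {k: [] for k in k_range}
    skipped = 0
    for i, vm in enumerate(voxel_matrices):
        try:
            for k in k_range:
                labels, _ = kmeans_cluster(vm.X, k, seed=_case_seed(seed, i))
                per_case[k].append(ch_score(vm.X, labels))
        except Exception as exc:  # pragma: no cover - defensive
            skipped += 1
            log.warning("K selection skipped case %d: %s", i, exc)
    if skipped > 0.2 * len(voxel_matrices):
        raise RuntimeError(f"K selection failed on {skipped}/{len(voxel_matrices)} cases")
    means = {k: float(np.mean(v)) for k, v in per_case.items()}
    top = max(means.values())
    # scores within 1e-9 relative of the max are ties -> smaller K wins
    if np.isinf(top):
        best = min(k for k in k_range if np.isinf(means[k]))
    else:
        best = min(k for k in k_range if means[k] >= top - abs(top) * 1e-9)
    vals = np.array(list(means.values()))
    finite = vals[np.isfinite(vals)]
    low_conf = finite.size > 1 and float(finite.max()) / float(np.median(finite)) < 1.2
    if low_conf:
        log.warning("CH profile is flat (max/median < 1.2): K choice is low-confidence")
    return CHResult(
        k_values=tuple(k_range),
        mean_scores=means,
        selected_k=int(best),
        per_case=per_case,
        low_confidence=bool(low_conf),
    )


_PART_NAMES_K3 = ("high-T2", "low-T2/high-ADC", "low-T2/low-ADC")


def canonical_labels(centroids: np.ndarray) -> tuple[np.ndarray, tuple[str, ...], bool]:
    """Map raw cluster indices to canonical part numbers.

    Returns ``(mapping, names, fallback)`` where ``mapping[raw] = part``
    (1-based). For K=3: part 1 = highest T2 centroid; of the remaining
    two, part 2 = higher ADC, part 3 = lower ADC. Any other K uses the
    lexicographic (-T2, -ADC) fallback (flagged). Near-ties (within
    1e-9) are broken by ADC then original index.
    """
    c = np.asarray(centroids, float)
    K = c.shape[0]
    order_key = np.round(c / 1e-9) * 1e-9  # quantize so exact ties break deterministically
    if K == 3:
        idx = np.arange(K)
        part1 = max(idx, key=lambda j: (order_key[j, 0], order_key[j, 1], -j))
        rest = [j for j in idx if j != part1]
        rest.sort(key=lambda j: (-order_key[j, 1], j))
        raw_order = [part1, rest[0], rest[1]]
        names = _PART_NAMES_K3
        fallback = False
    else:
        raw_order = sorted(range(K), key=lambda j: (-order_key[j, 0], -order_key[j, 1], j))
        names = tuple(f"part{p + 1}" for p in range(K))
        fallback = True
    mapping = np.empty(K, dtype=int)
    for part, raw in enumerate(raw_order, start=1):
        mapping[raw] = part
    return mapping, names, fallback


def decompose_case(roi: ROIVoxelSet, K: int, seed: int) -> HabitatMap:
    """Cluster one tumor at fixed K and label habitats canonically."""
    vm = build_voxel_matrix(roi)
    raw_labels, raw_centroids = kmeans_cluster(vm.X, K, seed=seed)
    mapping, names, fallback = canonical_labels(raw_centroids)
    labels = mapping[raw_labels]
    centroids = np.empty_like(raw_centroids)
    for raw, part in enumerate(mapping):
        centroids[part - 1] = raw_centroids[raw]
    return HabitatMap(
        labels=labels,
        label_volume=roi.label_volume(labels),
        K=K,
        centroids=centroids,
        canonical_names=names,
        canonical_fallback=fallback,
    )


def habitat_features(case: PatientCase, roi: ROIVoxelSet, hmap: HabitatMap) -> dict[str, float]:
    """Volume, volume ratio and first-order features per habitat part.

    T2 values are the whole-image z-scored intensities, ADC native. An
    empty part yields zero features plus an ``empty_habitat`` flag.
    """
    vv = float(np.prod(roi.spacing))
    n_total = roi.n_voxels
    out: dict[str, float] = {}
    for p in range(1, hmap.K + 1):
        sel = hmap.labels == p
        n_p = int(sel.sum())
        vf = volume_features(n_p, vv, n_total=n_total)
        out[f"habitat{p}_volume"] = vf["Volume"]
        out[f"habitat{p}_volume_ratio"] = vf["VolumeRatio"]
        out[f"habitat{p}_empty_habitat"] = float(n_p == 0)
        for m in ("t2", "adc"):
            if n_p >= 2:
                feats = first_order(roi.intensities[m][sel], voxel_volume=vv)
            else:
                feats = {s: 0.0 for s in FIRST_ORDER_NAMES}
            for stat, v in feats.items():
                out[f"habitat{p}_{m}_{stat}"] = v
    return out
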