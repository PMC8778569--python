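"""Weighted fusion of feature similarities and kNN outcome prediction.

The patient similarity score is a weighted sum of per-feature
similarities. Three dominant features are chosen by majority voting over
resampled weight-determination subsets: in each repetition the candidate
features are ranked by the AUROC of their single-feature leave-one-out
kNN predictions and the top three receive votes. Their weights
(w1, w2, w3) are then optimized by grid search in 0.05 steps under
w1 + w2 + w3 = 1 and w1 >= w2 >= w3 > 0, with w1 attached to the
highest-ranked feature. All remaining features get weight 0.

An index patient's risk score is the fraction of outcome-positive
patients among their k most similar training patients (k = 50 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_model import SEQUENCE_FEATURES, ValidationError
from .matrices import SimilarityMatrix


@dataclass
class FeatureSimilaritySet:
    """Aligned per-feature similarity matrices over one cohort."""

    matrices: dict[str, SimilarityMatrix]

    def __post_init__(self) -> None:
        ids = None
        for name, m in self.matrices.items():
            if ids is None:
                ids = m.patient_ids
            elif m.patient_ids != ids:
                raise ValidationError(f"matrix {name!r}: misaligned patient order")
        self.patient_ids = ids or []

    def __contains__(self, name: str) -> bool:
        return name in self.matrices

    def __getitem__(self, name: str) -> SimilarityMatrix:
        return self.matrices[name]

    @property
    def feature_names(self) -> list[str]:
        return list(self.matrices)


CROSS_SECTIONAL_FEATURES = ("S_dem", "S_lab", "S_text")

#: model variant -> (uses sequence features, trend method or None)
VARIANTS = {
    "kNN_E": (True, None),
    "kNN_D": (False, "dtw"),
    "kNN_H": (False, "haar"),
    "kNN_ED": (True, "dtw"),
    "kNN_EH": (True, "haar"),
}


@dataclass(frozen=True)
class ModelVariant:
    """A similarity-based kNN model and its candidate feature pool."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in VARIANTS:
            raise ValidationError(f"unknown model variant {self.name!r}")

    def pool(self, registry: list[str]) -> list[str]:
        """Candidate features of this variant present in a cohort registry."""
        use_seq, trend = VARIANTS[self.name]
        pool = []
        if use_seq:
            pool += [f for f in SEQUENCE_FEATURES.values() if f in registry]
        if trend is not None:
            pool += [f for f in registry if f.startswith(f"S_{trend}:")]
        pool += [f for f in CROSS_SECTIONAL_FEATURES if f in registry]
        return pool


@dataclass(frozen=True)
class WeightAssignment:
    """Dominant features (importance-ranked) with simplex-constrained weights."""

    features: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = self.weights
        if len(w) != len(self.features) or not self.features:
            raise ValidationError("features and weights must align")
        if abs(sum(w) - 1.0) > 1e-9 or any(b > a + 1e-12 for a, b in zip(w, w[1:])):
            raise ValidationError("weights must be non-increasing and sum to 1")
        if min(w) <= 0:
            raise ValidationError("weights must be positive")


def knn_predict(
    S: SimilarityMatrix | np.ndarray,
    labels,
    index_patient: int,
    k: int,
    train_mask=None,
    id_rank=None,
) -> float:
    """Risk score: positive fraction among the index patient's top-k neighbors.

    The index patient is excluded from their own neighbor set. Ties at
    the k-th similarity are broken by ascending patient_id.
    """
    values = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S)
    labels = np.asarray(labels)
    n = values.shape[0]
    mask = np.ones(n, dtype=bool) if train_mask is None else np.asarray(train_mask).copy()
    mask[index_patient] = False
    cand = np.flatnonzero(mask)
    if k > cand.size:
        raise ValidationError(f"k={k} exceeds training pool of {cand.size}")
    sims = values[index_patient, cand]
    rank = cand if id_rank is None else np.asarray(id_rank)[cand]
    order = np.lexsort((rank, -sims))
    top = cand[order[:k]]
    return float(labels[top].sum() / k)


def _loo_scores(values: np.ndarray, labels, k: int, eval_ids, id_rank=None):
    """Leave-one-out kNN scores over eval_ids, neighbors drawn from eval_ids."""
    eval_ids = np.asarray(eval_ids)
    n = values.shape[0]
    mask = np.zeros(n, dtype=bool)
    mask[eval_ids] = True
    return np.array(
        [
            knn_predict(values, labels, i, k, train_mask=mask, id_rank=id_rank)
            for i in eval_ids
        ]
    )


def feature_auroc(feature_matrix, labels, k: int, eval_ids, id_rank=None) -> float:
    """AUROC of single-feature leave-one-out kNN scores over eval_ids."""
    from .evaluation import auroc  # local import to avoid a module cycle

    values = (
        feature_matrix.values
        if isinstance(feature_matrix, SimilarityMatrix)
        else np.asarray(feature_matrix)
    )
    labels = np.asarray(labels)
    scores = _loo_scores(values, labels, k, eval_ids, id_rank)
    return auroc(scores, labels[np.asarray(eval_ids)])


def stratified_subset(labels, fraction: float, rng: np.random.Generator, pool=None):
    """Indices of a label-stratified random subset (without replacement)."""
    labels = np.asarray(labels)
    pool = np.arange(labels.size) if pool is None else np.asarray(pool)
    chosen = []
    for cls in np.unique(labels[pool]):
        members = pool[labels[pool] == cls]
        take = max(1, int(round(fraction * members.size)))
        chosen.append(rng.choice(members, size=take, replace=False))
    return np.sort(np.concatenate(chosen))


def select_dominant_features(
    fss: FeatureSimilaritySet,
    variant: ModelVariant | list[str],
    labels,
    k: int = 50,
    reps: int = 11,
    subset_fraction: float = 0.5,
    seed: int | np.random.Generator = 0,
    n_select: int = 3,
    pool_ids=None,
) -> list[str]:
    """Majority-voting dominant-feature selection.

    Each of ``reps`` stratified random subsets (the weight-determination
    sample sets) ranks the candidate pool by single-feature kNN AUROC
    and votes for its top ``n_select``; the features with most votes
    win. Vote ties are broken by mean AUROC across repetitions, then by
    feature name.
    """
    pool = (
        variant.pool(fss.feature_names)
        if isinstance(variant, ModelVariant)
        else list(variant)
    )
    if len(pool) < n_select:
        raise ValidationError(
            f"candidate pool has {len(pool)} features; need >= {n_select}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = np.asarray(labels)
    id_rank = _id_rank(fss.patient_ids)
    votes = {f: 0 for f in pool}
    auc_sums = {f: 0.0 for f in pool}
    for _ in range(reps):
        ids = stratified_subset(labels, subset_fraction, rng, pool=pool_ids)
        aucs = {
            f: feature_auroc(fss[f], labels, k, ids, id_rank) for f in pool
        }
        for f in pool:
            auc_sums[f] += aucs[f]
        top = sorted(pool, key=lambda f: (-aucs[f], f))[:n_select]
        for f in top:
            votes[f] += 1
    ranked = sorted(pool, key=lambda f: (-votes[f], -auc_sums[f], f))
    winners = ranked[:n_select]
    # importance order inside the winning set: mean AUROC, then name
    return sorted(winners, key=lambda f: (-auc_sums[f], f))


def enumerate_weight_grid(step: float = 0.05) -> list[tuple[float, float, float]]:
    """All (w1, w2, w3) with w1 >= w2 >= w3 > 0, summing to 1, on the grid."""
    return enumerate_weight_grid_k(step, 3)  # type: ignore[return-value]


def enumerate_weight_grid_k(step: float, n_weights: int) -> list[tuple[float, ...]]:
    """Non-increasing positive ``n_weights``-tuples of grid multiples summing to 1."""
    if not 0 < step < 1:
        raise ValidationError("step must lie in (0, 1)")
    units = round(1.0 / step)
    if abs(units * step - 1.0) > 1e-9:
        raise ValidationError("1/step must be integral")

    def parts(total: int, n: int, cap: int):
        if n == 1:
            if 1 <= total <= cap:
                yield (total,)
            return
        for first in range(min(total - (n - 1), cap), 0, -1):
            for rest in parts(total - first, n - 1, first):
                yield (first, *rest)

    return [tuple(p * step for p in combo) for combo in parts(units, n_weights, units)]


def combined_similarity(
    fss: FeatureSimilaritySet, wa: WeightAssignment
) -> SimilarityMatrix:
    """Elementwise weighted sum of the assigned features' matrices."""
    out = None
    for f, w in zip(wa.features, wa.weights):
        m = fss[f]
        out = w * m.values if out is None else out + w * m.values
    return SimilarityMatrix(fss.patient_ids, out)


def optimize_weights(
    fss: FeatureSimilaritySet,
    dominant: list[str],
    labels,
    k: int = 50,
    grid: list[tuple[float, ...]] | None = None,
    eval_ids=None,
) -> WeightAssignment:
    """Grid-search the simplex weights of the dominant features.

    Features are ordered by their single-feature AUROC on ``eval_ids``
    (w1 goes to the best-ranked feature); each grid triple is scored by
    the leave-one-out kNN AUROC of the fused matrix over ``eval_ids``.
    Ties keep the first triple in grid order.
    """
    labels = np.asarray(labels)
    if eval_ids is None:
        eval_ids = np.arange(labels.size)
    if grid is None:
        grid = enumerate_weight_grid_k(0.05, len(dominant))
    if not grid:
        raise ValidationError("empty weight grid")
    id_rank = _id_rank(fss.patient_ids)
    aucs = {f: feature_auroc(fss[f], labels, k, eval_ids, id_rank) for f in dominant}
    ranked = tuple(sorted(dominant, key=lambda f: (-aucs[f], f)))
    stack = np.stack([fss[f].values for f in ranked])
    best, best_auc = None, -np.inf
    from .evaluation import auroc

    y = labels[np.asarray(eval_ids)]
    for weights in grid:
        fused = np.tensordot(np.asarray(weights), stack, axes=1)
        scores = _loo_scores(fused, labels, k, eval_ids, id_rank)
        a = auroc(scores, y)
        if a > best_auc + 1e-12:
            best, best_auc = weights, a
    return WeightAssignment(ranked, tuple(best))


def _id_rank(patient_ids: list[str]) -> np.ndarray:
    """Rank of each position under ascending patient_id (tie-break key)."""
    order = np.argsort(np.asarray(patient_ids, dtype=object))
    rank = np.empty(len(patient_ids), dtype=int)
    rank[order] = np.arange(len(patient_ids))
    return rank
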