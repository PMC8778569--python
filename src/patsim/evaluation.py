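"""Evaluation protocol: leave-one-out kNN runs, metrics, and baselines.

A run fits the similarity model (dominant-feature selection by majority
voting, then weight grid search, both on stratified weight-determination
subsets of the training patients), fuses the selected matrices, and
scores every patient leave-one-out: the patient is removed from the
training pool and their risk is the positive fraction among their k most
similar training patients. AUROC and F1 are the main metrics; precision,
sensitivity and specificity are also reported. The process is repeated
(100 runs in the reference protocol) with the weight-determination
subsample reseeded each run; model A significantly outperforms B when
A's metric is strictly higher in at least 95 of 100 paired runs.

The Euclidean-distance kNN baseline ranks neighbors by Euclidean
distance on z-scored static features: cross-sectional features plus
either zero-padded flattened series or six summary statistics per series
(min, max, mean, SD, skewness, length).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .cohort_model import (
    DOMAINS,
    SEQUENCE_FEATURES,
    Cohort,
    TimePoint,
    ValidationError,
    truncate_cohort,
)
from .cross_sectional_similarity import (
    demographic_similarity_matrix,
    lab_similarity_matrix,
    text_similarity_matrix,
)
from .fusion_knn import (
    FeatureSimilaritySet,
    ModelVariant,
    WeightAssignment,
    _id_rank,
    combined_similarity,
    enumerate_weight_grid_k,
    knn_predict,
    optimize_weights,
    select_dominant_features,
    stratified_subset,
)
from .sequence_similarity import EditCostScheme, sequence_similarity_matrix
from .trend_similarity import HaarConfig, trend_similarity_matrix


def auroc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties 0.5)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def binary_metrics(scores, labels, threshold: float):
    """(F1, precision, sensitivity, specificity) at ``scores >= threshold``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & neg))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & neg))
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity
        else 0.0
    )
    return f1, precision, sensitivity, specificity


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one predictive model."""

    variant: str = "kNN_ED"  # kNN_E/D/H/ED/EH or kNN_Eucli
    outcome: str = "mortality"
    k: int = 50
    grid_step: float = 0.05
    reps: int = 11
    subset_fraction: float = 0.5
    threshold: float | None = None  # None -> training outcome prevalence
    baseline_mode: str = "stats"  # kNN_Eucli input: "flatten" | "stats"
    scheme: EditCostScheme = field(default_factory=EditCostScheme)
    haar: HaarConfig = field(default_factory=HaarConfig)


@dataclass
class RunResult:
    """One evaluation run: per-patient risk scores and summary metrics."""

    run_index: int
    seed: int
    scores: np.ndarray
    labels: np.ndarray
    weights: WeightAssignment | None
    auroc: float
    f1: float
    precision: float
    sensitivity: float
    specificity: float

    def metric(self, name: str) -> float:
        return getattr(self, name)


def compute_feature_similarities(
    cohort: Cohort,
    timepoint: TimePoint | None = None,
    scheme: EditCostScheme | None = None,
    haar: HaarConfig | None = None,
    methods: tuple[str, ...] = ("dtw", "haar"),
) -> FeatureSimilaritySet:
    """All registry feature similarity matrices for a cohort at a time point.

    This is the expensive step (O(n^2) dynamic programs); compute it once
    and reuse it across runs — the matrices do not depend on run seeds.
    """
    if timepoint is not None and cohort.timepoint.label != timepoint.label:
        cohort = truncate_cohort(cohort, timepoint)
    matrices = {}
    for domain in DOMAINS:
        name = SEQUENCE_FEATURES[domain]
        if name in cohort.feature_registry:
            matrices[name] = sequence_similarity_matrix(cohort, domain, scheme)
    for test in cohort.trend_tests():
        for method in methods:
            name = f"S_{method}:{test}"
            if name in cohort.feature_registry:
                matrices[name] = trend_similarity_matrix(cohort, test, method, haar)
    if "S_dem" in cohort.feature_registry:
        matrices["S_dem"] = demographic_similarity_matrix(cohort)
    if "S_lab" in cohort.feature_registry:
        matrices["S_lab"] = lab_similarity_matrix(cohort)
    if "S_text" in cohort.feature_registry:
        if all(p.text_features is not None for p in cohort.patients):
            matrices["S_text"] = text_similarity_matrix(cohort)
    return FeatureSimilaritySet(matrices)


def fit_similarity_model(
    fss: FeatureSimilaritySet,
    labels,
    spec: ModelSpec,
    rng: np.random.Generator,
    train_ids=None,
) -> WeightAssignment:
    """Select dominant features and optimize weights on resampled subsets."""
    variant = ModelVariant(spec.variant)
    pool = variant.pool(fss.feature_names)
    if not pool:
        raise ValidationError(
            f"{spec.variant} has no available feature at this time point"
        )
    n_select = min(3, len(pool))
    if n_select < 3:
        # admission leaves only the cross-sectional features; weight what exists
        dominant = sorted(pool)
        if n_select == 1:
            return WeightAssignment(tuple(dominant), (1.0,))
    else:
        dominant = select_dominant_features(
            fss,
            variant,
            labels,
            k=spec.k,
            reps=spec.reps,
            subset_fraction=spec.subset_fraction,
            seed=rng,
            pool_ids=train_ids,
        )
    weight_ids = stratified_subset(
        np.asarray(labels), spec.subset_fraction, rng, pool=train_ids
    )
    grid = enumerate_weight_grid_k(spec.grid_step, len(dominant))
    return optimize_weights(fss, dominant, labels, spec.k, grid, weight_ids)


def loo_evaluate(
    model_spec: ModelSpec,
    cohort: Cohort,
    timepoint: TimePoint | None = None,
    seed: int = 0,
    fss: FeatureSimilaritySet | None = None,
    run_index: int = 0,
) -> RunResult:
    """One leave-one-out evaluation run of a model over a cohort.

    Temporal-only variants refuse to run at admission (no temporal
    information exists on day 1). At day 7, short-stay patients are
    excluded from the training pool and the weight-determination subsets
    but are still scored. The variability between runs comes from the
    reseeded weight-determination subsample.
    """
    if timepoint is not None and cohort.timepoint.label != timepoint.label:
        cohort = truncate_cohort(cohort, timepoint)
    labels = np.asarray(cohort.outcomes(model_spec.outcome))
    if model_spec.variant == "kNN_Eucli":
        return _loo_evaluate_baseline(model_spec, cohort, labels, seed, run_index)
    if cohort.timepoint.label == "admission" and _is_temporal_only(model_spec.variant):
        raise ValidationError(
            f"{model_spec.variant} uses only temporal similarities; no "
            "temporal information is available at admission"
        )
    if fss is None:
        fss = compute_feature_similarities(
            cohort, scheme=model_spec.scheme, haar=model_spec.haar
        )
    rng = np.random.default_rng(seed)
    train_mask = np.array([not p.excluded for p in cohort.patients])
    train_ids = np.flatnonzero(train_mask)
    wa = fit_similarity_model(fss, labels, model_spec, rng, train_ids=train_ids)
    fused = combined_similarity(fss, wa)
    id_rank = _id_rank(fss.patient_ids)
    scores = np.array(
        [
            knn_predict(fused, labels, i, model_spec.k, train_mask.copy(), id_rank)
            for i in range(len(cohort))
        ]
    )
    return _summarize(model_spec, scores, labels, train_mask, seed, run_index, wa)


def _is_temporal_only(variant: str) -> bool:
    return variant in ("kNN_D", "kNN_H", "kNN_ED", "kNN_EH")


def _summarize(spec, scores, labels, train_mask, seed, run_index, wa) -> RunResult:
    threshold = (
        spec.threshold
        if spec.threshold is not None
        else float(labels[train_mask].mean())
    )
    a = auroc(scores, labels)
    f1, prec, sens, spc = binary_metrics(scores, labels, threshold)
    return RunResult(run_index, seed, scores, labels, wa, a, f1, prec, sens, spc)


# ---------------------------------------------------------------------------
# repeated-run protocol


def multi_run(
    model_spec: ModelSpec,
    cohort: Cohort,
    timepoint: TimePoint | None = None,
    n_runs: int = 100,
    base_seed: int = 0,
    fss: FeatureSimilaritySet | None = None,
) -> tuple[list[RunResult], pd.DataFrame]:
    """Independent repeated runs; run r uses seed base_seed + r.

    Returns the runs and a one-row summary with "mean (SD)" formatted
    metric columns.
    """
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    if timepoint is not None and cohort.timepoint.label != timepoint.label:
        cohort = truncate_cohort(cohort, timepoint)
    if fss is None and model_spec.variant != "kNN_Eucli":
        fss = compute_feature_similarities(
            cohort, scheme=model_spec.scheme, haar=model_spec.haar
        )
    results = [
        loo_evaluate(model_spec, cohort, None, base_seed + r, fss, run_index=r)
        for r in range(n_runs)
    ]
    rows = {}
    for m in ("auroc", "f1", "precision", "sensitivity", "specificity"):
        vals = np.array([res.metric(m) for res in results])
        rows[m] = f"{vals.mean():.3f} ({vals.std(ddof=0):.3f})"
    summary = pd.DataFrame([rows], index=[model_spec.variant])
    return results, summary


@dataclass
class ComparisonMatrix:
    """Pairwise fraction-of-wins between models over paired runs."""

    models: list[str]
    wins: np.ndarray
    significant: np.ndarray
    alpha_wins: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.wins, index=self.models, columns=self.models)


def pairwise_win_matrix(
    results_by_model: dict[str, list[RunResult]], metric: str = "auroc"
) -> ComparisonMatrix:
    """Fraction of paired runs in which the row model strictly beats the column.

    A difference is flagged significant when the row model wins at least
    95% of runs. Ties count for neither model.
    """
    models = list(results_by_model)
    counts = {m: len(results_by_model[m]) for m in models}
    if len(set(counts.values())) > 1:
        raise ValidationError(f"unequal run counts across models: {counts}")
    series = {
        m: np.array([r.metric(metric) for r in results_by_model[m]]) for m in models
    }
    n = len(models)
    wins = np.zeros((n, n))
    for i, a in enumerate(models):
        for j, b in enumerate(models):
            if i != j:
                wins[i, j] = float(np.mean(series[a] > series[b]))
    significant = wins >= 0.95
    np.fill_diagonal(significant, False)
    return ComparisonMatrix(models, wins, significant)


# ---------------------------------------------------------------------------
# Euclidean-distance kNN baseline


def baseline_features(cohort: Cohort, mode: str = "stats") -> pd.DataFrame:
    """Static feature table for the Euclidean-distance kNN baseline.

    ``flatten``: each trend test's series zero-padded to the cohort
    maximum length and concatenated. ``stats``: six statistics per trend
    test — min, max, mean, sample SD, moment skewness (0 for fewer than
    3 values or zero variance), length. Both modes append the
    cross-sectional block: demographics, admission labs (median-imputed),
    text features when extracted, plus a presence flag per trend test.
    """
    if mode not in ("flatten", "stats"):
        raise ValidationError(f"unknown baseline mode {mode!r}")
    tests = cohort.trend_tests()
    cols: dict[str, list[float]] = {}

    def put(name, values):
        cols[name] = values

    for t in tests:
        series = [p.series.get(t) for p in cohort.patients]
        put(f"{t}:present", [1.0 if s else 0.0 for s in series])
        if mode == "flatten":
            max_len = max((len(s) for s in series if s), default=0)
            for j in range(max_len):
                put(
                    f"{t}:v{j}",
                    [
                        float(s.values[j]) if s and j < len(s) else 0.0
                        for s in series
                    ],
                )
        else:
            for stat in ("min", "max", "mean", "sd", "skew", "len"):
                put(f"{t}:{stat}", [_series_stat(s, stat) for s in series])
    for i, name in enumerate(("age_ge60", "male", "married", "insured")):
        put(name, [float(p.demographics.as_tuple()[i]) for p in cohort.patients])
    cross_tests = sorted({t for p in cohort.patients for t in p.cross_labs})
    for t in cross_tests:
        vals = np.array(
            [p.cross_labs.get(t, np.nan) for p in cohort.patients], dtype=float
        )
        if np.isnan(vals).all():
            continue
        vals[np.isnan(vals)] = np.nanmedian(vals)
        put(f"xlab:{t}", list(vals))
    if all(p.text_features is not None for p in cohort.patients) and cohort.patients:
        h = len(cohort.patients[0].text_features)
        for j in range(h):
            put(f"text:{j}", [float(p.text_features[j]) for p in cohort.patients])
    return pd.DataFrame(cols, index=cohort.patient_ids)


def _series_stat(s, stat: str) -> float:
    if s is None:
        return 0.0
    v = np.asarray(s.values, dtype=float)
    if stat == "min":
        return float(v.min())
    if stat == "max":
        return float(v.max())
    if stat == "mean":
        return float(v.mean())
    if stat == "sd":
        return float(v.std(ddof=1)) if v.size > 1 else 0.0
    if stat == "skew":
        if v.size < 3 or np.isclose(v.std(ddof=0), 0.0):
            return 0.0
        return float(stats.skew(v, bias=True))
    return float(v.size)


def euclidean_knn_baseline(
    feature_table: pd.DataFrame,
    labels,
    k: int,
    index_patient: int,
    train_mask=None,
) -> float:
    """kNN risk score with neighbors ranked by Euclidean distance on z-scores."""
    X = feature_table.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    labels = np.asarray(labels)
    n = Z.shape[0]
    mask = np.ones(n, dtype=bool) if train_mask is None else np.asarray(train_mask).copy()
    mask[index_patient] = False
    cand = np.flatnonzero(mask)
    if k > cand.size:
        raise ValidationError(f"k={k} exceeds training pool of {cand.size}")
    dist = np.linalg.norm(Z[cand] - Z[index_patient], axis=1)
    id_rank = _id_rank(list(feature_table.index))
    order = np.lexsort((id_rank[cand], dist))
    top = cand[order[:k]]
    return float(labels[top].sum() / k)


def _loo_evaluate_baseline(spec, cohort, labels, seed, run_index) -> RunResult:
    table = baseline_features(cohort, spec.baseline_mode)
    train_mask = np.array([not p.excluded for p in cohort.patients])
    scores = np.array(
        [
            euclidean_knn_baseline(table, labels, spec.k, i, train_mask.copy())
            for i in range(len(cohort))
        ]
    )
    return _summarize(spec, scores, labels, train_mask, seed, run_index, None)
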