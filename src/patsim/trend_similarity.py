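"""Trend similarity between lab-test time series: DTW and Haar routes.

Lab series in EMR data have unequal lengths and uneven sampling, so two
distances that tolerate this are provided. Dynamic time warping aligns
the two value lists along a monotone warping path with per-step cost
|a - b| and returns the cumulative distance of the optimal path. The
Haar route first resamples each series to a common dyadic length by
linear interpolation, applies the orthonormal discrete Haar transform,
truncates to the coarsest coefficient levels (the dimension reduction
that summarizes level and trend), and takes the Euclidean distance
between the retained coefficients.

Cohort-level distances D are converted to similarities by min-max over
the available off-diagonal pairs: ``S = (d_max - D) / (d_max - d_min)``,
mirroring the "1 - normalized Euclidean distance" convention used for
cross-sectional labs. d_min/d_max are recomputed per test, per method,
and per index time point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .cohort_model import Cohort, LabTimeSeries, ValidationError
from .matrices import DistanceMatrix, SimilarityMatrix


@dataclass(frozen=True)
class HaarConfig:
    """Resampling length (power of two) and retained coefficient levels.

    ``keep_levels`` counts coefficient groups coarsest-first: the
    approximation level, then detail levels from coarsest down. The
    default (target_length 8, keep_levels 3) keeps the approximation and
    the two coarsest detail levels — 4 of 8 coefficients.
    """

    target_length: int = 8
    keep_levels: int = 3

    def __post_init__(self) -> None:
        L = int(np.log2(self.target_length))
        if 2**L != self.target_length or L < 1:
            raise ValidationError("target_length must be a power of two >= 2")
        if not 1 <= self.keep_levels <= L + 1:
            raise ValidationError("keep_levels out of range")


def dtw_distance(s1, s2) -> float:
    """Cumulative DTW distance between two value lists (|a-b| step cost).

    Unit step set {(1,0),(0,1),(1,1)}, endpoints aligned, no window
    constraint and no path-length normalization.
    """
    a = np.asarray(getattr(s1, "values", s1), dtype=float)
    b = np.asarray(getattr(s2, "values", s2), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("DTW requires nonempty series")
    n, m = a.size, b.size
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        cost = np.abs(a[i - 1] - b)
        for j in range(1, m + 1):
            D[i, j] = cost[j - 1] + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    return float(D[n, m])


def haar_interpolate(s, target_length: int = 8) -> np.ndarray:
    """Piecewise-linear resampling of the value list to ``target_length``.

    Positions are equally spaced over the observation index (first to
    last value); endpoints are preserved exactly.
    """
    v = np.asarray(getattr(s, "values", s), dtype=float)
    if v.size < 2:
        raise ValidationError("interpolation needs >= 2 values (not a trend feature)")
    x = np.linspace(0.0, v.size - 1.0, target_length)
    return np.interp(x, np.arange(v.size), v)


def haar_decompose(v: np.ndarray, keep_levels: int | None = None) -> np.ndarray:
    """Orthonormal discrete Haar transform, coarsest coefficients first.

    Input length must be a power of two. With ``keep_levels`` set, only
    that many coefficient groups (approximation, then detail levels from
    coarsest) are returned; energy is preserved before truncation.
    """
    v = np.asarray(v, dtype=float)
    L = int(np.log2(v.size))
    if 2**L != v.size:
        raise ValidationError("Haar transform requires power-of-two length")
    coeffs = pywt.wavedec(v, "haar", level=L)  # [cA_L, cD_L, ..., cD_1]
    if keep_levels is not None:
        coeffs = coeffs[:keep_levels]
    return np.concatenate(coeffs)


def haar_distance(s1, s2, config: HaarConfig | None = None) -> float:
    """Euclidean distance between retained Haar coefficients of two series."""
    config = config or HaarConfig()
    c1 = haar_decompose(haar_interpolate(s1, config.target_length), config.keep_levels)
    c2 = haar_decompose(haar_interpolate(s2, config.target_length), config.keep_levels)
    return float(np.linalg.norm(c1 - c2))


def distances_to_similarity(dm: DistanceMatrix) -> SimilarityMatrix:
    """Min-max conversion of a distance matrix to similarities in [0, 1].

    d_min/d_max are taken over available off-diagonal pairs. If all
    pairwise distances are equal the available pairs get similarity 1.
    Pairs involving an unavailable patient get similarity 0 (flagged via
    the availability mask); the diagonal is 1.
    """
    avail = dm.available
    n = len(dm.patient_ids)
    if avail.sum() < 2:
        raise ValidationError(f"test {dm.test_id!r}: no available pair")
    mask = np.outer(avail, avail)
    off = mask & ~np.eye(n, dtype=bool)
    d = dm.values[off]
    d_min, d_max = d.min(), d.max()
    S = np.zeros((n, n))
    if d_max > d_min:
        S[off] = (d_max - dm.values[off]) / (d_max - d_min)
    else:
        S[off] = 1.0
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(dm.patient_ids, S, available=avail.copy())


def trend_distance_matrix(
    cohort: Cohort, test_id: str, method: str, config: HaarConfig | None = None
) -> DistanceMatrix:
    """Pairwise DTW or Haar distances for one registered trend test."""
    if method not in ("dtw", "haar"):
        raise ValidationError(f"unknown trend method {method!r}")
    if test_id not in cohort.trend_tests():
        raise ValidationError(f"test {test_id!r} is not a registered trend feature")
    series = [
        p.series.get(test_id) if p.series.get(test_id) is not None else None
        for p in cohort.patients
    ]
    avail = np.array([s is not None and s.is_trend for s in series])
    n = len(cohort)
    D = np.zeros((n, n))
    if method == "haar":
        config = config or HaarConfig()
        coeffs = [
            haar_decompose(
                haar_interpolate(s, config.target_length), config.keep_levels
            )
            if ok
            else None
            for s, ok in zip(series, avail)
        ]
        idx = np.flatnonzero(avail)
        C = np.array([coeffs[i] for i in idx])
        diff = np.linalg.norm(C[:, None, :] - C[None, :, :], axis=2)
        D[np.ix_(idx, idx)] = diff
    else:
        idx = np.flatnonzero(avail)
        for ii, i in enumerate(idx):
            for j in idx[ii + 1:]:
                D[i, j] = D[j, i] = dtw_distance(series[i], series[j])
    return DistanceMatrix(test_id, cohort.patient_ids, D, avail)


def trend_similarity_matrix(
    cohort: Cohort, test_id: str, method: str, config: HaarConfig | None = None
) -> SimilarityMatrix:
    """Distance matrix for (test, method) followed by min-max normalization."""
    return distances_to_similarity(
        trend_distance_matrix(cohort, test_id, method, config)
    )
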