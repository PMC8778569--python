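"""Cross-sectional similarities: demographics, admission labs, report text.

Demographics (four binary indicators) and extracted text features are
compared with Jaccard similarity over the positive indicators. Admission
-only lab panels are compared as 1 minus the min-max-normalized
Euclidean distance: each test is min-max scaled across the cohort,
pairwise Euclidean distances are taken on the scaled panels, and the
distances are min-max normalized over off-diagonal pairs. Text features
are binary phrase-presence indicators from a user-supplied lexicon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort_model import Cohort, ValidationError
from .matrices import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TextLexicon:
    """Ordered feature phrases matched case-insensitively as substrings."""

    phrases: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.phrases)) != len(self.phrases) or not all(self.phrases):
            raise ValidationError("lexicon phrases must be unique and nonempty")

    def __len__(self) -> int:
        return len(self.phrases)

    @classmethod
    def from_file(cls, path) -> "TextLexicon":
        with open(path) as fh:
            phrases = tuple(line.strip() for line in fh if line.strip())
        return cls(phrases)


def jaccard_similarity(u1, u2) -> float:
    """|intersection| / |union| of positive indicators; both-empty -> 1."""
    a = np.asarray(u1, dtype=bool)
    b = np.asarray(u2, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("jaccard requires equal-length vectors")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def extract_text_features(report_text: str, lexicon: TextLexicon) -> tuple[int, ...]:
    """Binary vector: 1 where the lexicon phrase occurs in the report."""
    text = (report_text or "").lower()
    return tuple(int(p.lower() in text) for p in lexicon.phrases)


def apply_lexicon(cohort: Cohort, lexicon: TextLexicon) -> None:
    """Populate every patient's text_features from its report text."""
    for p in cohort.patients:
        p.text_features = extract_text_features(p.report_text, lexicon)


def _jaccard_matrix(ids: list[str], vectors: np.ndarray) -> SimilarityMatrix:
    n = len(ids)
    S = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = jaccard_similarity(vectors[i], vectors[j])
    return SimilarityMatrix(ids, S)


def demographic_similarity_matrix(cohort: Cohort) -> SimilarityMatrix:
    """Pairwise Jaccard similarity on the four binary demographics (S_dem)."""
    vectors = np.array([p.demographics.as_tuple() for p in cohort.patients])
    return _jaccard_matrix(cohort.patient_ids, vectors)


def text_similarity_matrix(
    cohort: Cohort, lexicon: TextLexicon | None = None
) -> SimilarityMatrix:
    """Pairwise Jaccard similarity on extracted text features (S_text)."""
    if lexicon is not None:
        apply_lexicon(cohort, lexicon)
    if any(p.text_features is None for p in cohort.patients):
        raise ValidationError("text features not extracted; provide a lexicon")
    vectors = np.array([p.text_features for p in cohort.patients])
    return _jaccard_matrix(cohort.patient_ids, vectors)


def lab_similarity_matrix(cohort: Cohort) -> SimilarityMatrix:
    """Admission-lab similarity (S_lab): 1 - min-max-normalized Euclidean.

    Missing values are imputed by the cohort median of the test;
    constant tests carry no distance information and are dropped with a
    warning. With all pairwise distances equal (e.g. a single pair of
    identical panels) every pair gets similarity 1.
    """
    tests = sorted({t for p in cohort.patients for t in p.cross_labs})
    if not tests:
        raise ValidationError("no cross-sectional lab registered")
    n = len(cohort)
    X = np.full((n, len(tests)), np.nan)
    for i, p in enumerate(cohort.patients):
        for j, t in enumerate(tests):
            if t in p.cross_labs:
                X[i, j] = p.cross_labs[t]
    keep = []
    for j, t in enumerate(tests):
        col = X[:, j]
        if np.isnan(col).all():
            continue
        med = np.nanmedian(col)
        col[np.isnan(col)] = med
        lo, hi = col.min(), col.max()
        if hi == lo:
            logger.warning("cross-sectional test %r constant; dropped", t)
            continue
        X[:, j] = (col - lo) / (hi - lo)
        keep.append(j)
    if not keep:
        raise ValidationError("no usable (non-constant) cross-sectional test")
    Z = X[:, keep]
    diff = Z[:, None, :] - Z[None, :, :]
    D = np.linalg.norm(diff, axis=2)
    off = ~np.eye(n, dtype=bool)
    d_min, d_max = D[off].min(), D[off].max()
    S = np.ones((n, n))
    if d_max > d_min:
        S[off] = 1.0 - (D[off] - d_min) / (d_max - d_min)
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(cohort.patient_ids, S)
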