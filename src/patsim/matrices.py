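"""Symmetric pairwise matrix containers shared by the similarity modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_model import ValidationError


@dataclass
class SimilarityMatrix:
    """Symmetric patient-by-patient similarity in [0, 1], unit diagonal.

    ``available`` marks patients for whom the underlying feature exists;
    rows/columns of unavailable patients are 0 off-diagonal so that an
    absent repeated test reads as maximal dissimilarity.
    """

    patient_ids: list[str]
    values: np.ndarray
    available: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.patient_ids)
        if self.values.shape != (n, n):
            raise ValidationError("matrix shape must match patient count")
        if self.available is None:
            self.available = np.ones(n, dtype=bool)
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("similarity matrix must be symmetric")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValidationError("similarities must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.values, index=self.patient_ids, columns=self.patient_ids
        ).to_csv(path, index_label="patient_id")

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances for one lab test, with availability."""

    test_id: str
    patient_ids: list[str]
    values: np.ndarray
    available: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.available = np.asarray(self.available, dtype=bool)
        n = len(self.patient_ids)
        if self.values.shape != (n, n) or self.available.shape != (n,):
            raise ValidationError("distance matrix shape mismatch")
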