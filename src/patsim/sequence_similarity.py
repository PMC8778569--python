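"""Edit distance between timestamped clinical event sequences.

Two event sequences are compared by the minimum total cost of edit
operations transforming one into the other. Insertion and deletion of an
event cost 1 each; substitution — changing the occurrence day of the
*same* event code from t_i to t_j — costs ``sub_rate * |t_i - t_j|``
(default 0.5 per day). Substitution between different codes is not an
operation: unlike string edit distance, a glucose test cannot be
"rewritten" into an echocardiogram, only removed and the other inserted.

The minimization is solved by dynamic programming over order-preserving
alignments. The distance M is converted to a similarity
``S = 1 - M / (m + n)`` where m, n are the sequence lengths: m + n is
the cost of the always-available delete-all/insert-all series under unit
costs, so S lies in [0, 1].

An alternative ``forced_substitution`` mode mandates that occurrences of
a code present in both sequences are matched (in temporal order) and
substituted, with only surplus occurrences inserted or deleted; it gives
a cost that is never below the free DP minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_model import Cohort, EventSequence, ValidationError
from .matrices import SimilarityMatrix


@dataclass(frozen=True)
class EditCostScheme:
    """Costs of the three edit operations; substitution is per day shifted."""

    ins_cost: float = 1.0
    del_cost: float = 1.0
    sub_rate: float = 0.5
    forced_substitution: bool = False

    def __post_init__(self) -> None:
        if min(self.ins_cost, self.del_cost, self.sub_rate) < 0:
            raise ValidationError("edit costs must be nonnegative")


@dataclass(frozen=True)
class EditOperation:
    """One edit step. Sub carries both days; Ins/Del carry one."""

    kind: str  # "Ins" | "Del" | "Sub"
    code: str
    source_day: int | None = None  # t_i for Del/Sub
    target_day: int | None = None  # t_j for Ins/Sub

    def cost(self, scheme: EditCostScheme) -> float:
        if self.kind == "Ins":
            return scheme.ins_cost
        if self.kind == "Del":
            return scheme.del_cost
        if self.kind == "Sub":
            return scheme.sub_rate * abs(self.source_day - self.target_day)
        raise ValidationError(f"unknown operation kind {self.kind!r}")


@dataclass
class OperationSeries:
    """An ordered series of edit operations with its total cost."""

    operations: list[EditOperation] = field(default_factory=list)
    total_cost: float = 0.0


def operation_series_cost(ops: OperationSeries, scheme: EditCostScheme) -> float:
    """Total cost of an operation series under a cost scheme."""
    return float(sum(op.cost(scheme) for op in ops.operations))


def edit_distance(
    r1: EventSequence, r2: EventSequence, scheme: EditCostScheme | None = None
) -> tuple[float, OperationSeries]:
    """Minimum-cost transformation of r1 into r2, with a realizing trace.

    Returns ``(M, trace)``. The DP is the classic sequence-alignment
    recurrence with substitution permitted only between identical codes;
    in ``forced_substitution`` mode the per-code matching described in
    the module docstring is used instead.
    """
    scheme = scheme or EditCostScheme()
    if scheme.forced_substitution:
        return _forced_substitution_distance(r1, r2, scheme)

    a, b = r1.events, r2.events
    m, n = len(a), len(b)
    M = np.empty((m + 1, n + 1))
    M[:, 0] = np.arange(m + 1) * scheme.del_cost
    M[0, :] = np.arange(n + 1) * scheme.ins_cost
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            bj = b[j - 1]
            best = min(M[i - 1, j] + scheme.del_cost, M[i, j - 1] + scheme.ins_cost)
            if ai.code == bj.code:
                sub = M[i - 1, j - 1] + scheme.sub_rate * abs(ai.day - bj.day)
                if sub < best:
                    best = sub
            M[i, j] = best

    # backtrack; tie preference Sub > Del > Ins for a deterministic trace
    ops: list[EditOperation] = []
    i, j = m, n
    eps = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0 and a[i - 1].code == b[j - 1].code:
            sub = scheme.sub_rate * abs(a[i - 1].day - b[j - 1].day)
            if abs(M[i, j] - (M[i - 1, j - 1] + sub)) < eps:
                ops.append(
                    EditOperation("Sub", a[i - 1].code, a[i - 1].day, b[j - 1].day)
                )
                i, j = i - 1, j - 1
                continue
        if i > 0 and abs(M[i, j] - (M[i - 1, j] + scheme.del_cost)) < eps:
            ops.append(EditOperation("Del", a[i - 1].code, source_day=a[i - 1].day))
            i -= 1
            continue
        ops.append(EditOperation("Ins", b[j - 1].code, target_day=b[j - 1].day))
        j -= 1
    ops.reverse()
    return float(M[m, n]), OperationSeries(ops, float(M[m, n]))


def _forced_substitution_distance(
    r1: EventSequence, r2: EventSequence, scheme: EditCostScheme
) -> tuple[float, OperationSeries]:
    """Per-code matching: shared codes must be substituted, not re-created.

    The k-th occurrence (in temporal order) of each code in r1 is matched
    to the k-th occurrence in r2 and substituted; surplus occurrences are
    deleted or inserted.
    """
    by_code_1: dict[str, list[int]] = {}
    by_code_2: dict[str, list[int]] = {}
    for e in r1.events:
        by_code_1.setdefault(e.code, []).append(e.day)
    for e in r2.events:
        by_code_2.setdefault(e.code, []).append(e.day)

    ops: list[EditOperation] = []
    for code in sorted(set(by_code_1) | set(by_code_2)):
        d1 = by_code_1.get(code, [])
        d2 = by_code_2.get(code, [])
        k = min(len(d1), len(d2))
        for t1, t2 in zip(d1[:k], d2[:k]):
            ops.append(EditOperation("Sub", code, t1, t2))
        for t1 in d1[k:]:
            ops.append(EditOperation("Del", code, source_day=t1))
        for t2 in d2[k:]:
            ops.append(EditOperation("Ins", code, target_day=t2))
    series = OperationSeries(ops)
    series.total_cost = operation_series_cost(series, scheme)
    return series.total_cost, series


def sequence_similarity(
    r1: EventSequence, r2: EventSequence, scheme: EditCostScheme | None = None
) -> float:
    """Bounded similarity ``1 - M/(m+n)``; two empty sequences are identical."""
    m, n = r1.m, r2.m
    if m + n == 0:
        return 1.0
    M, _ = edit_distance(r1, r2, scheme)
    return 1.0 - M / (m + n)


def sequence_similarity_matrix(
    cohort: Cohort, domain: str, scheme: EditCostScheme | None = None
) -> SimilarityMatrix:
    """Pairwise sequence similarity over a cohort for one event domain."""
    if domain not in ("lab", "rad", "pro"):
        raise ValidationError(f"unknown domain {domain!r}")
    n = len(cohort)
    S = np.ones((n, n))
    seqs = [p.sequences[domain] for p in cohort.patients]
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = sequence_similarity(seqs[i], seqs[j], scheme)
    return SimilarityMatrix(cohort.patient_ids, S)
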