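import numpy as np
import pytest

import patsim as ps


@pytest.fixture(scope="session")
def small_cohort():
    """30-patient synthetic cohort shared by fast tests."""
    return ps.generate_cohort(ps.GeneratorConfig(n_patients=30, seed=3))


@pytest.fixture(scope="session")
def worked_pair():
    return ps.generate_worked_example()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, max_len=5, vocab="ABC", max_day=9, domain="pro"):
    n = int(rng.integers(0, max_len + 1))
    raw = [
        (vocab[rng.integers(len(vocab))], int(rng.integers(1, max_day + 1)))
        for _ in range(n)
    ]
    return ps.build_event_sequence(raw, domain)


def brute_force_edit_distance(r1, r2, scheme=None):
    """Independent oracle: plain recursion over all monotone operation series."""
    scheme = scheme or ps.EditCostScheme()
    a, b = r1.events, r2.events

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0.0
        best = np.inf
        if i < len(a):
            best = min(best, scheme.del_cost + rec(i + 1, j))
        if j < len(b):
            best = min(best, scheme.ins_cost + rec(i, j + 1))
        if i < len(a) and j < len(b) and a[i].code == b[j].code:
            best = min(
                best, scheme.sub_rate * abs(a[i].day - b[j].day) + rec(i + 1, j + 1)
            )
        return best

    return rec(0, 0)


def brute_force_dtw(a, b):
    """Independent oracle: enumerate all monotone warping paths recursively."""
    def rec(i, j):
        cost = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return cost
        best = np.inf
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        return cost + best

    return rec(len(a) - 1, len(b) - 1)


def naive_auroc(scores, labels):
    """Independent O(n^2) pairwise oracle with half-credit ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
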