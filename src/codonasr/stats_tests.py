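"""Permutation statistics for ordinal hypersensitive-response (HR) scores.

Leaf infiltration assays score cell death on a 0 (no necrosis) to 7
(confluent necrosis) scale.  Group comparisons use a two-sided permutation
test with the difference between the two group means as the test statistic:
labels are permuted without replacement, and the Monte-Carlo p-value carries
the +1 small-sample correction so it is never exactly zero.  An exact
enumeration over all label assignments serves as the oracle for small
groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np

_TIE_EPS = 1e-12

SCORE_MIN, SCORE_MAX = 0, 7


@dataclass
class HRScoreDataset:
    """Ordinal 0–7 HR scores keyed by treatment label."""

    groups: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for label, scores in self.groups.items():
            arr = np.asarray(scores, dtype=int)
            if arr.size == 0:
                raise ValueError(f"group {label!r} is empty")
            if np.any(arr < SCORE_MIN) or np.any(arr > SCORE_MAX):
                raise ValueError(f"group {label!r} has scores outside {SCORE_MIN}..{SCORE_MAX}")
            clean[label] = arr
        self.groups = clean

    def __getitem__(self, label: str) -> np.ndarray:
        return self.groups[label]


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistic and p-value of a two-group permutation test."""

    t_obs: float
    p: float
    B: int
    seed: int | None
    method: str  # "monte_carlo" or "exact"

    def __post_init__(self) -> None:
        if not 0 < self.p <= 1:
            raise ValueError(f"p-value {self.p} outside (0, 1]")


def permutation_test(
    a: Sequence[float],
    b: Sequence[float],
    B: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Two-sided Monte-Carlo permutation test on the difference of means.

    ``B`` label permutations are drawn without replacement, independently
    across replicates; the two-sided p-value is
    ``(#{|T*| >= |T_obs|} + 1) / (B + 1)`` with a 1e-12 tolerance on the
    comparison to absorb floating-point ties.  Reproducible given ``seed``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if B < 1:
        raise ValueError("B must be >= 1")
    t_obs = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    rng = np.random.default_rng(seed)
    # vectorised label permutations: argsort of uniform draws
    order = np.argsort(rng.random((B, n)), axis=1)
    perm_a = pooled[order[:, :n_a]]
    t_star = perm_a.mean(axis=1) * (n / (n - n_a)) - pooled.sum() / (n - n_a)
    # identity: mean(a*) - mean(b*) where b* is the complement of a*
    hits = int(np.count_nonzero(np.abs(t_star) >= abs(t_obs) - _TIE_EPS))
    p = (hits + 1) / (B + 1)
    return PermutationResult(t_obs=t_obs, p=p, B=B, seed=seed, method="monte_carlo")


def exact_permutation_p(
    a: Sequence[float],
    b: Sequence[float],
    max_assignments: int = 10**6,
) -> PermutationResult:
    """Exact two-sided permutation p by full enumeration.

    Enumerates every distinct assignment of the pooled observations to the
    first group; ``p = #{|T*| >= |T_obs|} / C(n, n_a)`` with no +1 term.
    Refuses datasets whose assignment count exceeds ``max_assignments``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    total = comb(n, n_a)
    if total > max_assignments:
        raise ValueError(f"C({n},{n_a}) = {total} exceeds the enumeration bound")
    t_obs = float(a.mean() - b.mean())
    pooled_sum = pooled.sum()
    hits = 0
    for idx in combinations(range(n), n_a):
        sum_a = pooled[list(idx)].sum()
        t = sum_a / n_a - (pooled_sum - sum_a) / (n - n_a)
        if abs(t) >= abs(t_obs) - _TIE_EPS:
            hits += 1
    return PermutationResult(
        t_obs=t_obs, p=hits / total, B=total, seed=None, method="exact"
    )
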