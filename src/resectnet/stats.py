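"""Group-comparison statistics for cohort demographics and change metrics:
seeded permutation tests on the difference of means, uncorrected Pearson
chi-square on 2x2 tables, and Kruskal-Wallis on continuous variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

__all__ = [
    "PermutationTestResult",
    "ChiSquareResult",
    "permutation_test_mean_diff",
    "chi_square_2x2",
    "kruskal_wallis",
]


@dataclass
class PermutationTestResult:
    observed_diff: float
    n_permutations: int
    p_value: float
    seed: int | None


@dataclass
class ChiSquareResult:
    table: np.ndarray
    statistic: float
    p_value: float


def permutation_test_mean_diff(group1, group2, n_permutations: int = 10_000, seed: int | None = None) -> PermutationTestResult:
    """Two-sided permutation test for a difference between group means.

    Labels are shuffled ``n_permutations`` times with a seeded generator;
    the p-value uses the add-one correction
    p = (1 + #{|T_perm| >= |T_obs|}) / (N + 1), so p is never exactly 0.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    observed = float(g1.mean() - g2.mean())
    pooled = np.concatenate([g1, g2])
    n1 = g1.size
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        t = perm[:n1].mean() - perm[n1:].mean()
        if abs(t) >= abs(observed) - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return PermutationTestResult(observed_diff=observed, n_permutations=n_permutations, p_value=p, seed=seed)


def chi_square_2x2(table) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal")
    stat, p, _, _ = scipy.stats.chi2_contingency(t, correction=False)
    return ChiSquareResult(table=t, statistic=float(stat), p_value=float(p))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square(k-1).

    All-identical data across groups gives (H=0, p=1) rather than an error.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size == 0 for a in arrs):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*arrs)
    return float(h), float(p)
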