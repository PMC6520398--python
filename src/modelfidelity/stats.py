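"""Shared statistical primitives.

Every downstream stage funnels through the four primitives here: Spearman
rank correlation, the binomial upper-tail probability used by the
differential-mutation test, Benjamini-Hochberg FDR adjustment, and the
Wilcoxon rank-sum test. Keeping them in one module means every stage uses
identical tie handling (average ranks throughout) and identical tail
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import DegenerateDataError, DomainError

__all__ = [
    "TestResult",
    "spearman",
    "binomial_upper_tail",
    "benjamini_hochberg",
    "wilcoxon_rank_sum",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample test.

    ``direction`` is ``"a>b"`` / ``"b>a"`` / ``"none"`` for tests that report
    which group sits higher (sign of the difference of group medians), and
    ``None`` for tests that do not.
    """

    statistic: float
    p_value: float
    direction: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise DomainError(f"p_value {self.p_value} outside [0, 1]")


def spearman(x, y) -> float:
    """Spearman rank correlation with average-rank ties.

    Missing values (NaN) are removed pairwise before the length check.
    Equals the Pearson correlation of the average-ranked vectors.

    Raises
    ------
    DegenerateDataError
        If fewer than 3 complete pairs remain or either vector is constant
        after pairwise removal (the correlation is undefined; callers that
        aggregate over many vectors may catch this and skip).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError(f"expected equal-length 1-d vectors, got {x.shape} and {y.shape}")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise DegenerateDataError(f"need >=3 complete pairs, have {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("correlation undefined for a constant vector")
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    return float(np.corrcoef(rx, ry)[0, 1])


def binomial_upper_tail(n: int, N: int, q: float, inclusive: bool = False) -> float:
    """Upper-tail binomial probability for an observed mutated-sample count.

    With ``inclusive=False`` (default) returns ``P(X > n) = 1 - sum_{i<=n} Pr(i; N, q)``,
    i.e. the observed count itself is excluded from the tail. ``inclusive=True``
    switches to the conventional ``P(X >= n)``. Computed through the survival
    function of :mod:`scipy.stats`, which is numerically stable for large N.

    Raises
    ------
    DomainError
        If ``q`` is outside the open interval (0, 1) or ``n`` outside [0, N].
    """
    if not (0 < q < 1):
        raise DomainError(f"reference frequency q={q} outside (0, 1)")
    if not (0 <= n <= N):
        raise DomainError(f"count n={n} outside [0, N={N}]")
    k = n - 1 if inclusive else n
    return float(sps.binom.sf(k, N, q))


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Standard step-up: sort ascending, multiply by m/rank, take the running
    minimum from the largest p downwards, clip at 1. Input order is
    preserved in the output; the adjustment is monotone in p.

    Raises
    ------
    DomainError
        If any entry lies outside [0, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise DomainError("expected a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        bad = int(np.flatnonzero(np.isnan(p) | (p < 0) | (p > 1))[0])
        raise DomainError(f"p-value at position {bad} outside [0, 1]: {p[bad]}")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


def wilcoxon_rank_sum(a, b, alternative: str = "two_sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test with average-rank ties.

    For small groups (min size < 8) the p-value comes from exact
    enumeration of rank assignments; otherwise from the normal
    approximation with tie and continuity corrections. The reported
    statistic is the Mann-Whitney U of group ``a``; ``direction`` carries
    the sign of ``median(a) - median(b)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if alternative not in _ALTERNATIVES:
        raise DomainError(f"unknown alternative {alternative!r}")
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError(
            f"each group needs >=2 observations, have {a.size} and {b.size}"
        )
    method = "exact" if min(a.size, b.size) < 8 else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative=_ALTERNATIVES[alternative], method=method, use_continuity=True
    )
    diff = float(np.median(a) - np.median(b))
    direction = "a>b" if diff > 0 else ("b>a" if diff < 0 else "none")
    return TestResult(
        statistic=float(res.statistic), p_value=min(float(res.pvalue), 1.0), direction=direction
    )
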