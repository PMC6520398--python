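"""Fitted-null significance calling for model similarities.

Within a stratum (e.g. one tumor subtype), the similarity scores of a large
background panel of off-lineage models are approximately normal; a normal
null fitted to that background converts each candidate model's similarity
into a right-tailed p-value, and Benjamini-Hochberg over the candidate
family yields FDR-based significance calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateDataError, DomainError
from .stats import TestResult, benjamini_hochberg, wilcoxon_rank_sum

__all__ = [
    "NullModel",
    "fit_null",
    "right_tail_p",
    "evaluate_models",
    "compare_model_classes",
]


@dataclass(frozen=True)
class NullModel:
    """Normal null over background-model similarities."""

    mu: float
    sigma: float
    n_background: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DegenerateDataError(f"sigma must be positive, got {self.sigma}")
        if self.n_background < 3:
            raise DegenerateDataError("null fit needs >=3 background values")


def fit_null(background_similarities, robust: bool = False) -> NullModel:
    """Fit the normal null to background similarities.

    Default is moment matching: sample mean and sample standard deviation
    (n-1 denominator). ``robust=True`` switches to median and
    normal-consistent MAD (MAD / 0.6745).
    """
    x = np.asarray(background_similarities, dtype=float)
    if x.size < 3:
        raise DegenerateDataError(f"null fit needs >=3 values, have {x.size}")
    if np.all(x == x[0]):
        raise DegenerateDataError("all background similarities are equal")
    if robust:
        mu = float(np.median(x))
        sigma = float(np.median(np.abs(x - mu)) / sps.norm.ppf(0.75))
    else:
        mu = float(np.mean(x))
        sigma = float(np.std(x, ddof=1))
    return NullModel(mu=mu, sigma=sigma, n_background=int(x.size))


def right_tail_p(similarity: float, null: NullModel) -> float:
    """Right-tailed normal p-value: 1 - Phi((s - mu) / sigma)."""
    return float(sps.norm.sf((similarity - null.mu) / null.sigma))


def evaluate_models(
    candidates: pd.DataFrame,
    background: pd.DataFrame,
    fdr_levels: tuple[float, float] = (0.01, 0.05),
    robust: bool = False,
) -> pd.DataFrame:
    """Per-stratum significance calls for candidate models.

    ``candidates`` and ``background`` are similarity tables with columns
    ``model``, ``stratum``, ``similarity`` (the output layout of the
    stratified TC analysis); the two model sets must be disjoint. For each
    stratum the null is fitted on the background similarities, every
    candidate receives a right-tailed p-value, and BH is applied over the
    candidates of that stratum only. Significance flags use ``q <= level``.
    """
    lo, hi = sorted(fdr_levels)
    overlap = set(candidates["model"]) & set(background["model"])
    if overlap:
        raise DomainError(f"candidate and background sets overlap: {sorted(overlap)[0]!r}")
    rows = []
    for stratum, cand in candidates.groupby("stratum", sort=True):
        bg = background.loc[background["stratum"] == stratum, "similarity"]
        null = fit_null(bg.to_numpy(), robust=robust)
        cand = cand.sort_values("model", kind="stable")
        p = np.array([right_tail_p(s, null) for s in cand["similarity"]])
        q = benjamini_hochberg(p)
        for (_, row), pi, qi in zip(cand.iterrows(), p, q):
            rows.append(
                {
                    "model": row["model"],
                    "stratum": stratum,
                    "similarity": float(row["similarity"]),
                    "p_right": float(pi),
                    "q": float(qi),
                    f"significant_at_{lo}": bool(qi <= lo),
                    f"significant_at_{hi}": bool(qi <= hi),
                    "null_mu": null.mu,
                    "null_sigma": null.sigma,
                    "n_background": null.n_background,
                }
            )
    return pd.DataFrame(rows)


def compare_model_classes(a, b) -> TestResult:
    """Two-sided rank-sum comparison of two model classes' similarity (or
    per-sample correlation) values, with the direction of the median
    difference. Also serves pairwise model contrasts (one model's
    per-sample correlation distribution against another's)."""
    return wilcoxon_rank_sum(np.asarray(a, float), np.asarray(b, float), "two_sided")
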