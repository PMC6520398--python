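"""Single-sample gene-set activity scoring and differential-activity (DA)
analysis.

The activity score is the single-sample enrichment running-sum integral:
genes are ordered by decreasing expression, the weighted ECDF of in-set
genes (weights = rank magnitude ** alpha) is stepped against the uniform
ECDF of out-of-set genes, and the score is the sum of the differences over
all positions. Being rank-based, scores are invariant to monotone
transforms of expression. DA between a tumor cohort and a model class is a
per-set two-sided rank-sum test with BH adjustment across the collection;
the two model-class comparisons are then folded into a four-category
classification (organoid-only / cell-line-only / both / neither
significant).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import read_gmt, write_gmt  # re-exported for convenience
from .exceptions import DegenerateDataError, DomainError
from .stats import benjamini_hochberg, wilcoxon_rank_sum

logger = logging.getLogger("modelfidelity")

__all__ = [
    "read_gmt",
    "write_gmt",
    "ssgsea_score",
    "score_matrix",
    "differential_activity",
    "categorize",
    "consensus_categories",
    "intersect_de_lists",
]


def ssgsea_score(
    sample_expression: pd.Series,
    gene_set: Sequence[str],
    alpha: float = 0.25,
) -> float:
    """Single-sample enrichment score of one gene set in one sample.

    Parameters
    ----------
    sample_expression
        Expression vector indexed by gene.
    gene_set
        Gene identifiers; members absent from the vector are ignored, but
        at least one must be present.
    alpha
        Weight exponent on the rank magnitude (0.25 is the method's
        canonical default; 0 gives the unweighted Kolmogorov-Smirnov-like
        walk).

    Ties in expression get average rank magnitudes; the walking order among
    tied genes is fixed by gene identifier, which leaves the score
    deterministic (and, for average-rank weights, order-independent within
    a tie block up to the uniform step).
    """
    x = sample_expression.astype(float)
    members = set(gene_set) & set(x.index)
    if not members:
        raise DomainError(
            f"no member of the gene set is present in the sample (set size {len(set(gene_set))})"
        )
    values = x.to_numpy()
    if np.all(values == values[0]):
        raise DegenerateDataError("sample expression vector is constant")
    n_out = len(x) - len(members)
    if n_out == 0:
        raise DomainError("gene set covers every gene; no out-of-set ECDF exists")
    # rank magnitude: highest expression -> G, average ranks for ties
    magnitude = sps.rankdata(values, method="average")
    # walk order: decreasing expression, ties broken by gene id
    order = np.lexsort((x.index.to_numpy(), -values))
    in_set = np.fromiter((g in members for g in x.index[order]), bool, len(x))
    w = np.where(in_set, magnitude[order] ** alpha, 0.0)
    ecdf_in = np.cumsum(w) / w.sum()
    ecdf_out = np.cumsum(~in_set) / n_out
    return float(np.sum(ecdf_in - ecdf_out))


def score_matrix(
    expression: pd.DataFrame,
    sets: Mapping[str, Sequence[str]],
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Activity scores for every (gene set, sample) pair.

    Sets with no member present in the expression index are dropped with a
    log entry. ``normalize=True`` rescales the whole matrix by its value
    range (a variant some implementations apply); the default leaves the
    raw running-sum integrals.
    """
    kept: dict[str, list[float]] = {}
    for name, members in sets.items():
        try:
            kept[name] = [
                ssgsea_score(expression[s], members, alpha=alpha) for s in expression.columns
            ]
        except DomainError:
            logger.info("event=gene_set_dropped set=%s", name)
    if not kept:
        raise DegenerateDataError("every gene set was dropped; no scores computed")
    out = pd.DataFrame.from_dict(kept, orient="index", columns=list(expression.columns))
    out.index.name = "gene_set"
    if normalize:
        span = float(out.to_numpy().max() - out.to_numpy().min())
        if span > 0:
            out = out / span
    return out


def differential_activity(
    scores_a: pd.DataFrame, scores_b: pd.DataFrame, fdr: float = 0.001
) -> pd.DataFrame:
    """Per-set two-sided rank-sum comparison of activity scores between two
    sample groups, BH-adjusted across the set collection; ``significant``
    is q < fdr (strict)."""
    if not scores_a.index.equals(scores_b.index):
        raise DomainError("the two score matrices cover different gene-set collections")
    if scores_a.shape[1] < 2 or scores_b.shape[1] < 2:
        raise DegenerateDataError("each group needs >=2 samples")
    res = [
        wilcoxon_rank_sum(scores_a.loc[s].to_numpy(), scores_b.loc[s].to_numpy(), "two_sided")
        for s in scores_a.index
    ]
    p = np.array([r.p_value for r in res])
    q = benjamini_hochberg(p)
    return pd.DataFrame(
        {
            "p": p,
            "q": q,
            "significant": q < fdr,
            "direction": [r.direction for r in res],
        },
        index=scores_a.index,
    )


def categorize(da_cl: pd.Series, da_org: pd.Series) -> pd.Series:
    """Four-way classification from the two model-class DA outcomes.

    1 = significant only vs organoids, 2 = only vs cell lines,
    3 = both, 4 = neither. Inputs are boolean significance series over the
    same gene-set collection.
    """
    if not da_cl.index.sort_values().equals(da_org.index.sort_values()):
        raise DomainError("the two significance tables cover different gene-set collections")
    da_org = da_org.reindex(da_cl.index)
    cat = np.select(
        [~da_cl & da_org, da_cl & ~da_org, da_cl & da_org],
        [1, 2, 3],
        default=4,
    )
    return pd.Series(cat, index=da_cl.index, name="category")


def consensus_categories(
    per_stratum: Mapping[str, pd.Series],
) -> tuple[pd.Series, list[str]]:
    """Split gene sets into those with the same category in every stratum
    (returned with their shared category) and the discordant remainder."""
    strata = list(per_stratum)
    if len(strata) < 2:
        raise DomainError("consensus needs category tables for >=2 strata")
    table = pd.DataFrame({s: per_stratum[s] for s in strata})
    if table.isna().any().any():
        raise DomainError("strata cover different gene-set collections")
    agree = table.nunique(axis=1) == 1
    consensus = table.loc[agree, strata[0]].rename("category")
    discordant = sorted(table.index[~agree])
    return consensus, discordant


def intersect_de_lists(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Intersect externally produced differential-expression tables.

    Each table has columns ``gene`` and ``direction`` ("up"/"down"). A gene
    survives only if present in every table with the identical direction.
    Returns a table with columns ``gene``, ``direction`` sorted by gene.
    """
    if len(tables) < 2:
        raise DomainError("need >=2 DE tables to intersect")
    maps = []
    for t in tables:
        if "gene" not in t.columns or "direction" not in t.columns:
            raise DomainError("DE tables need 'gene' and 'direction' columns")
        maps.append(dict(zip(t["gene"], t["direction"])))
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    rows = [
        {"gene": g, "direction": maps[0][g]}
        for g in sorted(common)
        if all(m[g] == maps[0][g] for m in maps[1:])
    ]
    return pd.DataFrame(rows, columns=["gene", "direction"])
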