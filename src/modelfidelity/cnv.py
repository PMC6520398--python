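"""Copy-number comparison between a tumor cohort and a model panel.

Gene-level CNV (log-ratio scale) is summarised per sample set as a median
profile; profiles are compared by Spearman correlation, partitioned into
loss / gain / high-gain genes at the conventional cuts (loss < 0,
high gain >= 0.4), and each model is ranked by its median per-tumor CNV
correlation over the common genotyped panel (no marker selection: every
panel gene participates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, DomainError
from .stats import TestResult, spearman, wilcoxon_rank_sum
from .transcriptome import SimilarityResult, _spearman_cross

logger = logging.getLogger("modelfidelity")

__all__ = [
    "CNVProfile",
    "median_profile",
    "profile_correlation",
    "gain_loss_partition",
    "partition_shift_test",
    "cnv_similarity",
    "rank_models_by_cnv",
]


@dataclass(frozen=True)
class CNVProfile:
    """Per-gene median CNV over a sample set (defined only for genes with
    at least one non-missing value)."""

    values: pd.Series
    label: str
    n_samples: int


def median_profile(
    cnv: pd.DataFrame, samples, label: str = "", max_missing: float = 0.5
) -> CNVProfile:
    """Per-gene median CNV across a sample subset.

    Medians skip missing values; a gene missing in more than
    ``max_missing`` of the subset is dropped from the profile (logged).
    Even counts use the midpoint of the two central values.
    """
    samples = list(samples)
    if not samples:
        raise DegenerateDataError("median profile of an empty sample subset")
    missing = [s for s in samples if s not in cnv.columns]
    if missing:
        raise DomainError(f"sample {missing[0]!r} absent from the CNV matrix")
    sub = cnv[samples]
    frac_missing = sub.isna().mean(axis=1)
    keep = frac_missing <= max_missing
    dropped = int((~keep).sum())
    if dropped:
        logger.info("event=cnv_genes_dropped label=%s n=%d", label, dropped)
    med = sub[keep].median(axis=1, skipna=True).dropna()
    return CNVProfile(values=med.astype(float), label=label or "profile", n_samples=len(samples))


def profile_correlation(a: CNVProfile, b: CNVProfile) -> float:
    """Spearman correlation of two median profiles over the genes defined
    in both."""
    shared = a.values.index.intersection(b.values.index)
    if len(shared) < 3:
        raise DegenerateDataError(f"profiles share only {len(shared)} genes")
    return spearman(a.values.loc[shared].to_numpy(), b.values.loc[shared].to_numpy())


def gain_loss_partition(
    p: CNVProfile, loss_cut: float = 0.0, gain_cut: float = 0.4
) -> dict[str, list[str]]:
    """Partition profile genes into loss (median < ``loss_cut``) and gain
    (the complement), with the high-gain subset at median >= ``gain_cut``."""
    v = p.values
    loss = sorted(v.index[v < loss_cut])
    gain = sorted(v.index[v >= loss_cut])
    high_gain = sorted(v.index[v >= gain_cut])
    return {"loss": loss, "gain": gain, "high_gain": high_gain}


def partition_shift_test(genes, profile_a: CNVProfile, profile_b: CNVProfile) -> TestResult:
    """Two-sided Wilcoxon rank-sum comparison of two profiles restricted to
    a gene set (e.g. is the loss-gene median CNV lower in models than in
    tumors?). Direction is the sign of the difference of group medians."""
    genes = list(genes)
    if len(genes) < 2:
        raise DegenerateDataError("partition shift test needs >=2 genes")
    for g in genes:
        if g not in profile_a.values.index or g not in profile_b.values.index:
            raise DomainError(f"gene {g!r} not defined in both profiles")
    a = profile_a.values.loc[genes].to_numpy()
    b = profile_b.values.loc[genes].to_numpy()
    return wilcoxon_rank_sum(a, b, alternative="two_sided")


def cnv_similarity(
    model_vector: pd.Series, tumors: pd.DataFrame, panel, stratum: str = "all"
) -> SimilarityResult:
    """CNV analogue of transcriptome similarity: median per-tumor Spearman
    over the whole common gene panel, pairwise-complete in the face of
    missing gene values."""
    panel = list(panel)
    missing = [g for g in panel if g not in model_vector.index or g not in tumors.index]
    if missing:
        raise DomainError(f"panel gene {missing[0]!r} absent from model or tumors")
    if tumors.shape[1] < 1:
        raise DegenerateDataError("need at least one tumor")
    mv = model_vector.loc[panel]
    tv = tumors.loc[panel]
    corrs = {}
    dropped = 0
    for s in tv.columns:
        try:
            corrs[s] = spearman(mv.to_numpy(), tv[s].to_numpy())
        except DegenerateDataError:
            dropped += 1
    if not corrs:
        raise DegenerateDataError(f"all CNV correlations undefined for {model_vector.name!r}")
    return SimilarityResult(
        model=str(model_vector.name),
        correlations=pd.Series(corrs, dtype=float),
        stratum=stratum,
        n_dropped=dropped,
    )


def rank_models_by_cnv(models: pd.DataFrame, tumors: pd.DataFrame, panel) -> pd.DataFrame:
    """Rank every model by CNV similarity with the tumor cohort over the
    common panel. Rows sorted by descending similarity, ties broken by
    model id; ``rank`` is the 1-based position."""
    panel = list(panel)
    if models.shape[1] < 1:
        raise DegenerateDataError("need at least one model")
    msub = models.loc[panel]
    tsub = tumors.loc[panel]
    if not msub.isna().any().any() and not tsub.isna().any().any():
        corr = _spearman_cross(msub, tsub)
        sim = corr.median(axis=1, skipna=True)
        counts = corr.notna().sum(axis=1)
    else:
        sim = {}
        counts = {}
        for m in msub.columns:
            res = cnv_similarity(msub[m], tsub, panel)
            sim[m] = res.similarity
            counts[m] = res.n_samples
        sim = pd.Series(sim)
        counts = pd.Series(counts)
    out = pd.DataFrame(
        {"model": sim.index, "similarity": sim.to_numpy(dtype=float),
         "n_samples": counts.loc[sim.index].to_numpy()}
    )
    out = out.sort_values(["similarity", "model"], ascending=[False, True], kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
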