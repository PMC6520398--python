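"""Transcriptome-correlation (TC) analysis.

A model (cell line or organoid) is scored against a tumor cohort as the
median Spearman correlation between its expression profile and each tumor
sample, computed over a marker-gene panel. Marker genes are the k genes
whose within-sample ranks vary most across the model reference panel, so
the similarity is invariant to any per-sample monotone transform of the
abundances (FPKM, TPM, log-anything all give the same answer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DegenerateDataError, DomainError
from .stats import spearman

logger = logging.getLogger("modelfidelity")

__all__ = [
    "MarkerGeneSet",
    "SimilarityResult",
    "select_marker_genes",
    "transcriptome_similarity",
    "rank_models",
    "stratified_similarity",
    "stratum_agreement",
    "pam50_distance_matrix",
]

_DISPERSIONS = {
    "sd": lambda r: r.std(axis=1, ddof=1),
    "variance": lambda r: r.var(axis=1, ddof=1),
    "mad": lambda r: (r.sub(r.median(axis=1), axis=0)).abs().median(axis=1),
    "iqr": lambda r: r.quantile(0.75, axis=1) - r.quantile(0.25, axis=1),
}


@dataclass(frozen=True)
class MarkerGeneSet:
    """Top-k most rank-variable genes of a reference panel, with their
    variation scores in non-increasing order."""

    genes: list[str]
    scores: list[float]
    reference: str = ""
    k: int = 0

    def __post_init__(self) -> None:
        if list(self.scores) != sorted(self.scores, reverse=True):
            raise DomainError("marker scores must be non-increasing")


@dataclass(frozen=True)
class SimilarityResult:
    """One model's per-sample correlations against a sample set and their
    median (the transcriptome-similarity score)."""

    model: str
    correlations: pd.Series
    stratum: str = "all"
    n_dropped: int = 0

    @property
    def similarity(self) -> float:
        return float(self.correlations.median())

    @property
    def n_samples(self) -> int:
        return int(self.correlations.size)


def select_marker_genes(
    reference: pd.DataFrame, k: int = 1000, dispersion: str = "sd"
) -> MarkerGeneSet:
    """Pick the ``k`` genes whose within-sample average ranks vary most
    across the reference samples.

    Each reference sample is rank-transformed (average-rank ties), then the
    per-gene dispersion of ranks across samples is computed (standard
    deviation by default). Ties in the dispersion are broken by gene symbol.
    """
    if k < 1:
        raise DomainError(f"marker count k must be >=1, got {k}")
    if reference.shape[1] < 2:
        raise DegenerateDataError("marker selection needs >=2 reference samples")
    if dispersion not in _DISPERSIONS:
        raise DomainError(f"unknown dispersion {dispersion!r}")
    ranks = pd.DataFrame(np.column_stack([sps.rankdata(reference[c], method="average")
                                          for c in reference.columns]),
                         index=reference.index, columns=reference.columns)
    score = _DISPERSIONS[dispersion](ranks)
    order = sorted(reference.index, key=lambda g: (-score[g], g))[: min(k, len(score))]
    return MarkerGeneSet(
        genes=list(order),
        scores=[float(score[g]) for g in order],
        reference="x".join(map(str, reference.shape)),
        k=k,
    )


def _rank_columns(df: pd.DataFrame) -> np.ndarray:
    """Column-wise average ranks; constant columns come out as NaN so they
    drop out of correlations."""
    arr = df.to_numpy(dtype=float)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        if np.all(col == col[0]):
            out[:, j] = np.nan
        else:
            out[:, j] = sps.rankdata(col, method="average")
    return out


def _spearman_cross(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Spearman between columns of ``a`` and columns of ``b``
    (shared gene index required). Constant columns yield NaN."""
    ra = _rank_columns(a)
    rb = _rank_columns(b)
    ra = (ra - np.nanmean(ra, axis=0)) / np.nanstd(ra, axis=0)
    rb = (rb - np.nanmean(rb, axis=0)) / np.nanstd(rb, axis=0)
    corr = ra.T @ rb / a.shape[0]
    return pd.DataFrame(corr, index=a.columns, columns=b.columns)


def transcriptome_similarity(
    model: pd.Series, samples: pd.DataFrame, markers: MarkerGeneSet, stratum: str = "all"
) -> SimilarityResult:
    """Median-of-Spearman similarity of one model against a sample set,
    over the marker genes. Samples with undefined correlation (constant
    over the markers) are dropped and counted."""
    missing = [g for g in markers.genes if g not in model.index or g not in samples.index]
    if missing:
        raise DomainError(f"marker gene {missing[0]!r} absent from model or samples")
    if samples.shape[1] < 1:
        raise DegenerateDataError("need at least one sample")
    mv = model.loc[markers.genes]
    sv = samples.loc[markers.genes]
    corrs = {}
    dropped = 0
    for s in sv.columns:
        try:
            corrs[s] = spearman(mv.to_numpy(), sv[s].to_numpy())
        except DegenerateDataError:
            dropped += 1
    if not corrs:
        raise DegenerateDataError(
            f"all per-sample correlations undefined for model {model.name!r}"
        )
    if dropped:
        logger.info("event=undefined_correlations model=%s dropped=%d", model.name, dropped)
    return SimilarityResult(
        model=str(model.name),
        correlations=pd.Series(corrs, dtype=float),
        stratum=stratum,
        n_dropped=dropped,
    )


def rank_models(
    models: pd.DataFrame,
    samples: pd.DataFrame,
    markers: MarkerGeneSet,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rank every model by its transcriptome similarity with the sample set.

    Rows are sorted by descending similarity with ties broken by model id;
    ``rank`` is the resulting 1-based position. Lineage and cohort-class
    metadata are carried along when supplied so lineage-level queries
    ("are the top models all breast?") need no joins.
    """
    if models.shape[1] < 1:
        raise DegenerateDataError("need at least one model")
    corr = _spearman_cross(models.loc[markers.genes], samples.loc[markers.genes])
    sim = corr.median(axis=1, skipna=True)
    out = pd.DataFrame(
        {
            "model": sim.index,
            "similarity": sim.to_numpy(dtype=float),
            "n_samples": corr.notna().sum(axis=1).to_numpy(),
        }
    )
    if metadata is not None:
        meta = metadata.set_index("sample")
        out["lineage"] = [meta.at[m, "lineage"] if m in meta.index else "unknown" for m in out["model"]]
        out["cohort_class"] = [
            meta.at[m, "cohort_class"] if m in meta.index else "unknown" for m in out["model"]
        ]
    out = out.sort_values(["similarity", "model"], ascending=[False, True], kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def stratified_similarity(
    models: pd.DataFrame,
    samples: pd.DataFrame,
    metadata: pd.DataFrame,
    markers: MarkerGeneSet,
    stratify_by: str = "metastatic_site",
    min_stratum: int = 9,
) -> pd.DataFrame:
    """Per-stratum transcriptome similarity of every model.

    Strata are the levels of ``metastatic_site`` or ``subtype`` among the
    samples; strata with fewer than ``min_stratum`` samples are skipped
    (and logged), mirroring the minimum-cohort rule used for site-specific
    comparisons.
    """
    if stratify_by not in {"metastatic_site", "subtype"}:
        raise DomainError(f"cannot stratify by {stratify_by!r}")
    meta = metadata.set_index("sample")
    labels = meta.loc[[s for s in samples.columns if s in meta.index], stratify_by]
    rows = []
    used = 0
    for stratum in sorted(labels.dropna().unique()):
        if stratum in {"none", "unknown", ""}:
            continue
        members = labels.index[labels == stratum]
        if len(members) < min_stratum:
            logger.info(
                "event=stratum_skipped stratum=%s n=%d min=%d", stratum, len(members), min_stratum
            )
            continue
        used += 1
        corr = _spearman_cross(models.loc[markers.genes], samples.loc[markers.genes, members])
        sim = corr.median(axis=1, skipna=True)
        for m in sim.index:
            rows.append(
                {
                    "model": m,
                    "stratum": f"{stratify_by}:{stratum}",
                    "similarity": float(sim[m]),
                    "n_samples": int(corr.loc[m].notna().sum()),
                }
            )
    if used == 0:
        raise DegenerateDataError(f"no {stratify_by} stratum reaches {min_stratum} samples")
    return pd.DataFrame(rows)


def stratum_agreement(stratified: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman agreement of per-model similarity vectors across
    strata (symmetric, unit diagonal). Requires >=2 strata sharing >=3
    models."""
    wide = stratified.pivot(index="model", columns="stratum", values="similarity")
    strata = list(wide.columns)
    if len(strata) < 2:
        raise DegenerateDataError("stratum agreement needs >=2 strata")
    out = pd.DataFrame(np.eye(len(strata)), index=strata, columns=strata)
    for i, s1 in enumerate(strata):
        for s2 in strata[i + 1 :]:
            pair = wide[[s1, s2]].dropna()
            if len(pair) < 3:
                raise DegenerateDataError(
                    f"strata {s1!r} and {s2!r} share fewer than 3 models"
                )
            rho = spearman(pair[s1].to_numpy(), pair[s2].to_numpy())
            out.loc[s1, s2] = out.loc[s2, s1] = rho
    return out


def pam50_distance_matrix(samples: pd.DataFrame, pam50_genes: list[str]) -> pd.DataFrame:
    """Pairwise sample distance 1 - Spearman over the intrinsic-subtype
    (PAM50-style) gene list; range [0, 2], zero diagonal."""
    present = [g for g in pam50_genes if g in samples.index]
    if len(present) < 2:
        raise DomainError("fewer than 2 of the listed genes are present")
    if samples.shape[1] < 2:
        raise DegenerateDataError("need >=2 samples")
    sub = samples.loc[present]
    for s in sub.columns:
        col = sub[s].to_numpy()
        if np.all(col == col[0]):
            raise DegenerateDataError(f"sample {s!r} is constant over the gene list")
    corr = _spearman_cross(sub, sub)
    dist = 1.0 - corr
    np.fill_diagonal(dist.values, 0.0)
    return dist
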