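"""Differential-mutation landscape between a metastatic cohort and a
primary-tumor reference, plus the culture-artifact (hypermutation) calls.

The central test asks, gene by gene, whether the metastatic cohort carries
more mutations than expected under the primary-cohort frequency q-hat: the
right-tailed p-value is the binomial upper tail P(X > n) at (N, q-hat),
with the left tail defined as its complement. Genes with zero reference
frequency borrow the minimum nonzero frequency across the panel so the
binomial is always defined. Left- and right-tailed families are adjusted
with Benjamini-Hochberg independently.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, DomainError
from .stats import benjamini_hochberg, binomial_upper_tail

logger = logging.getLogger("modelfidelity")

__all__ = [
    "mutation_frequencies",
    "highly_mutated",
    "differential_mutation_test",
    "merge_candidate_panel",
    "cellline_hypermutation",
    "recapitulation_report",
]


def mutation_frequencies(m: pd.DataFrame) -> pd.Series:
    """Per-gene mutation frequency: mutated-sample count / total samples."""
    if m.shape[1] == 0:
        raise DegenerateDataError("mutation matrix has zero samples")
    return m.mean(axis=1).astype(float)


def highly_mutated(freqs: pd.Series, threshold: float = 0.05) -> list[str]:
    """Genes with frequency strictly above ``threshold``, sorted by
    descending frequency then symbol."""
    hits = freqs[freqs > threshold]
    return sorted(hits.index, key=lambda g: (-hits[g], g))


def differential_mutation_test(
    met: pd.DataFrame,
    reference_freqs: pd.Series,
    inclusive_tail: bool = False,
) -> pd.DataFrame:
    """Per-gene binomial test of elevated mutation frequency in the
    metastatic cohort.

    Parameters
    ----------
    met
        Binary gene x sample mutation matrix of the metastatic cohort.
    reference_freqs
        Primary-cohort mutation frequency per gene, aligned to ``met``'s
        panel. Zeros are replaced by the minimum nonzero frequency over the
        panel (q-hat substitution).
    inclusive_tail
        Switch the right tail from the default P(X > n) to P(X >= n).

    Returns a table indexed by gene with columns n, N, q_hat, freq_met,
    p_right, p_left, q_right, q_left. The left- and right-tailed p-value
    families are BH-adjusted separately.
    """
    if not met.index.equals(reference_freqs.index):
        reference_freqs = reference_freqs.reindex(met.index)
        if reference_freqs.isna().any():
            missing = reference_freqs.index[reference_freqs.isna()][0]
            raise DomainError(f"no reference frequency for panel gene {missing!r}")
    if met.shape[1] == 0:
        raise DegenerateDataError("metastatic cohort has zero samples")
    ref = reference_freqs.astype(float)
    nonzero = ref[ref > 0]
    if nonzero.empty:
        raise DomainError("all reference frequencies are zero; no q-hat substitute exists")
    q_floor = float(nonzero.min())
    n_sub = int((ref == 0).sum())
    if n_sub:
        logger.info("event=qhat_zero_substitution n_genes=%d floor=%g", n_sub, q_floor)
    q_hat = ref.where(ref > 0, q_floor).clip(upper=1 - 1e-12)
    N = met.shape[1]
    n = met.sum(axis=1).astype(int)
    p_right = np.array(
        [binomial_upper_tail(int(k), N, float(q), inclusive=inclusive_tail)
         for k, q in zip(n, q_hat)]
    )
    p_left = 1.0 - p_right
    return pd.DataFrame(
        {
            "n": n,
            "N": N,
            "q_hat": q_hat,
            "freq_met": n / N,
            "p_right": p_right,
            "p_left": p_left,
            "q_right": benjamini_hochberg(p_right),
            "q_left": benjamini_hochberg(p_left),
        },
        index=met.index,
    )


def merge_candidate_panel(
    highly: Sequence[str],
    differential: Sequence[str],
    met_freqs: pd.Series,
) -> list[str]:
    """Union of the highly-mutated and differentially-mutated gene lists,
    ordered by descending metastatic frequency then symbol."""
    merged = set(highly) | set(differential)
    return sorted(merged, key=lambda g: (-float(met_freqs.get(g, 0.0)), g))


def cellline_hypermutation(
    cl: pd.DataFrame,
    tumor_freqs: pd.Series,
    cl_fraction: float = 0.5,
    tumor_threshold: float = 0.05,
) -> list[str]:
    """Genes hypermutated specifically in cell lines: mutated in at least
    ``cl_fraction`` of model samples while rare (< ``tumor_threshold``)
    in the tumor cohort."""
    cl_freqs = mutation_frequencies(cl)
    tumor_freqs = tumor_freqs.reindex(cl_freqs.index).fillna(0.0)
    hits = cl_freqs[(cl_freqs >= cl_fraction) & (tumor_freqs < tumor_threshold)]
    return sorted(hits.index, key=lambda g: (-hits[g], g))


def recapitulation_report(
    panel: Sequence[str],
    cl: pd.DataFrame,
    highly: Sequence[str] = (),
    differential: Sequence[str] = (),
    hypermutated: Sequence[str] = (),
) -> pd.DataFrame:
    """How well the model panel recapitulates a candidate gene panel.

    One row per panel gene: the fraction of model samples carrying a
    mutation, plus membership flags; ``unmodeled`` marks genes mutated in
    no model at all.
    """
    missing = [g for g in panel if g not in cl.index]
    if missing:
        raise DomainError(f"panel gene {missing[0]!r} absent from the model mutation matrix")
    frac = mutation_frequencies(cl.loc[list(panel)])
    return pd.DataFrame(
        {
            "fraction_of_models_mutated": frac,
            "highly_mutated": [g in set(highly) for g in panel],
            "differentially_mutated": [g in set(differential) for g in panel],
            "cellline_hypermutated": [g in set(hypermutated) for g in panel],
            "unmodeled": frac == 0.0,
        },
        index=pd.Index(panel, name="gene"),
    )
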