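"""Marker selection, transcriptome-correlation similarity and rankings."""

import numpy as np
import pandas as pd
import pytest

from modelfidelity.exceptions import DegenerateDataError, DomainError
from modelfidelity.stats import spearman
from modelfidelity.transcriptome import (
    MarkerGeneSet,
    pam50_distance_matrix,
    rank_models,
    select_marker_genes,
    stratified_similarity,
    stratum_agreement,
    transcriptome_similarity,
)


def expr(genes, data, samples=None):
    data = np.asarray(data, dtype=float)
    samples = samples or [f"S{i}" for i in range(data.shape[1])]
    return pd.DataFrame(data, index=pd.Index(genes, name="gene"), columns=samples)


def markers_of(genes):
    return MarkerGeneSet(genes=list(genes), scores=[0.0] * len(genes))


class TestMarkerSelection:
    def test_zero_variation_gene_never_beats_varying_gene(self):
        # G0 is always lowest-expressed (rank 1 in every sample)
        m = expr(["G0", "G1", "G2"], [[0.1, 0.2, 0.1], [5, 1, 9], [1, 7, 3]])
        sel = select_marker_genes(m, k=2)
        assert "G0" not in sel.genes

    def test_k_larger_than_panel_returns_all(self):
        m = expr(["G0", "G1"], [[1, 2], [2, 1]])
        assert len(select_marker_genes(m, k=10).genes) == 2

    def test_hand_computed_rank_sd_ordering(self):
        data = np.array(
            [
                [1.0, 5.0, 1.0],  # ranks 1,3,1
                [2.0, 4.0, 2.0],  # ranks 2,2,2
                [3.0, 3.0, 3.0],  # ranks 3,1,4  -> wait recompute below
                [4.0, 2.0, 2.5],
                [5.0, 1.0, 5.0],
            ]
        )
        m = expr([f"G{i}" for i in range(5)], data)
        ranks = m.apply(lambda c: c.rank(), axis=0)
        expected = ranks.std(axis=1, ddof=1).sort_values(ascending=False)
        sel = select_marker_genes(m, k=5)
        assert sel.genes[0] == expected.index[0]
        assert list(sel.scores) == sorted(sel.scores, reverse=True)

    def test_ties_broken_by_symbol(self):
        # two genes with identical rank trajectories
        m = expr(["GB", "GA", "GC"], [[1, 9], [2, 8], [5, 1]])
        sel = select_marker_genes(m, k=3)
        swapped = select_marker_genes(m.reindex(["GA", "GB", "GC"]), k=3)
        assert sel.genes == swapped.genes

    def test_needs_two_samples(self):
        with pytest.raises(DegenerateDataError):
            select_marker_genes(expr(["G0"], [[1.0]]), k=1)


class TestTranscriptomeSimilarity:
    def test_identical_model_and_sample(self):
        genes = [f"G{i}" for i in range(10)]
        samples = expr(genes, np.arange(10)[:, None] + 1.0)
        res = transcriptome_similarity(samples["S0"], samples, markers_of(genes))
        assert res.similarity == pytest.approx(1.0)

    def test_monotone_transform_gives_unit_similarity(self, rng):
        genes = [f"G{i}" for i in range(30)]
        samples = expr(genes, rng.lognormal(1, 1, (30, 1)))
        model = np.log1p(samples["S0"]).rename("M")
        res = transcriptome_similarity(model, samples, markers_of(genes))
        assert res.similarity == pytest.approx(1.0)

    def test_median_of_per_sample_correlations(self, rng):
        genes = [f"G{i}" for i in range(200)]
        model = pd.Series(rng.normal(0, 1, 200), index=genes, name="M")
        samples = expr(genes, rng.normal(0, 1, (200, 3)))
        res = transcriptome_similarity(model, samples, markers_of(genes))
        direct = sorted(
            spearman(model.to_numpy(), samples[s].to_numpy()) for s in samples.columns
        )
        assert res.similarity == pytest.approx(direct[1])

    def test_missing_marker_rejected(self, rng):
        genes = [f"G{i}" for i in range(5)]
        samples = expr(genes, rng.random((5, 2)))
        with pytest.raises(DomainError):
            transcriptome_similarity(samples["S0"], samples, markers_of(genes + ["GX"]))


class TestRankModels:
    def test_matches_scalar_path(self, rng):
        genes = [f"G{i}" for i in range(50)]
        models = expr(genes, rng.lognormal(0, 1, (50, 4)), samples=list("ABCD"))
        samples = expr(genes, rng.lognormal(0, 1, (50, 6)))
        mk = markers_of(genes)
        table = rank_models(models, samples, mk)
        for m in "ABCD":
            scalar = transcriptome_similarity(models[m], samples, mk).similarity
            assert table.loc[table.model == m, "similarity"].iloc[0] == pytest.approx(scalar)

    def test_duplicate_model_adjacent_ranks(self, rng):
        genes = [f"G{i}" for i in range(20)]
        vec = rng.random(20)
        models = expr(genes, np.column_stack([vec, vec]), samples=["M2", "M1"])
        samples = expr(genes, rng.random((20, 3)))
        table = rank_models(models, samples, markers_of(genes))
        assert list(table["model"]) == ["M1", "M2"] and list(table["rank"]) == [1, 2]

    def test_invariant_under_per_sample_monotone_transform(self, rng):
        genes = [f"G{i}" for i in range(40)]
        models = expr(genes, rng.lognormal(0, 1, (40, 3)), samples=list("XYZ"))
        samples = expr(genes, rng.lognormal(0, 1, (40, 5)))
        mk = markers_of(genes)
        base = rank_models(models, samples, mk)
        warped = rank_models(models**2, np.log1p(samples), mk)
        pd.testing.assert_frame_equal(base, warped)


def _meta(samples, **cols):
    base = {
        "sample": samples,
        "cohort_class": "tumor",
        "lineage": "breast",
        "metastatic_site": "none",
        "subtype": "unknown",
        "derivation_site": "unknown",
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestStratified:
    def test_identical_strata_identical_columns(self, rng):
        genes = [f"G{i}" for i in range(30)]
        samples = expr(genes, rng.random((30, 8)))
        # two sites with identical sample membership is impossible; instead
        # duplicate the samples under a second label
        doubled = pd.concat(
            [samples, samples.rename(columns=lambda s: s + "x")], axis=1
        )
        meta = _meta(
            list(doubled.columns),
            metastatic_site=["liver"] * 8 + ["bone"] * 8,
        )
        models = expr(genes, rng.random((30, 3)), samples=list("ABC"))
        out = stratified_similarity(models, doubled, meta, markers_of(genes),
                                    "metastatic_site", min_stratum=4)
        wide = out.pivot(index="model", columns="stratum", values="similarity")
        np.testing.assert_allclose(
            wide["metastatic_site:liver"], wide["metastatic_site:bone"]
        )

    def test_small_stratum_skipped(self, rng):
        genes = [f"G{i}" for i in range(10)]
        samples = expr(genes, rng.random((10, 6)))
        meta = _meta(list(samples.columns),
                     metastatic_site=["liver"] * 5 + ["bone"])
        models = expr(genes, rng.random((10, 2)), samples=["M1", "M2"])
        out = stratified_similarity(models, samples, meta, markers_of(genes),
                                    "metastatic_site", min_stratum=5)
        assert set(out["stratum"]) == {"metastatic_site:liver"}

    def test_no_qualifying_stratum_rejected(self, rng):
        genes = [f"G{i}" for i in range(10)]
        samples = expr(genes, rng.random((10, 3)))
        meta = _meta(list(samples.columns), metastatic_site=["liver", "bone", "lung"])
        models = expr(genes, rng.random((10, 2)), samples=["M1", "M2"])
        with pytest.raises(DegenerateDataError):
            stratified_similarity(models, samples, meta, markers_of(genes),
                                  "metastatic_site", min_stratum=3)


class TestStratumAgreement:
    def _table(self, sims: dict) -> pd.DataFrame:
        rows = [
            {"model": m, "stratum": s, "similarity": v}
            for s, col in sims.items()
            for m, v in col.items()
        ]
        return pd.DataFrame(rows)

    def test_duplicated_stratum_full_agreement(self):
        col = {"M1": 0.1, "M2": 0.5, "M3": 0.9}
        ag = stratum_agreement(self._table({"a": col, "b": col}))
        assert ag.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(ag), 1.0)

    def test_reversed_ordering_negative(self):
        col = {"M1": 0.1, "M2": 0.5, "M3": 0.9}
        rev = {"M1": 0.9, "M2": 0.5, "M3": 0.1}
        ag = stratum_agreement(self._table({"a": col, "b": rev}))
        assert ag.loc["a", "b"] == pytest.approx(-1.0)

    def test_too_few_shared_models(self):
        with pytest.raises(DegenerateDataError):
            stratum_agreement(
                self._table({"a": {"M1": 0.1, "M2": 0.2}, "b": {"M1": 0.3, "M2": 0.1}})
            )


class TestPAM50Distance:
    def test_properties_and_hand_check(self, rng):
        genes = [f"G{i}" for i in range(12)]
        samples = expr(genes, rng.random((12, 4)))
        dist = pam50_distance_matrix(samples, genes)
        assert np.allclose(np.diag(dist), 0.0)
        assert np.allclose(dist, dist.T)
        for i, a in enumerate(samples.columns):
            for b in samples.columns[i + 1:]:
                expected = 1 - spearman(samples[a].to_numpy(), samples[b].to_numpy())
                assert dist.loc[a, b] == pytest.approx(expected, abs=1e-12)

    def test_duplicate_and_antimonotone(self):
        genes = [f"G{i}" for i in range(6)]
        v = np.arange(6, dtype=float)
        samples = expr(genes, np.column_stack([v, v, v[::-1]]), samples=list("abc"))
        dist = pam50_distance_matrix(samples, genes)
        assert dist.loc["a", "b"] == pytest.approx(0.0)
        assert dist.loc["a", "c"] == pytest.approx(2.0)

    def test_constant_sample_named(self, rng):
        genes = [f"G{i}" for i in range(6)]
        data = rng.random((6, 2))
        data[:, 1] = 3.0
        samples = expr(genes, data, samples=["ok", "flat"])
        with pytest.raises(DegenerateDataError, match="flat"):
            pam50_distance_matrix(samples, genes)
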