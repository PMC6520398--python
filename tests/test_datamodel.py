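"""Format I/O, panel filtering, segment-to-gene mapping, harmonization."""

import numpy as np
import pandas as pd
import pytest

from modelfidelity.datamodel import (
    Cohort,
    filter_gene_panel,
    harmonize,
    map_segments_to_genes,
    mutation_matrix,
    read_bed,
    read_expression,
    read_gene_annotation,
    read_gmt,
    read_maf,
    read_metadata,
    read_seg,
    write_bed,
    write_expression,
    write_gene_annotation,
    write_gmt,
    write_maf,
    write_metadata,
    write_seg,
)
from modelfidelity.exceptions import FormatError


def make_annotation(rows):
    return pd.DataFrame(
        rows, columns=["symbol", "has_hgnc", "has_refseq", "chromosome", "start", "end"]
    )


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

class TestExpressionIO:
    def test_tsv_round_trip_exact(self, expr3x2, tmp_path):
        path = tmp_path / "e.tsv"
        write_expression(expr3x2, path)
        back = read_expression(path)
        pd.testing.assert_frame_equal(back, expr3x2)

    def test_gct_matches_tsv_dialect(self, expr3x2, tmp_path):
        write_expression(expr3x2, tmp_path / "e.tsv")
        write_expression(expr3x2, tmp_path / "e.gct", format="gct")
        a = read_expression(tmp_path / "e.tsv")
        b = read_expression(tmp_path / "e.gct", format="gct")
        pd.testing.assert_frame_equal(a, b)

    def test_negative_abundance_names_cell(self, expr3x2, tmp_path):
        bad = expr3x2.copy()
        bad.loc["GB", "S2"] = -1.0
        bad.to_csv(tmp_path / "bad.tsv", sep="\t")
        with pytest.raises(FormatError, match="GB.*S2"):
            read_expression(tmp_path / "bad.tsv")

    def test_duplicate_gene_rejected(self, tmp_path):
        (tmp_path / "dup.tsv").write_text("gene\tS1\nGA\t1\nGA\t2\n")
        with pytest.raises(FormatError, match="duplicate gene"):
            read_expression(tmp_path / "dup.tsv")

    def test_gene_order_preserved(self, tmp_path):
        (tmp_path / "o.tsv").write_text("gene\tS1\nGZ\t1\nGA\t2\n")
        assert list(read_expression(tmp_path / "o.tsv").index) == ["GZ", "GA"]


# ---------------------------------------------------------------------------
# MAF and mutation matrix
# ---------------------------------------------------------------------------

MAF_TEXT = (
    "Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification\n"
    "TP53\tS1\tMissense_Mutation\n"
    "TP53\tS2\tNonsense_Mutation\n"
    "ESR1\tS1\tSilent\n"
    "GATA3\tS2\tFrame_Shift_Del\n"
    "PIK3CA\tS3\tSplice_Site\n"
)


class TestMAF:
    def test_default_filter_drops_silent(self, tmp_path):
        p = tmp_path / "m.maf"
        p.write_text(MAF_TEXT)
        calls = read_maf(p)
        assert len(calls) == 4
        assert "Silent" not in set(calls["classification"])

    def test_all_classes_kept_when_requested(self, tmp_path):
        p = tmp_path / "m.maf"
        p.write_text(MAF_TEXT)
        classes = {"Missense_Mutation", "Nonsense_Mutation", "Silent",
                   "Frame_Shift_Del", "Splice_Site"}
        assert len(read_maf(p, qualifying_classes=classes)) == 5

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "m.maf"
        p.write_text("Tumor_Sample_Barcode\tVariant_Classification\nS1\tSilent\n")
        with pytest.raises(FormatError, match="Hugo_Symbol"):
            read_maf(p)

    def test_round_trip(self, tmp_path):
        p = tmp_path / "m.maf"
        p.write_text(MAF_TEXT)
        calls = read_maf(p)
        write_maf(calls, tmp_path / "m2.maf")
        pd.testing.assert_frame_equal(read_maf(tmp_path / "m2.maf"), calls)


class TestMutationMatrix:
    def test_repeated_calls_collapse_to_single_indicator(self):
        calls = pd.DataFrame(
            {"gene": ["A", "A"], "sample": ["S1", "S1"],
             "classification": ["Missense_Mutation"] * 2}
        )
        m = mutation_matrix(calls, ["S1", "S2"], ["A", "B"])
        assert m.to_numpy().sum() == 1 and m.loc["A", "S1"] == 1

    def test_empty_calls_all_zero(self):
        calls = pd.DataFrame(columns=["gene", "sample", "classification"])
        m = mutation_matrix(calls, ["S1"], ["A", "B"])
        assert m.to_numpy().sum() == 0 and m.shape == (2, 1)

    def test_fixture_count(self):
        calls = pd.DataFrame(
            {"gene": ["A", "B", "B"], "sample": ["S1", "S1", "S2"],
             "classification": ["x"] * 3}
        )
        m = mutation_matrix(calls, ["S1", "S2"], ["A", "B"])
        assert m.to_numpy().sum() == 3

    def test_calls_outside_panel_dropped(self):
        calls = pd.DataFrame(
            {"gene": ["A", "Z"], "sample": ["S1", "S1"], "classification": ["x"] * 2}
        )
        m = mutation_matrix(calls, ["S1"], ["A"])
        assert m.to_numpy().sum() == 1


# ---------------------------------------------------------------------------
# segments -> genes
# ---------------------------------------------------------------------------

class TestSegmentMapping:
    def test_gene_inside_single_segment(self):
        segs = pd.DataFrame(
            [["S1", "chr1", 1, 1000, 0.5]],
            columns=["sample", "chromosome", "start", "end", "value"],
        )
        ann = make_annotation([["GA", True, True, "chr1", 100, 200]])
        out = map_segments_to_genes(segs, ann)
        assert out.loc["GA", "S1"] == pytest.approx(0.5)

    def test_equal_split_averages(self):
        segs = pd.DataFrame(
            [["S1", "chr1", 1, 150, 0.0], ["S1", "chr1", 151, 300, 1.0]],
            columns=["sample", "chromosome", "start", "end", "value"],
        )
        ann = make_annotation([["GA", True, True, "chr1", 101, 200]])
        assert map_segments_to_genes(segs, ann).loc["GA", "S1"] == pytest.approx(0.5)

    def test_weighted_mean_hand_computed(self):
        # 100 bp gene: 75 bp over value 0.2, 25 bp over value -0.2 -> 0.1
        segs = pd.DataFrame(
            [["S1", "chr1", 1, 175, 0.2], ["S1", "chr1", 176, 400, -0.2]],
            columns=["sample", "chromosome", "start", "end", "value"],
        )
        ann = make_annotation([["GA", True, True, "chr1", 101, 200]])
        assert map_segments_to_genes(segs, ann).loc["GA", "S1"] == pytest.approx(0.1)

    def test_no_overlap_is_missing(self):
        segs = pd.DataFrame(
            [["S1", "chr2", 1, 1000, 0.5]],
            columns=["sample", "chromosome", "start", "end", "value"],
        )
        ann = make_annotation([["GA", True, True, "chr1", 100, 200]])
        assert np.isnan(map_segments_to_genes(segs, ann).loc["GA", "S1"])

    def test_max_abs_rule(self):
        segs = pd.DataFrame(
            [["S1", "chr1", 1, 150, -0.9], ["S1", "chr1", 151, 300, 0.2]],
            columns=["sample", "chromosome", "start", "end", "value"],
        )
        ann = make_annotation([["GA", True, True, "chr1", 101, 200]])
        assert map_segments_to_genes(segs, ann, rule="max_abs").loc["GA", "S1"] == -0.9

    def test_invariant_to_splitting_segments(self, rng):
        ann = make_annotation(
            [[f"G{i}", True, True, "chr1", 1 + i * 300, 200 + i * 300] for i in range(10)]
        )
        whole = pd.DataFrame(
            [["S1", "chr1", 1, 4000, 0.7]],
            columns=["sample", "chromosome", "start", "end", "value"],
        )
        cut = int(rng.integers(2, 3999))
        split = pd.DataFrame(
            [["S1", "chr1", 1, cut, 0.7], ["S1", "chr1", cut + 1, 4000, 0.7]],
            columns=["sample", "chromosome", "start", "end", "value"],
        )
        pd.testing.assert_frame_equal(
            map_segments_to_genes(whole, ann), map_segments_to_genes(split, ann)
        )

    def test_reversed_segment_rejected(self):
        segs = pd.DataFrame(
            [["S1", "chr1", 500, 100, 0.5]],
            columns=["sample", "chromosome", "start", "end", "value"],
        )
        ann = make_annotation([["GA", True, True, "chr1", 100, 200]])
        with pytest.raises(FormatError, match="end < start"):
            map_segments_to_genes(segs, ann)


# ---------------------------------------------------------------------------
# panel filter and harmonization
# ---------------------------------------------------------------------------

class TestGenePanelFilter:
    def test_three_step_filter_counts(self):
        rows = []
        for i in range(20):
            rows.append([f"G{i:02d}", True, True, "chr1", 1, 10])
        rows[0][1] = False  # no HGNC
        rows[1][1] = False
        rows[2][2] = False  # no RefSeq
        rows[3][3] = "chrY"
        ann = make_annotation(rows)
        kept = filter_gene_panel([r[0] for r in rows], ann)
        assert len(kept) == 16

    def test_fully_annotated_identity(self):
        ann = make_annotation([["GA", True, True, "chr1", 1, 10],
                               ["GB", True, True, "chr2", 1, 10]])
        assert filter_gene_panel(["GA", "GB"], ann) == ["GA", "GB"]

    def test_double_failure_removed_once(self):
        ann = make_annotation([["GA", False, False, "chr1", 1, 10],
                               ["GB", True, True, "chr1", 1, 10]])
        assert filter_gene_panel(["GA", "GB"], ann) == ["GB"]

    def test_unannotated_gene_dropped(self):
        ann = make_annotation([["GA", True, True, "chr1", 1, 10]])
        assert filter_gene_panel(["GA", "GX"], ann) == ["GA"]


def _cohort(genes, samples, name):
    meta = pd.DataFrame(
        {"sample": samples, "cohort_class": "tumor", "lineage": "breast",
         "metastatic_site": "none", "subtype": "unknown", "derivation_site": "unknown"}
    )
    expr = pd.DataFrame(1.0, index=pd.Index(genes, name="gene"), columns=samples)
    return Cohort(metadata=meta, gene_panel=list(genes), expression=expr, name=name)


class TestHarmonize:
    def test_intersection_panel(self):
        out = harmonize([_cohort(["A", "B", "C"], ["S1"], "x"),
                         _cohort(["B", "C", "D"], ["S2"], "y")])
        assert out[0].gene_panel == ["B", "C"] == out[1].gene_panel

    def test_identical_panels_full_set(self):
        out = harmonize([_cohort(["B", "A"], ["S1"], "x"), _cohort(["A", "B"], ["S2"], "y")])
        assert out[0].gene_panel == ["A", "B"]

    def test_empty_intersection_rejected(self):
        with pytest.raises(FormatError, match="empty"):
            harmonize([_cohort(["A"], ["S1"], "x"), _cohort(["B"], ["S2"], "y")])

    def test_idempotent(self):
        once = harmonize([_cohort(["A", "B", "C"], ["S1"], "x"),
                          _cohort(["B", "C", "D"], ["S2"], "y")])
        twice = harmonize(once)
        for a, b in zip(once, twice):
            assert a.gene_panel == b.gene_panel
            pd.testing.assert_frame_equal(a.expression, b.expression)

    def test_cohort_rejects_sample_without_metadata(self):
        meta = pd.DataFrame(
            {"sample": ["S1"], "cohort_class": ["tumor"], "lineage": ["breast"],
             "metastatic_site": ["none"], "subtype": ["unknown"],
             "derivation_site": ["unknown"]}
        )
        expr = pd.DataFrame(1.0, index=pd.Index(["A"], name="gene"), columns=["S1", "S2"])
        with pytest.raises(FormatError, match="S2"):
            Cohort(metadata=meta, gene_panel=["A"], expression=expr)


# ---------------------------------------------------------------------------
# remaining format round-trips
# ---------------------------------------------------------------------------

class TestOtherFormats:
    def test_seg_round_trip(self, tmp_path):
        segs = pd.DataFrame(
            [["S1", "chr1", 1, 100, 0.5], ["S2", "chr2", 5, 50, -1.25]],
            columns=["sample", "chromosome", "start", "end", "value"],
        )
        write_seg(segs, tmp_path / "x.seg")
        pd.testing.assert_frame_equal(read_seg(tmp_path / "x.seg"), segs)

    def test_bed_coordinate_convention(self, tmp_path):
        ann = make_annotation([["GA", True, True, "chr1", 101, 200]])
        write_bed(ann, tmp_path / "g.bed")
        line = (tmp_path / "g.bed").read_text().strip().split("\t")
        assert line[1] == "100" and line[2] == "200"  # 0-based half-open on disk
        back = read_bed(tmp_path / "g.bed")
        assert back.loc[0, "start"] == 101 and back.loc[0, "end"] == 200

    def test_annotation_round_trip(self, tmp_path):
        ann = make_annotation([["GA", True, False, "chr1", 101, 200],
                               ["GB", False, True, "chrY", 5, 10]])
        write_gene_annotation(ann, tmp_path / "a.tsv")
        pd.testing.assert_frame_equal(read_gene_annotation(tmp_path / "a.tsv"), ann)

    def test_metadata_round_trip(self, tmp_path, small_study):
        write_metadata(small_study.metadata, tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(read_metadata(tmp_path / "m.tsv"), small_study.metadata)

    def test_gmt_round_trip_and_validation(self, tmp_path):
        sets = {"S1": ["A", "B"], "S2": ["C"]}
        write_gmt(sets, tmp_path / "s.gmt")
        assert read_gmt(tmp_path / "s.gmt") == sets
        (tmp_path / "bad.gmt").write_text("S1\tna\tA\tA\n")
        with pytest.raises(FormatError, match="duplicate member"):
            read_gmt(tmp_path / "bad.gmt")
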