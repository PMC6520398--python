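"""Domain containers, standard-format I/O, gene-panel filtering and cohort
harmonization.

Matrices are plain :class:`pandas.DataFrame` objects, genes in rows and
samples in columns; validators enforce the container invariants at the I/O
boundary so downstream stages can assume them. Coordinates are 1-based
inclusive everywhere (the MAF/SEG convention); BED input is converted on
read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError

logger = logging.getLogger("modelfidelity")

__all__ = [
    "COHORT_CLASSES",
    "SUBTYPES",
    "DEFAULT_EXCLUDED_MAF_CLASSES",
    "Cohort",
    "read_expression",
    "write_expression",
    "read_maf",
    "write_maf",
    "mutation_matrix",
    "read_seg",
    "write_seg",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_bed",
    "write_bed",
    "read_metadata",
    "write_metadata",
    "read_gmt",
    "write_gmt",
    "map_segments_to_genes",
    "filter_gene_panel",
    "harmonize",
]

COHORT_CLASSES = ("tumor", "cell_line", "organoid")
SUBTYPES = ("LuminalA", "LuminalB", "Her2", "Basal", "NormalLike", "unknown")

#: MAF variant classes treated as non-qualifying by default (non-coding or
#: silent); the qualifying set is configurable on read.
DEFAULT_EXCLUDED_MAF_CLASSES = frozenset(
    {"Silent", "Intron", "3'UTR", "5'UTR", "5'Flank", "IGR", "RNA"}
)

METADATA_COLUMNS = [
    "sample",
    "cohort_class",
    "lineage",
    "metastatic_site",
    "subtype",
    "derivation_site",
]

SEG_COLUMNS = ["sample", "chromosome", "start", "end", "value"]
ANNOTATION_COLUMNS = ["symbol", "has_hgnc", "has_refseq", "chromosome", "start", "end"]


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def _check_unique(values: Iterable[str], what: str) -> None:
    s = pd.Index(values)
    if s.has_duplicates:
        dup = s[s.duplicated()][0]
        raise FormatError(f"duplicate {what} identifier: {dup!r}")


def validate_expression(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce the expression-matrix invariants: unique identifiers,
    finite non-negative values."""
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    values = df.to_numpy(dtype=float, copy=False)
    bad = ~np.isfinite(values) | (values < 0)
    if bad.any():
        g, s = np.argwhere(bad)[0]
        raise FormatError(
            f"non-finite or negative abundance at gene {df.index[g]!r}, "
            f"sample {df.columns[s]!r}: {values[g, s]}"
        )
    return df


# ---------------------------------------------------------------------------
# expression I/O (TSV and GCT 1.2)
# ---------------------------------------------------------------------------

def read_expression(path, format: str = "tsv") -> pd.DataFrame:
    """Read a gene x sample abundance matrix (FPKM/RPKM-like).

    ``tsv``: first column gene identifiers, header row of sample ids.
    ``gct``: GCT 1.2 with its two header lines and a Description column.
    Gene order is preserved from the file.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    elif format == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise FormatError(f"{path}: expected GCT version line '#1.2', got {version!r}")
            dims = fh.readline().split()
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
        if len(dims) >= 2 and (df.shape[0] != int(dims[0]) or df.shape[1] != int(dims[1])):
            raise FormatError(
                f"{path}: GCT header declares {dims[0]}x{dims[1]}, found {df.shape}"
            )
    else:
        raise FormatError(f"unknown expression format {format!r}")
    df.index = df.index.astype(str)
    df.index.name = "gene"
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric abundance value ({exc})") from exc
    return validate_expression(df)


def write_expression(df: pd.DataFrame, path, format: str = "tsv") -> None:
    validate_expression(df)
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", index_label="gene")
    elif format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
            out = df.copy()
            out.insert(0, "Description", "na")
            out.to_csv(fh, sep="\t", index_label="Name")
    else:
        raise FormatError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# mutation calls (MAF) and the binary gene x sample indicator
# ---------------------------------------------------------------------------

_MAF_REQUIRED = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]


def read_maf(path, qualifying_classes: set[str] | None = None) -> pd.DataFrame:
    """Read somatic mutation calls from a MAF-style tab-separated file.

    Returns a call table with columns ``gene``, ``sample``,
    ``classification``. Only records whose classification is in
    ``qualifying_classes`` are retained; the default keeps every class not
    in :data:`DEFAULT_EXCLUDED_MAF_CLASSES` (all non-silent coding classes).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _MAF_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: MAF is missing required column(s) {missing}")
    calls = df[_MAF_REQUIRED].rename(
        columns={
            "Hugo_Symbol": "gene",
            "Tumor_Sample_Barcode": "sample",
            "Variant_Classification": "classification",
        }
    )
    empty = calls["gene"].isna() | (calls["gene"] == "") | calls["sample"].isna() | (
        calls["sample"] == ""
    )
    if empty.any():
        raise FormatError(f"{path}: empty gene or sample at MAF row {int(np.flatnonzero(empty)[0])}")
    if qualifying_classes is None:
        keep = ~calls["classification"].isin(DEFAULT_EXCLUDED_MAF_CLASSES)
    else:
        keep = calls["classification"].isin(qualifying_classes)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("event=maf_filtered file=%s dropped=%d kept=%d", path, dropped, int(keep.sum()))
    return calls[keep].reset_index(drop=True)


def write_maf(calls: pd.DataFrame, path) -> None:
    out = calls.rename(
        columns={
            "gene": "Hugo_Symbol",
            "sample": "Tumor_Sample_Barcode",
            "classification": "Variant_Classification",
        }
    )
    out.to_csv(path, sep="\t", index=False)


def mutation_matrix(
    calls: pd.DataFrame, samples: Sequence[str], genes: Sequence[str]
) -> pd.DataFrame:
    """Binary gene x sample indicator: 1 iff at least one qualifying call.

    Calls outside the requested gene/sample lists are dropped (counted in a
    log message); requested genes/samples with no calls yield zero
    rows/columns.
    """
    _check_unique(genes, "gene")
    _check_unique(samples, "sample")
    m = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=list(samples), dtype=np.int8)
    in_panel = calls["gene"].isin(m.index) & calls["sample"].isin(m.columns)
    outside = int((~in_panel).sum())
    if outside:
        logger.info("event=calls_outside_panel dropped=%d", outside)
    hit = calls[in_panel]
    if len(hit):
        m.values[
            m.index.get_indexer(hit["gene"]), m.columns.get_indexer(hit["sample"])
        ] = 1
    return m


# ---------------------------------------------------------------------------
# segmented copy number (SEG) and gene annotation (BED / TSV)
# ---------------------------------------------------------------------------

def read_seg(path) -> pd.DataFrame:
    """Read a SEG file (sample, chromosome, start, end, value; 1-based
    inclusive coordinates). Header names are normalised case-insensitively."""
    df = pd.read_csv(path, sep="\t", comment="#")
    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in {"sample", "id", "sample_id"}:
            rename[col] = "sample"
        elif key in {"chromosome", "chrom", "chr"}:
            rename[col] = "chromosome"
        elif key in {"start", "loc.start", "start.pos"}:
            rename[col] = "start"
        elif key in {"end", "loc.end", "end.pos"}:
            rename[col] = "end"
        elif key in {"value", "seg.mean", "segment_mean", "mean"}:
            rename[col] = "value"
    df = df.rename(columns=rename)
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: SEG is missing column(s) {missing}")
    df = df[SEG_COLUMNS].copy()
    df["sample"] = df["sample"].astype(str)
    df["chromosome"] = df["chromosome"].astype(str)
    df[["start", "end"]] = df[["start", "end"]].astype(np.int64)
    df["value"] = df["value"].astype(float)
    return validate_segments(df)


def validate_segments(segments: pd.DataFrame) -> pd.DataFrame:
    bad = segments["end"] < segments["start"]
    if bad.any():
        row = segments[bad].iloc[0]
        raise FormatError(
            f"segment with end < start: sample {row['sample']!r} "
            f"{row['chromosome']}:{row['start']}-{row['end']}"
        )
    if not np.isfinite(segments["value"]).all():
        raise FormatError("non-finite segment value")
    return segments


def write_seg(segments: pd.DataFrame, path) -> None:
    validate_segments(segments)
    segments.rename(
        columns={
            "sample": "Sample",
            "chromosome": "Chromosome",
            "start": "Start",
            "end": "End",
            "value": "Segment_Mean",
        }
    ).to_csv(path, sep="\t", index=False)


def read_gene_annotation(path) -> pd.DataFrame:
    """Read the extended gene-annotation TSV (symbol, has_hgnc, has_refseq,
    chromosome, start, end; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation is missing column(s) {missing}")
    df = df[ANNOTATION_COLUMNS].copy()
    df["symbol"] = df["symbol"].astype(str)
    df["chromosome"] = df["chromosome"].astype(str)
    for col in ("has_hgnc", "has_refseq"):
        df[col] = df[col].astype(bool)
    df[["start", "end"]] = df[["start", "end"]].astype(np.int64)
    return validate_annotation(df)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    _check_unique(annotation["symbol"], "gene symbol")
    bad = annotation["end"] < annotation["start"]
    if bad.any():
        sym = annotation.loc[bad, "symbol"].iloc[0]
        raise FormatError(f"annotation with end < start for gene {sym!r}")
    return annotation


def write_gene_annotation(annotation: pd.DataFrame, path) -> None:
    validate_annotation(annotation)
    annotation[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bed(path) -> pd.DataFrame:
    """Read gene coordinates from BED (0-based half-open, converted to
    1-based inclusive on read). HGNC/RefSeq flags are absent from BED and
    default to True."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chromosome", "start", "end", "symbol"], usecols=[0, 1, 2, 3],
    )
    out = pd.DataFrame(
        {
            "symbol": df["symbol"].astype(str),
            "has_hgnc": True,
            "has_refseq": True,
            "chromosome": df["chromosome"].astype(str),
            "start": df["start"].astype(np.int64) + 1,
            "end": df["end"].astype(np.int64),
        }
    )
    return validate_annotation(out)


def write_bed(annotation: pd.DataFrame, path) -> None:
    """Write gene coordinates as BED (converting back to 0-based half-open)."""
    validate_annotation(annotation)
    out = pd.DataFrame(
        {
            "chromosome": annotation["chromosome"],
            "start": annotation["start"] - 1,
            "end": annotation["end"],
            "symbol": annotation["symbol"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# sample metadata and gene sets
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("none")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata is missing column(s) {missing}")
    df = df[METADATA_COLUMNS].copy()
    return validate_metadata(df)


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    _check_unique(metadata["sample"], "sample")
    bad = ~metadata["cohort_class"].isin(COHORT_CLASSES)
    if bad.any():
        raise FormatError(
            f"unknown cohort class {metadata.loc[bad, 'cohort_class'].iloc[0]!r} "
            f"(expected one of {COHORT_CLASSES})"
        )
    return metadata


def write_metadata(metadata: pd.DataFrame, path) -> None:
    validate_metadata(metadata)
    metadata[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, members = parts[0], [g for g in parts[2:] if g]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
            if not members:
                raise FormatError(f"{path}:{lineno}: empty gene set {name!r}")
            if len(set(members)) != len(members):
                raise FormatError(f"{path}:{lineno}: duplicate member within set {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


# ---------------------------------------------------------------------------
# segment-to-gene mapping
# ---------------------------------------------------------------------------

def map_segments_to_genes(
    segments: pd.DataFrame,
    annotation: pd.DataFrame,
    rule: str = "overlap_weighted_mean",
) -> pd.DataFrame:
    """Map segmented copy number onto genes.

    Under the default ``overlap_weighted_mean`` rule a gene's value in a
    sample is the overlap-length-weighted mean of the overlapping segment
    values, which makes the mapping invariant to splitting a segment into
    contiguous sub-segments of equal value. ``max_abs`` keeps the value of
    the overlapping segment with the largest magnitude. Genes with no
    overlapping segment are missing (NaN).
    """
    if rule not in {"overlap_weighted_mean", "max_abs"}:
        raise FormatError(f"unknown mapping rule {rule!r}")
    validate_segments(segments)
    validate_annotation(annotation)
    genes = annotation["symbol"].tolist()
    samples = sorted(segments["sample"].unique())
    out = pd.DataFrame(
        np.nan, index=pd.Index(genes, name="gene"), columns=samples, dtype=float
    )
    ann_by_chrom = {c: g for c, g in annotation.groupby("chromosome", sort=False)}
    for (sample, chrom), segs in segments.groupby(["sample", "chromosome"], sort=False):
        ann = ann_by_chrom.get(chrom)
        if ann is None:
            continue
        seg_start = segs["start"].to_numpy()
        seg_end = segs["end"].to_numpy()
        seg_val = segs["value"].to_numpy()
        g_start = ann["start"].to_numpy()[:, None]
        g_end = ann["end"].to_numpy()[:, None]
        overlap = np.minimum(g_end, seg_end[None, :]) - np.maximum(g_start, seg_start[None, :]) + 1
        overlap = np.clip(overlap, 0, None).astype(float)
        covered = overlap.sum(axis=1) > 0
        if not covered.any():
            continue
        if rule == "overlap_weighted_mean":
            vals = np.full(len(ann), np.nan)
            vals[covered] = (
                overlap[covered] @ seg_val
            ) / overlap[covered].sum(axis=1)
        else:  # max_abs
            masked = np.where(overlap > 0, np.abs(seg_val)[None, :], -np.inf)
            pick = masked.argmax(axis=1)
            vals = np.where(covered, seg_val[pick], np.nan)
        out.loc[ann["symbol"].to_numpy(), sample] = vals
    return out


# ---------------------------------------------------------------------------
# gene-panel filtering and cross-study harmonization
# ---------------------------------------------------------------------------

def filter_gene_panel(genes: Sequence[str], annotation: pd.DataFrame) -> list[str]:
    """Three-step confidence filter for a genotyped gene panel.

    Removes genes without an HGNC record, genes without a RefSeq record,
    and Y-chromosome genes; order is preserved. Genes absent from the
    annotation are treated as failing both record flags (and logged).
    """
    validate_annotation(annotation)
    ann = annotation.set_index("symbol")
    kept: list[str] = []
    unannotated = 0
    for g in genes:
        if g not in ann.index:
            unannotated += 1
            continue
        row = ann.loc[g]
        if not bool(row["has_hgnc"]) or not bool(row["has_refseq"]):
            continue
        if str(row["chromosome"]).lstrip("chr") == "Y":
            continue
        kept.append(g)
    if unannotated:
        logger.info("event=unannotated_genes_dropped n=%d", unannotated)
    return kept


@dataclass
class Cohort:
    """A harmonized per-study bundle of matrices plus sample metadata.

    Every present matrix is restricted to ``gene_panel`` and every sample
    appearing in any matrix has exactly one metadata row.
    """

    metadata: pd.DataFrame
    gene_panel: list[str]
    expression: pd.DataFrame | None = None
    mutations: pd.DataFrame | None = None
    cnv: pd.DataFrame | None = None
    name: str = "study"

    def __post_init__(self) -> None:
        validate_metadata(self.metadata)
        known = set(self.metadata["sample"])
        panel = pd.Index(self.gene_panel)
        _check_unique(panel, "panel gene")
        for label in ("expression", "mutations", "cnv"):
            m = getattr(self, label)
            if m is None:
                continue
            if not set(m.index) <= set(panel):
                extra = sorted(set(m.index) - set(panel))[0]
                raise FormatError(
                    f"{self.name}: {label} gene {extra!r} not in the cohort gene panel"
                )
            orphan = set(m.columns) - known
            if orphan:
                raise FormatError(
                    f"{self.name}: sample {sorted(orphan)[0]!r} in {label} has no metadata row"
                )

    @property
    def matrices(self) -> dict[str, pd.DataFrame]:
        return {
            k: v
            for k, v in {
                "expression": self.expression,
                "mutations": self.mutations,
                "cnv": self.cnv,
            }.items()
            if v is not None
        }


def harmonize(cohorts: Sequence[Cohort]) -> list[Cohort]:
    """Restrict >=2 study cohorts to their common gene panel.

    The shared panel is the intersection of the studies' panels, ordered
    lexicographically for determinism. Harmonizing already-harmonized
    cohorts is the identity.
    """
    if len(cohorts) < 2:
        raise FormatError("harmonize requires at least two cohorts")
    panel: set[str] = set(cohorts[0].gene_panel)
    for c in cohorts[1:]:
        panel &= set(c.gene_panel)
    if not panel:
        raise FormatError("empty gene-panel intersection across cohorts")
    shared = sorted(panel)
    out = []
    for c in cohorts:
        out.append(
            Cohort(
                metadata=c.metadata,
                gene_panel=list(shared),
                expression=None if c.expression is None else c.expression.loc[shared],
                mutations=None if c.mutations is None else c.mutations.loc[shared],
                cnv=None if c.cnv is None else c.cnv.loc[shared],
                name=c.name,
            )
        )
    return out
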