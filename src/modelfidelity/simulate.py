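"""Seeded multi-omic toy-study generator with planted ground truth.

The generator emulates the statistical structure the evaluation pipeline
assumes in real data: a metastatic tumor cohort with subtype and
metastatic-site structure, a primary-tumor reference cohort (mutation
only), a model panel of breast and non-breast cell lines plus organoids
with a culture-effect expression shift, per-gene Bernoulli mutation
profiles with planted differentially mutated and cell-line-hypermutated
genes, and segmented copy number with planted gain/loss regions.

Expression is log-scale Gaussian: every downstream statistic is rank-based,
so the abundance family is immaterial and a Gaussian log-model keeps the
generator fast and analytically transparent. On the log2 scale a sample is

    baseline + subtype effect + lineage effect + site effect
             + lambda * culture direction + noise,

where lambda is the per-model culture-shift magnitude. Organoids receive a
smaller lambda than cell lines; one "faithful" cell line per subtype has
its lambda further reduced (the planted best model) and one "unfaithful"
line per subtype has it inflated. The full lambda ordering is recorded in
the truth object, as are the planted mutation genes, the gain/loss regions
and the culture-affected gene sets.

Identical (config, seed) pairs produce byte-identical output files; each
data modality draws from its own child RNG stream so modalities can be
regenerated independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import datamodel as dm
from .exceptions import DomainError

__all__ = ["GeneratorConfig", "SyntheticTruth", "SyntheticStudy", "generate_cohort", "truth_report"]

_NONSILENT = ["Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del", "Splice_Site"]


def _default_tumors_per_subtype() -> dict[str, int]:
    return {"LuminalA": 15, "LuminalB": 15, "Her2": 15, "Basal": 15}


def _default_site_sizes() -> dict[str, int]:
    return {"liver": 27, "lymph_node": 18, "bone": 15}


def _default_faithful_shifts() -> dict[str, float]:
    # LuminalA carries the global minimum, making its faithful line the
    # planted best model overall; the margin to the other faithful lines is
    # kept wide because similarity is quadratic in the shift near zero.
    return {"LuminalA": 0.05, "LuminalB": 0.3, "Her2": 0.3, "Basal": 0.3}


@dataclass
class GeneratorConfig:
    """Study-design knobs of the synthetic cohort. Defaults give a cohort
    large enough for stable rankings yet small enough for seconds-scale
    generation."""

    seed: int = 0

    # --- counts ---
    n_genes: int = 2000
    n_panel_genes: int = 600
    tumors_per_subtype: dict[str, int] = field(default_factory=_default_tumors_per_subtype)
    site_sizes: dict[str, int] = field(default_factory=_default_site_sizes)
    n_primary_tumors: int = 1000
    n_breast_cell_lines: int = 40
    n_nonbreast_cell_lines: int = 200
    n_organoids: int = 26
    n_metastatic_derived: int = 24  # breast cell lines derived from metastases

    # --- expression model (log2 scale) ---
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.3
    n_subtype_genes: int = 400
    subtype_scale: float = 0.6
    basal_scale: float = 2.0  # Basal sits farther from the other subtypes
    n_lineage_genes: int = 600
    lineage_scale: float = 2.0
    n_site_genes: int = 200
    site_scale: float = 0.15
    bone_scale: float = 0.5
    bone_basal_alignment: float = 0.6  # bone site effect leans onto the Basal axis
    n_culture_genes: int = 700
    cellline_shift: float = 1.0
    cellline_shift_sd: float = 0.1
    organoid_shift: float = 0.5
    organoid_shift_sd: float = 0.03
    faithful_shifts: dict[str, float] = field(default_factory=_default_faithful_shifts)
    unfaithful_shift: float = 2.5

    # --- mutation model ---
    mut_freq_low: float = 0.01
    mut_freq_high: float = 0.08
    n_differential_genes: int = 15
    differential_freq: float = 0.45
    n_hypermutated_genes: int = 8
    hypermutated_cl_freq: float = 0.9
    hypermutated_tumor_freq: float = 0.005
    silent_rate: float = 0.01

    # --- copy-number model ---
    n_cnv_chromosomes: int = 4
    gene_length: int = 10_000
    gene_gap: int = 5_000
    breaks_per_chromosome: int = 6
    recurrent_sd: float = 0.3
    cnv_noise_sd: float = 0.15
    cnv_distortion_sd: float = 0.25
    gain_region: tuple[int, int, int] = (2, 30, 60)  # chromosome, first gene, one-past-last
    loss_region: tuple[int, int, int] = (3, 20, 60)
    gain_tumor: float = 0.6
    gain_metastatic_model: float = 0.55
    gain_primary_model: float = 0.25
    loss_tumor: float = -0.3
    loss_cellline: float = -0.8

    # --- planted annotation-filter failures (all on chromosome 1) ---
    n_no_hgnc: int = 4
    n_no_refseq: int = 3
    n_y_chromosome: int = 1

    # --- gene sets ---
    n_culture_sets: int = 4
    n_control_sets: int = 8
    set_size: int = 20

    def validate(self) -> None:
        if sum(self.site_sizes.values()) != sum(self.tumors_per_subtype.values()):
            raise DomainError("site sizes must sum to the total tumor count")
        if self.n_panel_genes > self.n_genes:
            raise DomainError("panel cannot exceed the gene universe")
        if not (0 < self.mut_freq_low < self.mut_freq_high < 1):
            raise DomainError("mutation frequency range must satisfy 0 < low < high < 1")
        if self.n_metastatic_derived > self.n_breast_cell_lines:
            raise DomainError("metastatic-derived count exceeds breast cell-line count")
        per_chrom = self.n_panel_genes // self.n_cnv_chromosomes
        for label, (chrom, lo, hi) in (("gain", self.gain_region), ("loss", self.loss_region)):
            if not (1 <= chrom <= self.n_cnv_chromosomes and 0 <= lo < hi <= per_chrom):
                raise DomainError(f"{label} region outside the panel gene tiling")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SyntheticTruth:
    """Planted parameters of one generated study; fully determined by
    (config, seed)."""

    seed: int
    config_digest: str
    differential_genes: list[str]
    hypermutated_genes: list[str]
    gain_region_genes: list[str]
    loss_region_genes: list[str]
    faithful_models: dict[str, str]
    unfaithful_models: dict[str, str]
    best_model_overall: str
    culture_magnitudes: dict[str, float]
    culture_gene_sets: list[str]
    divergent_site: str
    config: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1)


@dataclass
class SyntheticStudy:
    """In-memory view of one generated study (what the output files
    contain)."""

    expression: dict[str, pd.DataFrame]
    mutation_calls: dict[str, pd.DataFrame]
    segments: dict[str, pd.DataFrame]
    annotation: pd.DataFrame
    metadata: pd.DataFrame
    gene_sets: dict[str, list[str]]
    truth: SyntheticTruth


def _calls_from_matrix(indicator: pd.DataFrame, rng: np.random.Generator,
                       silent_rate: float) -> pd.DataFrame:
    """Expand a binary gene x sample matrix into MAF-style call records,
    sprinkling non-qualifying Silent records on top."""
    g_idx, s_idx = np.nonzero(indicator.to_numpy())
    classes = rng.choice(_NONSILENT, size=g_idx.size)
    silent_mask = rng.random((indicator.shape[0], indicator.shape[1])) < silent_rate
    sg, ss = np.nonzero(silent_mask)
    calls = pd.DataFrame(
        {
            "gene": np.concatenate([indicator.index.to_numpy()[g_idx],
                                    indicator.index.to_numpy()[sg]]),
            "sample": np.concatenate([indicator.columns.to_numpy()[s_idx],
                                      indicator.columns.to_numpy()[ss]]),
            "classification": np.concatenate([classes, np.repeat("Silent", sg.size)]),
        }
    )
    return calls.sort_values(["sample", "gene", "classification"], kind="stable").reset_index(
        drop=True
    )


def generate_cohort(
    config: GeneratorConfig | None = None, out_dir=None
) -> SyntheticStudy:
    """Generate the full synthetic study; optionally write every pipeline
    input format (plus ``truth.json``) under ``out_dir``."""
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng_assign, rng_expr, rng_mut, rng_cnv = (
        np.random.default_rng([cfg.seed, k]) for k in range(4)
    )

    genes = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    panel = genes[: cfg.n_panel_genes]
    subtypes = list(cfg.tumors_per_subtype)

    # ---- sample identities -------------------------------------------------
    tumor_ids, tumor_subtype = [], {}
    for st, n in cfg.tumors_per_subtype.items():
        for i in range(n):
            sid = f"MET_{st}_{i + 1:02d}"
            tumor_ids.append(sid)
            tumor_subtype[sid] = st
    site_labels = np.repeat(list(cfg.site_sizes), list(cfg.site_sizes.values()))
    tumor_site = dict(zip(tumor_ids, rng_assign.permutation(site_labels)))

    primary_ids = [f"PRI_{i + 1:03d}" for i in range(cfg.n_primary_tumors)]

    breast_cl = [f"BCL_{i + 1:03d}" for i in range(cfg.n_breast_cell_lines)]
    nonbreast_cl = [f"NCL_{i + 1:03d}" for i in range(cfg.n_nonbreast_cell_lines)]
    organoids = [f"ORG_{i + 1:02d}" for i in range(cfg.n_organoids)]
    cl_subtype = {m: subtypes[i % len(subtypes)] for i, m in enumerate(breast_cl)}
    org_subtype = {m: subtypes[i % len(subtypes)] for i, m in enumerate(organoids)}
    metastatic_derived = set(
        rng_assign.choice(breast_cl, size=cfg.n_metastatic_derived, replace=False)
    )

    faithful, unfaithful = {}, {}
    for st in subtypes:
        lines = [m for m in breast_cl if cl_subtype[m] == st]
        pick = rng_assign.choice(len(lines), size=2, replace=False)
        faithful[st] = lines[int(pick[0])]
        unfaithful[st] = lines[int(pick[1])]

    # ---- culture-shift magnitudes -----------------------------------------
    lam: dict[str, float] = {}
    for m in breast_cl + nonbreast_cl:
        lam[m] = max(0.0, float(rng_assign.normal(cfg.cellline_shift, cfg.cellline_shift_sd)))
    for m in organoids:
        lam[m] = max(0.0, float(rng_assign.normal(cfg.organoid_shift, cfg.organoid_shift_sd)))
    for st in subtypes:
        lam[faithful[st]] = cfg.faithful_shifts[st]
        lam[unfaithful[st]] = cfg.unfaithful_shift

    # ---- expression --------------------------------------------------------
    G = cfg.n_genes
    gene_arr = np.array(genes)
    baseline = rng_expr.normal(cfg.baseline_mean, cfg.baseline_sd, G)

    subtype_idx = rng_expr.choice(G, size=cfg.n_subtype_genes, replace=False)
    lineage_idx = rng_expr.choice(
        np.setdiff1d(np.arange(G), subtype_idx), size=cfg.n_lineage_genes, replace=False
    )
    site_idx = rng_expr.choice(G, size=cfg.n_site_genes, replace=False)

    # orthonormal subtype directions with fixed norms: every pair of
    # subtypes sits at the same expression distance (scaled up for Basal),
    # so no subtype is accidentally central to the cohort in a given draw
    basis, _ = np.linalg.qr(
        rng_expr.normal(0.0, 1.0, (cfg.n_subtype_genes, len(subtypes)))
    )
    v = {}
    for i, st in enumerate(subtypes):
        scale = cfg.basal_scale if st == "Basal" else cfg.subtype_scale
        vec = np.zeros(G)
        vec[subtype_idx] = basis[:, i] * scale * np.sqrt(cfg.n_subtype_genes)
        v[st] = vec

    site_vec = {}
    for site in cfg.site_sizes:
        vec = np.zeros(G)
        if site == "bone":
            vec += cfg.bone_basal_alignment * v["Basal"]
            vec[site_idx] += rng_expr.normal(0.0, cfg.bone_scale, cfg.n_site_genes)
        else:
            vec[site_idx] += rng_expr.normal(0.0, cfg.site_scale, cfg.n_site_genes)
        site_vec[site] = vec

    # culture direction: +/-1 on a support overlapping the
    # lineage-informative genes (which dominate marker selection, so the
    # culture shift is visible to the similarity) but disjoint from the
    # subtype genes (so the shift penalty is identical across subtypes)
    n_cult = cfg.n_culture_genes
    n_from_lineage = n_cult * 5 // 7
    cult_from_lineage = rng_expr.choice(lineage_idx, size=n_from_lineage, replace=False)
    remaining = np.setdiff1d(
        np.arange(G), np.concatenate([lineage_idx, subtype_idx])
    )
    cult_other = rng_expr.choice(remaining, size=n_cult - n_from_lineage, replace=False)
    culture_support = np.concatenate([cult_from_lineage, cult_other])
    # sign-balanced so the class-wise rank displacement of unaffected genes
    # cancels in expectation (the activity score is rank-compositional)
    signs = np.ones(n_cult)
    signs[rng_expr.choice(n_cult, size=n_cult // 2, replace=False)] = -1.0
    u = np.zeros(G)
    u[culture_support] = signs

    def _expr(sample_ids, effect_fn) -> pd.DataFrame:
        log2 = np.empty((G, len(sample_ids)))
        for j, sid in enumerate(sample_ids):
            log2[:, j] = baseline + effect_fn(sid) + rng_expr.normal(0.0, cfg.noise_sd, G)
        return pd.DataFrame(2.0 ** log2, index=pd.Index(genes, name="gene"), columns=sample_ids)

    expr_tumor = _expr(tumor_ids, lambda s: v[tumor_subtype[s]] + site_vec[tumor_site[s]])
    nonbreast_w = {
        m: rng_expr.normal(0.0, cfg.lineage_scale, cfg.n_lineage_genes) for m in nonbreast_cl
    }

    unfaithful_ids = set(unfaithful.values())

    def _cl_effect(m: str) -> np.ndarray:
        eff = lam[m] * u
        if m in unfaithful_ids:
            # the planted unfaithful line keeps its subtype label but lacks
            # the subtype expression program (a mislabeled-subtype model)
            return eff
        if m in cl_subtype:
            eff = eff + v[cl_subtype[m]]
        else:
            w = np.zeros(G)
            w[lineage_idx] = nonbreast_w[m]
            eff = eff + w
        return eff

    expr_cl = _expr(breast_cl + nonbreast_cl, _cl_effect)
    expr_org = _expr(organoids, lambda m: v[org_subtype[m]] + lam[m] * u)

    # ---- annotation / panel tiling ----------------------------------------
    per_chrom = cfg.n_panel_genes // cfg.n_cnv_chromosomes
    step = cfg.gene_length + cfg.gene_gap
    ann_rows = []
    for i, g in enumerate(panel):
        chrom = i // per_chrom + 1
        pos = i % per_chrom
        start = 1 + pos * step
        ann_rows.append(
            {
                "symbol": g,
                "has_hgnc": True,
                "has_refseq": True,
                "chromosome": f"chr{chrom}",
                "start": start,
                "end": start + cfg.gene_length - 1,
            }
        )
    annotation = pd.DataFrame(ann_rows)
    # planted filter failures, confined to chromosome 1 so the planted
    # mutation/CNV genes (drawn elsewhere) are never filtered out
    chr1 = annotation.index[annotation["chromosome"] == "chr1"].to_numpy()
    n_fail = cfg.n_no_hgnc + cfg.n_no_refseq + cfg.n_y_chromosome
    fail_idx = rng_assign.choice(chr1, size=n_fail, replace=False)
    annotation.loc[fail_idx[: cfg.n_no_hgnc], "has_hgnc"] = False
    annotation.loc[fail_idx[cfg.n_no_hgnc : cfg.n_no_hgnc + cfg.n_no_refseq], "has_refseq"] = False
    annotation.loc[fail_idx[cfg.n_no_hgnc + cfg.n_no_refseq :], "chromosome"] = "chrY"
    failing_genes = set(annotation.loc[fail_idx, "symbol"])

    # ---- mutations ---------------------------------------------------------
    P = cfg.n_panel_genes
    q_base = rng_mut.uniform(cfg.mut_freq_low, cfg.mut_freq_high, P)
    eligible = [i for i, g in enumerate(panel) if g not in failing_genes and i >= per_chrom]
    planted = rng_mut.choice(
        eligible, size=cfg.n_differential_genes + cfg.n_hypermutated_genes, replace=False
    )
    diff_idx = planted[: cfg.n_differential_genes]
    hyper_idx = planted[cfg.n_differential_genes :]

    q_primary = q_base.copy()
    q_primary[hyper_idx] = cfg.hypermutated_tumor_freq
    q_met = q_primary.copy()
    q_met[diff_idx] = cfg.differential_freq
    q_cl = q_primary.copy()
    q_cl[hyper_idx] = cfg.hypermutated_cl_freq

    def _mut_matrix(sample_ids, q) -> pd.DataFrame:
        draws = rng_mut.random((P, len(sample_ids))) < q[:, None]
        return pd.DataFrame(
            draws.astype(np.int8), index=pd.Index(panel, name="gene"), columns=sample_ids
        )

    m_met = _mut_matrix(tumor_ids, q_met)
    m_primary = _mut_matrix(primary_ids, q_primary)
    m_models = _mut_matrix(breast_cl, q_cl)
    calls_met = _calls_from_matrix(m_met, rng_mut, cfg.silent_rate)
    calls_primary = _calls_from_matrix(m_primary, rng_mut, cfg.silent_rate)
    calls_models = _calls_from_matrix(m_models, rng_mut, cfg.silent_rate)

    # ---- copy number -------------------------------------------------------
    recurrent = rng_cnv.normal(0.0, cfg.recurrent_sd, P)
    distortion = rng_cnv.normal(0.0, cfg.cnv_distortion_sd, P)
    gchrom, glo, ghi = cfg.gain_region
    lchrom, llo, lhi = cfg.loss_region
    gain_slice = slice((gchrom - 1) * per_chrom + glo, (gchrom - 1) * per_chrom + ghi)
    loss_slice = slice((lchrom - 1) * per_chrom + llo, (lchrom - 1) * per_chrom + lhi)
    gain_genes = [g for g in panel[gain_slice] if g not in failing_genes]
    loss_genes = [g for g in panel[loss_slice] if g not in failing_genes]

    forced_breaks = {gchrom: {glo, ghi}, lchrom: {llo, lhi}}

    def _segments(sample_ids, gain_off, loss_off, lam_scale) -> pd.DataFrame:
        rows = []
        for j, sid in enumerate(sample_ids):
            latent = recurrent + rng_cnv.normal(0.0, cfg.cnv_noise_sd, P)
            if lam_scale is not None:
                latent = latent + lam_scale[j] * distortion
            latent[gain_slice] += gain_off[j] if np.ndim(gain_off) else gain_off
            latent[loss_slice] += loss_off
            for chrom in range(1, cfg.n_cnv_chromosomes + 1):
                lo = (chrom - 1) * per_chrom
                breaks = set(
                    rng_cnv.choice(per_chrom - 1, size=cfg.breaks_per_chromosome, replace=False) + 1
                )
                breaks |= forced_breaks.get(chrom, set())
                bounds = [0, *sorted(b for b in breaks if 0 < b < per_chrom), per_chrom]
                for a, b in zip(bounds[:-1], bounds[1:]):
                    rows.append(
                        {
                            "sample": sid,
                            "chromosome": f"chr{chrom}",
                            "start": 1 + a * step,
                            "end": (b - 1) * step + cfg.gene_length,
                            "value": float(latent[lo + a : lo + b].mean()),
                        }
                    )
        return pd.DataFrame(rows, columns=dm.SEG_COLUMNS)

    seg_tumors = _segments(tumor_ids, cfg.gain_tumor, cfg.loss_tumor, None)
    model_gain = np.array(
        [
            cfg.gain_metastatic_model if m in metastatic_derived else cfg.gain_primary_model
            for m in breast_cl
        ]
    )
    seg_models = _segments(
        breast_cl, model_gain, cfg.loss_cellline, np.array([lam[m] for m in breast_cl])
    )

    # ---- gene sets ---------------------------------------------------------
    # culture sets: up-shifted culture genes away from the subtype/site
    # programs (so tumor-side heterogeneity does not dilute the signal);
    # control sets: genes carrying no planted effect at all
    confounded = np.union1d(subtype_idx, site_idx)
    plus_pool = np.setdiff1d(culture_support[signs > 0], confounded)
    plus_genes = gene_arr[np.sort(plus_pool)]
    all_support = np.union1d(
        np.union1d(culture_support, confounded), lineage_idx
    )
    neutral_idx = np.setdiff1d(np.arange(G), all_support)
    # activity scores are rank-compositional: shifting the culture genes
    # also displaces the ranks of unaffected genes. Plant the control sets
    # among effect-free genes whose baseline rank barely moves under the
    # class shifts, so "no planted effect" really means "no activity shift".
    r0 = np.argsort(np.argsort(baseline))
    displacement = np.zeros(G)
    for shift in (cfg.cellline_shift, cfg.organoid_shift):
        shifted = baseline + shift * u
        displacement += np.abs(np.argsort(np.argsort(shifted)) - r0)
    n_control = cfg.n_control_sets * cfg.set_size
    if len(plus_genes) < cfg.n_culture_sets * cfg.set_size:
        raise DomainError("not enough unconfounded culture genes for the requested sets")
    if len(neutral_idx) < n_control:
        raise DomainError("not enough effect-free genes for the requested control sets")
    calm = neutral_idx[np.lexsort((neutral_idx, displacement[neutral_idx]))]
    pool = gene_arr[np.sort(calm[: min(len(calm), n_control * 3 // 2)])]
    picked_plus = rng_assign.choice(
        plus_genes, size=cfg.n_culture_sets * cfg.set_size, replace=False
    )
    picked_neutral = rng_assign.choice(pool, size=n_control, replace=False)
    gene_sets: dict[str, list[str]] = {}
    for i in range(cfg.n_culture_sets):
        gene_sets[f"CULTURE_SET_{i + 1}"] = sorted(
            picked_plus[i * cfg.set_size : (i + 1) * cfg.set_size]
        )
    for i in range(cfg.n_control_sets):
        gene_sets[f"CONTROL_SET_{i + 1}"] = sorted(
            picked_neutral[i * cfg.set_size : (i + 1) * cfg.set_size]
        )

    # ---- metadata ----------------------------------------------------------
    meta_rows = []
    for sid in tumor_ids:
        meta_rows.append((sid, "tumor", "breast", tumor_site[sid], tumor_subtype[sid], "metastatic"))
    for sid in primary_ids:
        meta_rows.append((sid, "tumor", "breast", "none", "unknown", "primary"))
    for m in breast_cl:
        meta_rows.append(
            (m, "cell_line", "breast", "none", cl_subtype[m],
             "metastatic" if m in metastatic_derived else "primary")
        )
    for m in nonbreast_cl:
        meta_rows.append((m, "cell_line", "non_breast", "none", "unknown", "unknown"))
    for m in organoids:
        meta_rows.append((m, "organoid", "breast", "none", org_subtype[m], "metastatic"))
    metadata = pd.DataFrame(meta_rows, columns=dm.METADATA_COLUMNS)

    truth = SyntheticTruth(
        seed=cfg.seed,
        config_digest=cfg.digest(),
        differential_genes=sorted(str(panel[i]) for i in diff_idx),
        hypermutated_genes=sorted(str(panel[i]) for i in hyper_idx),
        gain_region_genes=gain_genes,
        loss_region_genes=loss_genes,
        faithful_models=faithful,
        unfaithful_models=unfaithful,
        best_model_overall=min(lam, key=lambda m: (lam[m], m)),
        culture_magnitudes={m: lam[m] for m in sorted(lam)},
        culture_gene_sets=[f"CULTURE_SET_{i + 1}" for i in range(cfg.n_culture_sets)],
        divergent_site="bone",
        config=cfg.to_dict(),
    )

    study = SyntheticStudy(
        expression={"tumor": expr_tumor, "cell_line": expr_cl, "organoid": expr_org},
        mutation_calls={"metastatic": calls_met, "primary": calls_primary, "models": calls_models},
        segments={"tumors": seg_tumors, "models": seg_models},
        annotation=annotation,
        metadata=metadata,
        gene_sets=gene_sets,
        truth=truth,
    )
    if out_dir is not None:
        _write_study(study, Path(out_dir))
    return study


def _write_study(study: SyntheticStudy, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    dm.write_expression(study.expression["tumor"], out_dir / "expression_tumors.tsv")
    dm.write_expression(study.expression["cell_line"], out_dir / "expression_cell_lines.tsv")
    dm.write_expression(study.expression["organoid"], out_dir / "expression_organoids.tsv")
    dm.write_maf(study.mutation_calls["metastatic"], out_dir / "mutations_metastatic.maf")
    dm.write_maf(study.mutation_calls["primary"], out_dir / "mutations_primary.maf")
    dm.write_maf(study.mutation_calls["models"], out_dir / "mutations_models.maf")
    dm.write_seg(study.segments["tumors"], out_dir / "cnv_tumors.seg")
    dm.write_seg(study.segments["models"], out_dir / "cnv_models.seg")
    dm.write_gene_annotation(study.annotation, out_dir / "gene_annotation.tsv")
    dm.write_bed(study.annotation, out_dir / "genes.bed")
    dm.write_metadata(study.metadata, out_dir / "metadata.tsv")
    dm.write_gmt(study.gene_sets, out_dir / "gene_sets.gmt")
    (out_dir / "truth.json").write_text(study.truth.to_json() + "\n")


def load_truth(path) -> SyntheticTruth:
    return SyntheticTruth(**json.loads(Path(path).read_text()))


def truth_report(truth: SyntheticTruth, outputs: dict) -> dict[str, float]:
    """Recovery metrics of a pipeline run against the planted truth.

    ``outputs`` carries the pipeline products to audit (any subset):
    ``ranking`` (transcriptome ranking table), ``differential`` (the
    differential-mutation table), ``hypermutated`` (gene list),
    ``tumor_cnv_profile`` (a :class:`~modelfidelity.cnv.CNVProfile`),
    plus a ``seed``/``config_digest`` echo which must match the truth.
    Each metric is a direct comparison with the truth fields; nothing is
    re-estimated.
    """
    if outputs.get("seed") != truth.seed or outputs.get("config_digest") != truth.config_digest:
        raise DomainError(
            "outputs echo a different (seed, config) than the truth object"
        )
    report: dict[str, float] = {}
    if "ranking" in outputs:
        ranking = outputs["ranking"]
        row = ranking.loc[ranking["model"] == truth.best_model_overall]
        if row.empty:
            raise DomainError(f"planted best model {truth.best_model_overall!r} not in ranking")
        report["best_model_rank"] = float(row["rank"].iloc[0])
    if "differential" in outputs:
        table = outputs["differential"]
        called = set(table.index[table["q_right"] < 0.001])
        planted = set(truth.differential_genes)
        tp = len(called & planted)
        report["differential_sensitivity"] = tp / len(planted)
        report["differential_false_discoveries"] = float(len(called - planted))
        report["differential_fdr"] = (len(called) - tp) / max(1, len(called))
    if "hypermutated" in outputs:
        report["hypermutated_exact"] = float(
            set(outputs["hypermutated"]) == set(truth.hypermutated_genes)
        )
    if "tumor_cnv_profile" in outputs:
        prof = outputs["tumor_cnv_profile"]
        flagged = [
            g for g in truth.gain_region_genes
            if g in prof.values.index and prof.values[g] >= 0.4
        ]
        report["high_gain_recall"] = len(flagged) / len(truth.gain_region_genes)
    return report
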