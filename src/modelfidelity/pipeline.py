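"""End-to-end orchestration: load inputs, run every evaluation stage in
dependency order, write one TSV per product plus a run manifest.

The same analysis core (:func:`analyze_study`) serves both the file-driven
CLI path and in-memory synthetic studies, so recovery experiments and the
command-line pipeline cannot drift apart.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import cnv as cnvmod
from . import datamodel as dm
from . import genesets as gs
from . import mutation as mut
from . import significance as sig
from . import transcriptome as tc
from .exceptions import DomainError
from .simulate import SyntheticStudy

logger = logging.getLogger("modelfidelity")

__all__ = ["AnalysisParams", "StudyInputs", "RunConfig", "analyze_study", "run_full_analysis"]

ALL_STAGES = ("mutation", "cnv", "tc", "significance", "gsea")


@dataclass
class AnalysisParams:
    """Every threshold the evaluation stages use, with the conventional
    defaults: highly mutated means frequency > 0.05, hypermutation means
    mutated in >= 50% of models while < 5% of tumors, differential calls at
    FDR < 0.001, copy-number loss < 0 and high gain >= 0.4, model
    significance at FDR <= 0.01 / 0.05, differential activity at
    FDR < 0.001, and site/subtype strata need at least 9 samples."""

    marker_k: int = 1000
    highly_mutated_threshold: float = 0.05
    hypermutation_cl_fraction: float = 0.5
    hypermutation_tumor_threshold: float = 0.05
    differential_fdr: float = 0.001
    gain_cut: float = 0.4
    loss_cut: float = 0.0
    evaluation_fdr_levels: tuple[float, float] = (0.01, 0.05)
    da_fdr: float = 0.001
    min_stratum: int = 9
    ssgsea_alpha: float = 0.25
    inclusive_tail: bool = False

    def validate(self) -> None:
        for name in (
            "highly_mutated_threshold",
            "hypermutation_cl_fraction",
            "hypermutation_tumor_threshold",
            "differential_fdr",
            "da_fdr",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise DomainError(f"{name}={v} outside [0, 1]")
        if self.marker_k < 1:
            raise DomainError("marker_k must be >= 1")
        if self.min_stratum < 2:
            raise DomainError("min_stratum must be >= 2")
        lo, hi = self.evaluation_fdr_levels
        if not (0 < lo <= hi <= 1):
            raise DomainError("evaluation FDR levels must satisfy 0 < low <= high <= 1")
        if self.ssgsea_alpha < 0:
            raise DomainError("ssgsea_alpha must be non-negative")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class StudyInputs:
    """Loaded and harmonized in-memory inputs of one evaluation run."""

    expression: dict[str, pd.DataFrame]  # tumor / cell_line / organoid
    mutations: dict[str, pd.DataFrame]  # metastatic / primary / models (binary)
    cnv: dict[str, pd.DataFrame]  # tumors / models (gene-level)
    metadata: pd.DataFrame
    gene_panel: list[str]
    gene_sets: dict[str, list[str]]
    seed: int = 0
    config_digest: str = ""


def _samples_of(metadata: pd.DataFrame, cohort_class: str, **filters) -> list[str]:
    mask = metadata["cohort_class"] == cohort_class
    for col, val in filters.items():
        mask &= metadata[col] == val
    return metadata.loc[mask, "sample"].tolist()


def inputs_from_study(study: SyntheticStudy) -> StudyInputs:
    """Turn a generated synthetic study into analysis-ready inputs,
    exercising the same panel filter and matrix builders as the file path."""
    meta = study.metadata
    panel = dm.filter_gene_panel(study.annotation["symbol"].tolist(), study.annotation)
    ann = study.annotation[study.annotation["symbol"].isin(panel)]
    met_samples = _samples_of(meta, "tumor", derivation_site="metastatic")
    primary_samples = _samples_of(meta, "tumor", derivation_site="primary")
    breast_cl = _samples_of(meta, "cell_line", lineage="breast")

    def _qualify(calls: pd.DataFrame) -> pd.DataFrame:
        # same default class filter the MAF reader applies
        return calls[~calls["classification"].isin(dm.DEFAULT_EXCLUDED_MAF_CLASSES)]

    mutations = {
        "metastatic": dm.mutation_matrix(
            _qualify(study.mutation_calls["metastatic"]), met_samples, panel
        ),
        "primary": dm.mutation_matrix(
            _qualify(study.mutation_calls["primary"]), primary_samples, panel
        ),
        "models": dm.mutation_matrix(
            _qualify(study.mutation_calls["models"]), breast_cl, panel
        ),
    }
    cnv = {
        "tumors": dm.map_segments_to_genes(study.segments["tumors"], ann),
        "models": dm.map_segments_to_genes(study.segments["models"], ann),
    }
    return StudyInputs(
        expression=dict(study.expression),
        mutations=mutations,
        cnv=cnv,
        metadata=meta,
        gene_panel=panel,
        gene_sets=dict(study.gene_sets),
        seed=study.truth.seed,
        config_digest=study.truth.config_digest,
    )


def load_inputs(paths: dict[str, str]) -> StudyInputs:
    """Load the input file suite (the layout ``generate_cohort`` writes)."""
    annotation = dm.read_gene_annotation(paths["annotation"])
    metadata = dm.read_metadata(paths["metadata"])
    panel = dm.filter_gene_panel(annotation["symbol"].tolist(), annotation)
    ann = annotation[annotation["symbol"].isin(panel)]
    met_samples = _samples_of(metadata, "tumor", derivation_site="metastatic")
    primary_samples = _samples_of(metadata, "tumor", derivation_site="primary")
    breast_cl = _samples_of(metadata, "cell_line", lineage="breast")
    mutations = {
        "metastatic": dm.mutation_matrix(dm.read_maf(paths["maf_metastatic"]), met_samples, panel),
        "primary": dm.mutation_matrix(dm.read_maf(paths["maf_primary"]), primary_samples, panel),
        "models": dm.mutation_matrix(dm.read_maf(paths["maf_models"]), breast_cl, panel),
    }
    cnv = {
        "tumors": dm.map_segments_to_genes(dm.read_seg(paths["seg_tumors"]), ann),
        "models": dm.map_segments_to_genes(dm.read_seg(paths["seg_models"]), ann),
    }
    return StudyInputs(
        expression={
            "tumor": dm.read_expression(paths["expression_tumors"]),
            "cell_line": dm.read_expression(paths["expression_cell_lines"]),
            "organoid": dm.read_expression(paths["expression_organoids"]),
        },
        mutations=mutations,
        cnv=cnv,
        metadata=metadata,
        gene_panel=panel,
        gene_sets=dm.read_gmt(paths["gene_sets"]) if paths.get("gene_sets") else {},
    )


def analyze_study(
    inputs: StudyInputs,
    params: AnalysisParams | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
) -> dict:
    """Run the evaluation stages on loaded inputs and return every product.

    Stages (any subset of ``mutation``, ``cnv``, ``tc``, ``significance``,
    ``gsea``; significance requires tc) mirror the analysis flow:
    genomic-profile comparison, transcriptome-correlation ranking,
    fitted-null significance calling and gene-set differential activity.
    """
    params = params or AnalysisParams()
    params.validate()
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise DomainError(f"unknown stage(s) {sorted(unknown)}")
    meta = inputs.metadata
    out: dict = {"seed": inputs.seed, "config_digest": inputs.config_digest}

    if "mutation" in stages:
        met = inputs.mutations["metastatic"]
        met_freqs = mut.mutation_frequencies(met)
        primary_freqs = mut.mutation_frequencies(inputs.mutations["primary"])
        highly = mut.highly_mutated(met_freqs, params.highly_mutated_threshold)
        table = mut.differential_mutation_test(
            met, primary_freqs, inclusive_tail=params.inclusive_tail
        )
        differential = sorted(table.index[table["q_right"] < params.differential_fdr])
        panel_genes = mut.merge_candidate_panel(highly, differential, met_freqs)
        hyper = mut.cellline_hypermutation(
            inputs.mutations["models"],
            met_freqs,
            params.hypermutation_cl_fraction,
            params.hypermutation_tumor_threshold,
        )
        out["mutation"] = {
            "met_frequencies": met_freqs,
            "primary_frequencies": primary_freqs,
            "highly_mutated": highly,
            "differential": table,
            "differential_significant": differential,
            "candidate_panel": panel_genes,
            "hypermutated": hyper,
            "recapitulation": mut.recapitulation_report(
                panel_genes, inputs.mutations["models"], highly, differential, hyper
            ),
        }

    if "cnv" in stages:
        cnv_t, cnv_m = inputs.cnv["tumors"], inputs.cnv["models"]
        tumor_profile = cnvmod.median_profile(cnv_t, cnv_t.columns, "tumors")
        model_profile = cnvmod.median_profile(cnv_m, cnv_m.columns, "cell_lines")
        part_models = cnvmod.gain_loss_partition(model_profile, params.loss_cut, params.gain_cut)
        part_tumors = cnvmod.gain_loss_partition(tumor_profile, params.loss_cut, params.gain_cut)
        shift_tests = {}
        for label, genes in (("loss", part_models["loss"]), ("gain", part_models["gain"])):
            shared = [g for g in genes if g in tumor_profile.values.index]
            shift_tests[label] = cnvmod.partition_shift_test(shared, model_profile, tumor_profile)
        high_gain = [g for g in part_tumors["high_gain"] if g in cnv_m.index]
        subgroup_tests = {}
        for label, derivation in (("metastatic_derived", "metastatic"), ("primary_derived", "primary")):
            members = [
                s for s in _samples_of(meta, "cell_line", derivation_site=derivation)
                if s in cnv_m.columns
            ]
            if len(members) < 2:
                continue
            prof = cnvmod.median_profile(cnv_m, members, label)
            shared = [g for g in high_gain if g in prof.values.index]
            subgroup_tests[label] = {
                "test": cnvmod.partition_shift_test(shared, prof, tumor_profile),
                "median_gap": float(
                    (tumor_profile.values.loc[shared] - prof.values.loc[shared]).median()
                ),
            }
        shared_panel = [
            g for g in inputs.gene_panel
            if g in tumor_profile.values.index and g in model_profile.values.index
        ]
        out["cnv"] = {
            "tumor_profile": tumor_profile,
            "model_profile": model_profile,
            "profile_correlation": cnvmod.profile_correlation(tumor_profile, model_profile),
            "partition_models": part_models,
            "partition_tumors": part_tumors,
            "shift_tests": shift_tests,
            "subgroup_high_gain": subgroup_tests,
            "ranking": cnvmod.rank_models_by_cnv(cnv_m, cnv_t, shared_panel),
        }

    if "tc" in stages or "significance" in stages:
        tumors_expr = inputs.expression["tumor"]
        cl_expr = inputs.expression["cell_line"]
        org_expr = inputs.expression["organoid"]
        shared_genes = tumors_expr.index.intersection(cl_expr.index).intersection(org_expr.index)
        tumors_expr = tumors_expr.loc[shared_genes]
        models_expr = pd.concat([cl_expr.loc[shared_genes], org_expr.loc[shared_genes]], axis=1)
        markers = tc.select_marker_genes(cl_expr.loc[shared_genes], k=params.marker_k)
        ranking = tc.rank_models(models_expr, tumors_expr, markers, meta)
        stratified = {}
        agreement = {}
        for by in ("metastatic_site", "subtype"):
            try:
                strat = tc.stratified_similarity(
                    models_expr, tumors_expr, meta, markers, by, params.min_stratum
                )
            except Exception as exc:  # no qualifying stratum
                logger.info("event=stratification_skipped by=%s reason=%s", by, exc)
                continue
            stratified[by] = strat
            if strat["stratum"].nunique() >= 2:
                agreement[by] = tc.stratum_agreement(strat)
        out["tc"] = {
            "markers": markers,
            "ranking": ranking,
            "stratified": stratified,
            "agreement": agreement,
        }

    if "significance" in stages:
        strat = out["tc"]["stratified"].get("subtype")
        if strat is None:
            raise DomainError("significance stage needs a subtype stratification")
        lineage = meta.set_index("sample")["lineage"]
        klass = meta.set_index("sample")["cohort_class"]
        is_cl = strat["model"].map(klass) == "cell_line"
        cand = strat[is_cl & (strat["model"].map(lineage) == "breast")]
        background = strat[is_cl & (strat["model"].map(lineage) != "breast")]
        evaluation = sig.evaluate_models(cand, background, params.evaluation_fdr_levels)
        ranking = out["tc"]["ranking"]
        org_sims = ranking.loc[ranking["cohort_class"] == "organoid", "similarity"]
        cl_sims = ranking.loc[
            (ranking["cohort_class"] == "cell_line")
            & (ranking["lineage"] == "breast"),
            "similarity",
        ]
        out["significance"] = {
            "evaluation": evaluation,
            "organoid_vs_cellline": sig.compare_model_classes(org_sims, cl_sims),
        }

    if "gsea" in stages:
        if not inputs.gene_sets:
            raise DomainError("gsea stage needs a gene-set collection")
        tumors_expr = inputs.expression["tumor"]
        lineage = meta.set_index("sample")["lineage"]
        breast_cl_cols = [
            s for s in inputs.expression["cell_line"].columns if lineage.get(s) == "breast"
        ]
        scores = {
            "tumor": gs.score_matrix(tumors_expr, inputs.gene_sets, params.ssgsea_alpha),
            "cell_line": gs.score_matrix(
                inputs.expression["cell_line"][breast_cl_cols],
                inputs.gene_sets,
                params.ssgsea_alpha,
            ),
            "organoid": gs.score_matrix(
                inputs.expression["organoid"], inputs.gene_sets, params.ssgsea_alpha
            ),
        }
        subtype = meta.set_index("sample")["subtype"]
        groups = {
            "non_basal": lambda s: subtype.get(s) not in ("Basal", "unknown", None),
            "basal": lambda s: subtype.get(s) == "Basal",
        }
        da = {}
        categories = {}
        for label, belongs in groups.items():
            t_cols = [s for s in scores["tumor"].columns if belongs(s)]
            cl_cols = [s for s in scores["cell_line"].columns if belongs(s)]
            org_cols = [s for s in scores["organoid"].columns if belongs(s)]
            if min(len(t_cols), len(cl_cols), len(org_cols)) < 2:
                logger.info("event=da_group_skipped group=%s", label)
                continue
            da_cl = gs.differential_activity(
                scores["tumor"][t_cols], scores["cell_line"][cl_cols], params.da_fdr
            )
            da_org = gs.differential_activity(
                scores["tumor"][t_cols], scores["organoid"][org_cols], params.da_fdr
            )
            da[label] = {"vs_cell_line": da_cl, "vs_organoid": da_org}
            categories[label] = gs.categorize(da_cl["significant"], da_org["significant"])
        consensus, discordant = (
            gs.consensus_categories(categories) if len(categories) >= 2 else (None, None)
        )
        out["gsea"] = {
            "scores": scores,
            "da": da,
            "categories": categories,
            "consensus": consensus,
            "discordant": discordant,
        }

    return out


# ---------------------------------------------------------------------------
# file-driven full run
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Inputs, thresholds and output location of one full pipeline run."""

    paths: dict[str, str]
    out_dir: str
    params: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES


def _write_table(df: pd.DataFrame, path: Path, header: str, index: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index)


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every configured stage on the input files and write one TSV
    per product plus ``manifest.json``. Reruns with identical inputs and
    configuration reproduce identical outputs."""
    config.params.validate()
    inputs = load_inputs(config.paths)
    inputs.seed = config.seed
    results = analyze_study(inputs, config.params, config.stages)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.params.digest()
    header = f"# modelfidelity={__version__} params_digest={digest} seed={config.seed}\n"
    counts: dict[str, int] = {}

    def _emit(name: str, df: pd.DataFrame, index: bool = True) -> None:
        _write_table(df, out / f"{name}.tsv", header, index=index)
        counts[name] = len(df)

    if "mutation" in results:
        r = results["mutation"]
        _emit("differential_mutation", r["differential"])
        _emit("recapitulation", r["recapitulation"])
        freq = pd.DataFrame(
            {"freq_met": r["met_frequencies"], "freq_primary": r["primary_frequencies"]}
        )
        freq["highly_mutated"] = freq.index.isin(r["highly_mutated"])
        _emit("mutation_frequencies", freq)
        _emit(
            "hypermutated",
            pd.DataFrame({"gene": r["hypermutated"]}),
            index=False,
        )
    if "cnv" in results:
        r = results["cnv"]
        prof = pd.DataFrame(
            {
                "median_tumor": r["tumor_profile"].values,
                "median_model": r["model_profile"].values,
            }
        )
        membership = pd.DataFrame(
            {
                f"{side}_{part}": prof.index.isin(r[f"partition_{side}"][part])
                for side in ("tumors", "models")
                for part in ("loss", "gain", "high_gain")
            },
            index=prof.index,
        )
        _emit("cnv_profiles", pd.concat([prof, membership], axis=1))
        _emit("cnv_ranking", r["ranking"], index=False)
        tests = [
            {"comparison": k, "statistic": t.statistic, "p_value": t.p_value,
             "direction": t.direction}
            for k, t in r["shift_tests"].items()
        ] + [
            {"comparison": f"high_gain_{k}", "statistic": v["test"].statistic,
             "p_value": v["test"].p_value, "direction": v["test"].direction}
            for k, v in r["subgroup_high_gain"].items()
        ]
        _emit("cnv_shift_tests", pd.DataFrame(tests), index=False)
    if "tc" in results:
        r = results["tc"]
        _emit("tc_ranking", r["ranking"], index=False)
        for by, strat in r["stratified"].items():
            _emit(f"tc_stratified_{by}", strat, index=False)
        for by, agree in r["agreement"].items():
            _emit(f"tc_agreement_{by}", agree)
    if "significance" in results:
        r = results["significance"]
        _emit("cellline_evaluation", r["evaluation"], index=False)
        comp = r["organoid_vs_cellline"]
        _emit(
            "class_comparison",
            pd.DataFrame(
                [{"comparison": "organoid_vs_cellline", "statistic": comp.statistic,
                  "p_value": comp.p_value, "direction": comp.direction}]
            ),
            index=False,
        )
    if "gsea" in results:
        r = results["gsea"]
        _emit("ssgsea_scores", pd.concat(r["scores"], axis=1))
        for label, pair in r["da"].items():
            merged = pair["vs_cell_line"].join(
                pair["vs_organoid"], lsuffix="_vs_cell_line", rsuffix="_vs_organoid"
            )
            merged["category"] = r["categories"][label]
            _emit(f"da_{label}", merged)
        if r["consensus"] is not None:
            _emit("da_consensus", r["consensus"].to_frame())

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "params": dataclasses.asdict(config.params),
        "params_digest": digest,
        "inputs": {k: str(v) for k, v in config.paths.items()},
        "stages": list(config.stages),
        "row_counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return results
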