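"""End-to-end orchestration of the profiling and survival stages.

``run_profiling`` ties the expression side together: genome and tag
catalog, tag emission, <=1-mismatch mapping, TPM normalization, paired
Audic-Claverie calls, recurrence aggregation, truth-overlap testing and
two-way clustering, with all artifacts and a machine-readable report
written to the configured output directory.  ``run_survival`` covers
the IHC side: staining indices, dichotomization, association tests,
Kaplan-Meier / log-rank, univariate and multivariate Cox, and the
combined-marker stratification.  Identical config and seed give
byte-identical reports.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

import dgekit.io as dio
from dgekit import __version__
from dgekit.config import MARKERS, RunConfig
from dgekit.crosscohort import (
    direction_stratified_overlap,
    hierarchical_cluster,
    cluster_heat_export,
)
from dgekit.diffexpr import call_pair, recurrent_genes
from dgekit.prognosis import (
    association_tests,
    cox_fit,
    kaplan_meier,
    logrank_test,
    marker_combination,
    staining_index,
)
from dgekit.quant import expression_matrix, map_tags
from dgekit.reference import build_tag_catalog
from dgekit.simulate import simulate_cohort, simulate_genome, simulate_paired_counts, simulate_tags


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc
    return wrap


def run_profiling(config: RunConfig) -> dict:
    """Execute catalog -> map -> normalize -> DE -> recurrence -> cluster."""
    config.validate()
    sim = config.simulation
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- substrate: genome + annotation -------------------------------
    if config.genome_fasta and config.annotation_bed:
        genome = _stage("read-genome")(dio.read_fasta, config.genome_fasta)
        annotation = _stage("read-annotation")(dio.read_bed, config.annotation_bed)
    else:
        n_chrom = 4
        chrom_length = max(200, math.ceil(sim.n_genes * 700 / n_chrom))
        genome, annotation = _stage("simulate-genome")(
            simulate_genome, n_chrom, chrom_length, sim.n_genes, sim.seed
        )
        dio.write_fasta(genome, outdir / "genome.fa")
        dio.write_bed(annotation, outdir / "annotation.bed")

    catalog = _stage("build-catalog")(build_tag_catalog, genome, annotation)
    catalog.to_frame().to_csv(outdir / "tag_catalog.tsv", sep="\t", index=False)

    # --- counts and tag libraries -------------------------------------
    study = _stage("simulate-counts")(simulate_paired_counts, sim)
    dio.write_counts(study.normal, outdir / "counts_normal.tsv")
    dio.write_counts(study.tumor, outdir / "counts_tumor.tsv")
    study.truth.to_csv(outdir / "truth.tsv", sep="\t", index_label="gene_id")

    if config.tag_dir:
        tag_files = sorted(Path(config.tag_dir).glob("*.tsv"))
        libraries = {f.stem: dio.read_tags(f) for f in tag_files}
    else:
        libraries = _stage("simulate-tags")(
            simulate_tags, study, catalog, sim.tag_error_rate, sim.seed + 7
        )
        tags_dir = outdir / "tags"
        tags_dir.mkdir(exist_ok=True)
        for lib_id, tags in libraries.items():
            dio.write_tags(tags, tags_dir / f"{lib_id}.tsv")

    # --- mapping and normalization ------------------------------------
    mapped = {
        lib_id: _stage("map-tags")(map_tags, tags, catalog, 1, lib_id)
        for lib_id, tags in libraries.items()
    }
    mapping_summary = {
        lib_id: {
            "clean_tags": lc.clean_tag_total,
            "unique_mapped": lc.unique_mapped_total,
            "unmapped": lc.unmapped,
            "ambiguous": lc.ambiguous,
            "genes_detected": len(lc.gene_counts),
        }
        for lib_id, lc in mapped.items()
    }
    gene_universe = catalog.genes_with_canonical
    tpm = expression_matrix(
        list(mapped.values()), gene_universe, denominator=config.tpm_denominator
    )
    tpm.to_csv(outdir / "tpm.tsv", sep="\t", index_label="gene_id")

    # --- per-pair differential expression -----------------------------
    patients = study.patients
    pair_results: dict[str, pd.DataFrame] = {}
    for patient in patients:
        normal_lc = mapped[f"{patient}_normal"]
        tumor_lc = mapped[f"{patient}_tumor"]
        denom = (
            "unique_mapped_total"
            if config.tpm_denominator == "unique"
            else "clean_tag_total"
        )
        res = _stage("call-pair")(
            call_pair,
            tumor_lc.counts_series(gene_universe),
            normal_lc.counts_series(gene_universe),
            getattr(normal_lc, denom),
            getattr(tumor_lc, denom),
            config.fold_threshold,
            config.fdr_threshold,
        )
        pair_results[patient] = res
        res.to_csv(outdir / f"de_{patient}.tsv", sep="\t", index_label="gene_id")

    rec = _stage("recurrence")(
        recurrent_genes, pair_results, config.min_cases,
        config.min_avg_fold, config.recurrence_over,
    )
    rec.to_csv(outdir / "recurrent_genes.tsv", sep="\t", index_label="gene_id")

    # --- planted-truth recovery and overlap ---------------------------
    truth = study.truth.reindex(rec.index).fillna({"is_de": False})
    detected = set(rec.index[rec["is_recurrent"]])
    planted = set(truth.index[truth["is_de"].astype(bool)])
    recall = len(detected & planted) / len(planted) if planted else float("nan")
    fdr_emp = (
        len(detected - planted) / len(detected) if detected else 0.0
    )
    overlap = None
    if planted and detected:
        up_d = set(rec.index[rec["is_recurrent"] & (rec["direction"] == "up")])
        down_d = detected - up_d
        up_p = set(truth.index[truth["is_de"].astype(bool) & (truth["sign"] > 0)])
        down_p = planted - up_p
        overlap = {
            k: {
                "overlap": r.overlap_size,
                "set_a": r.set_a_size,
                "set_b": r.set_b_size,
                "universe": r.universe_size,
                "p_value": r.p_value,
            }
            for k, r in direction_stratified_overlap(
                up_d, down_d, up_p, down_p, set(rec.index)
            ).items()
        }

    # --- clustering of log2ratio profiles over recurrent genes --------
    clustering = None
    if len(detected) >= 2 and len(patients) >= 2:
        profile = pd.concat(
            {p: pair_results[p]["log2ratio"] for p in patients}, axis=1
        ).loc[sorted(detected)]
        row_d = _stage("cluster")(hierarchical_cluster, profile, 0)
        col_d = _stage("cluster")(hierarchical_cluster, profile, 1)
        files = cluster_heat_export(profile, row_d, col_d, outdir, "clustered")
        clustering = {
            "n_genes": profile.shape[0],
            "n_samples": profile.shape[1],
            "sample_leaf_order": col_d.ordered_labels,
            "files": {k: str(Path(v).name) for k, v in files.items()},
        }

    n_rec = int(rec["is_recurrent"].sum())
    report = _jsonify(
        {
            "version": __version__,
            "parameters": config.to_dict(),
            "stages": {
                "catalog": {
                    "n_tags": len(catalog),
                    "n_genes_with_canonical": len(gene_universe),
                    "no_canonical": catalog.no_canonical_report(annotation),
                    "genome_digest": catalog.genome_digest,
                },
                "mapping": mapping_summary,
                "differential_expression": {
                    p: int(pair_results[p]["is_de"].sum()) for p in patients
                },
                "recurrence": {
                    "n_recurrent": n_rec,
                    "n_up": int(
                        (rec["is_recurrent"] & (rec["direction"] == "up")).sum()
                    ),
                    "n_down": int(
                        (rec["is_recurrent"] & (rec["direction"] == "down")).sum()
                    ),
                    "min_cases": config.min_cases
                    or math.ceil(0.5 * len(patients)),
                },
                "recovery": {
                    "n_planted": len(planted),
                    "recall": recall,
                    "empirical_fdr": fdr_emp,
                },
                "overlap_with_truth": overlap,
                "clustering": clustering,
            },
        }
    )
    dio.write_report(report, outdir / "profiling_report.json")
    return report


def run_survival(config: RunConfig) -> dict:
    """Execute scoring -> dichotomization -> associations -> KM/Cox."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.clinical_table:
        clinical = _stage("read-clinical")(dio.read_clinical, config.clinical_table)
    else:
        clinical = _stage("simulate-cohort")(simulate_cohort, config.simulation)
        dio.write_clinical(clinical, outdir / "clinical.tsv")

    # staining indices + dichotomization
    for m in MARKERS:
        scores = [
            staining_index(
                row[f"{m}_proportion_pct"], int(row[f"{m}_intensity_grade"]),
                combine=config.staining_combine, cutoff=config.staining_cutoff,
            )
            for _, row in clinical.iterrows()
        ]
        clinical[f"{m}_index"] = [s.staining_index for s in scores]
        clinical[f"{m}_group"] = [s.group for s in scores]
    dio.write_clinical(clinical, outdir / "clinical_scored.tsv")

    assoc = _stage("associations")(association_tests, clinical)
    assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)

    n_events = int(clinical["event"].sum())
    km_logrank = {}
    km_dir = outdir / "km"
    km_dir.mkdir(exist_ok=True)
    for m in MARKERS:
        curves = _stage("kaplan-meier")(kaplan_meier, clinical, f"{m}_group")
        for label, curve in curves.items():
            curve.to_csv(km_dir / f"{m}_{label}.tsv", sep="\t", index=False)
        entry = {"groups": {g: int((clinical[f"{m}_group"] == g).sum()) for g in curves}}
        if n_events >= 1 and clinical[f"{m}_group"].nunique() == 2:
            stat, p = logrank_test(clinical, f"{m}_group")
            entry.update({"logrank_statistic": stat, "logrank_p": p})
        km_logrank[m] = entry

    cox_report: dict = {}
    covariates = ["sex", "age", "t_stage"] + [f"{m}_group" for m in MARKERS]
    if n_events == 0:
        cox_report["refused"] = "no events in the cohort; Cox regression not identifiable"
    else:
        uni = {}
        for cov in covariates:
            fit = _stage("cox-univariate")(cox_fit, clinical, [cov])
            uni[cov] = fit.summary.round(6).to_dict(orient="index")
        multi_fit = _stage("cox-multivariate")(cox_fit, clinical, covariates)
        cox_report = {
            "univariate": uni,
            "multivariate": multi_fit.summary.round(6).to_dict(orient="index"),
            "multivariate_converged": multi_fit.converged,
            "n": multi_fit.n,
            "n_events": multi_fit.n_events,
        }
        multi_fit.summary.to_csv(outdir / "cox_multivariate.tsv", sep="\t",
                                 index_label="term")

    combo = None
    try:
        combo_res = marker_combination(clinical)
        combo = {
            "n_high_risk": combo_res["n_high_risk"],
            "n_other": combo_res["n_other"],
            "n_excluded": combo_res["n_excluded"],
            "logrank_statistic": combo_res["logrank_statistic"],
            "logrank_p": combo_res["logrank_p"],
        }
        for label, curve in combo_res["km_curves"].items():
            curve.to_csv(km_dir / f"combined_{label}.tsv", sep="\t", index=False)
    except ValueError as exc:
        combo = {"refused": str(exc)}

    report = _jsonify(
        {
            "version": __version__,
            "parameters": config.to_dict(),
            "n_patients": len(clinical),
            "n_events": n_events,
            "associations": assoc.to_dict(orient="records"),
            "km_logrank": km_logrank,
            "cox": cox_report,
            "combined_marker": combo,
        }
    )
    dio.write_report(report, outdir / "survival_report.json")
    return report
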