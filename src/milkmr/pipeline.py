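"""Stage drivers wiring the modules into a file-based pipeline.

Each stage reads/writes plain TSV so runs are machine-diffable; the CLI
and the analysis scripts are thin wrappers around these functions.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .exceptions import AnalysisError, ValidationError
from .instrument import weighted_score
from .phecode_engine import PhecodeMap, build_phenotype_matrix, filter_min_cases, map_records
from .phewas_scan import run_phewas, stratified_scan
from .reporting import RunManifest, format_assoc_table, manhattan_data
from .synthetic_biobank import PHENOTYPE_PREFIX, generate_summary_stats, simulate_cohort
from .tableio import config_hash, read_tsv, write_tsv
from .two_sample_mr import SnpSummaryStat, mr_pipeline, to_or_ci

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "snp", "effect_allele", "other_allele", "beta", "se", "n", "n_case", "n_control", "unit",
]


def _stat_row(stat: SnpSummaryStat, **extra) -> dict:
    row = {
        "snp": stat.snp_id,
        "effect_allele": stat.effect_allele,
        "other_allele": stat.other_allele,
        "beta": stat.beta,
        "se": stat.se,
        "n": stat.n,
        "n_case": stat.n_case,
        "n_control": stat.n_control,
        "unit": stat.unit,
    }
    row.update(extra)
    return row


def _manifest(config: PipelineConfig, stage: str) -> RunManifest:
    return RunManifest(
        config_hash=config_hash(config.raw),
        seed=config.cohort.seed,
        stage=stage,
        version=__version__,
    )


def simulate_stage(config: PipelineConfig, outdir, pmap: PhecodeMap) -> dict:
    """Generate a cohort, its ICD records and GWAS-style summary statistics."""
    outdir = Path(outdir)
    sim = simulate_cohort(config.cohort, pmap)
    cohort_path = write_tsv(sim.cohort.reset_index(), outdir / "cohort.tsv")
    records_path = write_tsv(sim.records, outdir / "icd_records.tsv")

    exposure_rows, outcome_rows = [], []
    for spec in config.cohort.outcome_specs:
        exp_stat, out_stat = generate_summary_stats(sim.cohort, spec.phecode, config.instrument)
        if not exposure_rows:
            exposure_rows.append(_stat_row(exp_stat))
        outcome_rows.append(_stat_row(out_stat, outcome=spec.phecode))
    exposure_path = write_tsv(pd.DataFrame(exposure_rows, columns=SUMMARY_COLUMNS), outdir / "exposure_stats.tsv")
    outcome_path = write_tsv(
        pd.DataFrame(outcome_rows, columns=["outcome"] + SUMMARY_COLUMNS), outdir / "outcome_stats.tsv"
    )

    manifest = _manifest(config, "simulate")
    manifest.record(cohort_path, len(sim.cohort))
    manifest.record(records_path, len(sim.records))
    manifest.record(exposure_path, len(exposure_rows))
    manifest.record(outcome_path, len(outcome_rows))
    manifest.write(outdir / "manifest_simulate.json")
    return {
        "cohort": cohort_path,
        "records": records_path,
        "exposure_stats": exposure_path,
        "outcome_stats": outcome_path,
    }


def phewas_stage(
    config: PipelineConfig,
    cohort_path,
    records_path,
    outdir,
    pmap: PhecodeMap,
    no_bmi_sensitivity: bool = False,
    stratify_bmi: bool = False,
) -> dict:
    """Map records to phecodes and scan the genetic score across them."""
    outdir = Path(outdir)
    cohort = read_tsv(cohort_path, dtype={"center": str})
    if "person_id" not in cohort.columns:
        raise ValidationError("cohort table must have a person_id column")
    cohort = cohort.set_index("person_id")
    records = read_tsv(records_path, dtype={"code": str, "vocabulary": str})

    indicators = map_records(records, pmap)
    sex = cohort["sex"].map({1: "F", 0: "M"}) if "sex" in cohort.columns else None
    matrix = build_phenotype_matrix(indicators, pmap, cohort.index, sex=sex)
    matrix = filter_min_cases(matrix, config.scan.min_cases)
    score = weighted_score(cohort["dosage"].to_numpy(), config.instrument, config.mr.unit_g)
    covariates = cohort.drop(
        columns=[c for c in cohort.columns if c in ("dosage", "exposure") or c.startswith(PHENOTYPE_PREFIX)]
    )

    manifest = _manifest(config, "phewas")
    results = run_phewas(matrix, score, covariates, config.scan)
    out = {"results": write_tsv(results, outdir / "phewas_results.tsv")}
    manifest.record(out["results"], len(results))
    if no_bmi_sensitivity:
        from dataclasses import replace

        res_nobmi = run_phewas(matrix, score, covariates, replace(config.scan, include_bmi=False))
        out["results_no_bmi"] = write_tsv(res_nobmi, outdir / "phewas_results_no_bmi.tsv")
        manifest.record(out["results_no_bmi"], len(res_nobmi))
    if stratify_bmi:
        low, high = stratified_scan(matrix, score, covariates, config.scan)
        out["results_bmi_low"] = write_tsv(low, outdir / "phewas_results_bmi_lt25.tsv")
        out["results_bmi_high"] = write_tsv(high, outdir / "phewas_results_bmi_ge25.tsv")
        manifest.record(out["results_bmi_low"], len(low))
        manifest.record(out["results_bmi_high"], len(high))
    manifest.write(outdir / "manifest_phewas.json")
    return out


MR_COLUMNS = ["outcome", "source", "n_case", "n_control", "beta", "se", "or", "ci_low", "ci_high", "p"]


def _read_stat_row(row: pd.Series, unit: str) -> SnpSummaryStat:
    def _opt(key):
        v = row.get(key)
        return int(v) if pd.notna(v) else None

    return SnpSummaryStat(
        snp_id=str(row["snp"]),
        effect_allele=str(row["effect_allele"]),
        other_allele=str(row["other_allele"]),
        beta=float(row["beta"]),
        se=float(row["se"]),
        n=_opt("n"),
        n_case=_opt("n_case"),
        n_control=_opt("n_control"),
        unit=str(row.get("unit") or unit),
    )


def mr_stage(
    config: PipelineConfig,
    outdir,
    exposure_path=None,
    outcomes_path=None,
    ratios_path=None,
) -> dict:
    """Two-sample MR from summary TSVs, or OR conversion of per-50g ratios.

    With ``exposure_path``/``outcomes_path``, harmonizes each outcome row
    against the exposure statistic and runs the Wald-ratio pipeline.  With
    ``ratios_path`` (columns outcome, beta, se already on the per-50 g/day
    log-odds scale), applies only the OR/CI conversion.
    """
    outdir = Path(outdir)
    rows = []
    if ratios_path is not None:
        table = read_tsv(ratios_path, dtype={"outcome": str})
        for _, row in table.iterrows():
            est = to_or_ci(float(row["beta"]), float(row["se"]))
            rows.append(
                {
                    "outcome": row.get("outcome", ""),
                    "source": row.get("source", ""),
                    "n_case": row.get("n_case", np.nan),
                    "n_control": row.get("n_control", np.nan),
                    "beta": float(row["beta"]),
                    "se": float(row["se"]),
                    "or": est.or_,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "p": est.p,
                }
            )
    else:
        if exposure_path is None or outcomes_path is None:
            raise ValidationError("mr stage needs either --ratios or both --exposure and --outcomes")
        exposure = _read_stat_row(read_tsv(exposure_path).iloc[0], unit="g/day per allele")
        outcomes = read_tsv(outcomes_path, dtype={"outcome": str})
        for _, row in outcomes.iterrows():
            stat = _read_stat_row(row, unit="log-odds per allele")
            est = mr_pipeline(exposure, stat, unit_g=config.mr.unit_g, method=config.mr.method)
            rows.append(
                {
                    "outcome": row.get("outcome", ""),
                    "source": row.get("source", "synthetic cohort"),
                    "n_case": stat.n_case,
                    "n_control": stat.n_control,
                    "beta": est.beta_mr,
                    "se": est.se_mr,
                    "or": est.or_,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "p": est.p,
                }
            )
    if not rows:
        raise AnalysisError("no outcome rows for the MR stage")
    results = pd.DataFrame(rows, columns=MR_COLUMNS)
    path = write_tsv(results, outdir / "mr_results.tsv")
    manifest = _manifest(config, "mr")
    manifest.record(path, len(results))
    manifest.write(outdir / "manifest_mr.json")
    return {"results": path}


def report_stage(config: PipelineConfig, results_path, outdir, results_no_bmi_path=None, dash: str = "-") -> dict:
    """Publication-style association table and Manhattan plot data."""
    outdir = Path(outdir)
    results = read_tsv(results_path, dtype={"phecode": str})
    no_bmi = read_tsv(results_no_bmi_path, dtype={"phecode": str}) if results_no_bmi_path else None
    style = "both" if no_bmi is not None else "bmi_adjusted"
    text = format_assoc_table(results, style=style, results_no_bmi=no_bmi, dash=dash)
    table_path = Path(outdir) / "assoc_table.tsv"
    table_path.parent.mkdir(parents=True, exist_ok=True)
    table_path.write_text(text)
    mh = manhattan_data(results, config.scan.fdr_level)
    mh_path = write_tsv(mh, outdir / "manhattan.tsv")
    manifest = _manifest(config, "report")
    manifest.record(table_path, len(results))
    manifest.record(mh_path, len(mh))
    manifest.write(outdir / "manifest_report.json")
    return {"table": table_path, "manhattan": mh_path}
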