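"""End-to-end reproducibility pipeline and report rendering.

Stage order mirrors the study's analysis: ingest (or simulate) the
concentration table -> CSF partial-volume correction -> CRLB quality filter
-> head-movement summary -> intra/inter-subject variability -> inferential
statistics (repeated-measures ANOVA, ANCOVA, CRLB-CV correlation) -> report.
Every run writes a provenance manifest (config hash, package version, seed,
per-stage record counts) and is deterministic given inputs and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inferential import COVARIATES, ancova_covariates, crlb_cv_correlation, rm_anova_sessions
from .movement import read_realignment, summarize_movement
from .study_data import (
    QualityPolicy,
    StudyTable,
    filter_by_crlb,
    read_concentration_table,
)
from .variability import (
    ResamplingConfig,
    VariabilityReport,
    aggregate_report,
    compute_cv_results,
)
from .voxel_geometry import csf_correct

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "render_report", "apply_csf_correction"]

log = logging.getLogger("mrsrepro")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Inputs, options and output location for one pipeline run.

    With ``concentrations=None`` a synthetic study at the default design is
    generated under ``seed``.  ``csf_fractions`` (a CSV keyed by subject,
    session, region with an ``f_csf`` column, or the synthetic covariate
    table) enables the partial-volume correction; ``covariates`` (same key,
    columns gm_wm_ratio, daytime_hours, displacement_d) enables the ANCOVA;
    ``realignment`` paths enable the movement summary.
    """

    concentrations: str | None = None
    covariates: str | None = None
    csf_fractions: str | None = None
    realignment: list = field(default_factory=list)
    crlb_threshold: float = 20.0
    crlb_rule: str = "mean_below"
    intra_method: str = "mean_of_subject_cvs"
    n_iter: int = 5000
    out_dir: str = "results"
    seed: int = 0
    apply_csf_correction: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def apply_csf_correction(table: StudyTable, fractions: pd.DataFrame) -> StudyTable:
    """Divide each concentration by (1 - F_CSF) of its (subject, session, region)."""
    req = {"subject", "session", "region", "f_csf"}
    missing = req - set(fractions.columns)
    if missing:
        raise ValueError(f"fractions table lacks column(s): {sorted(missing)}")
    frac = fractions[list(req)].copy()
    frac["subject"] = frac["subject"].astype(str)
    frac["session"] = frac["session"].astype(int)
    merged = table.frame.merge(frac, on=["subject", "session", "region"], how="left", validate="m:1")
    if merged["f_csf"].isna().any():
        bad = merged.loc[merged["f_csf"].isna(), ["subject", "session", "region"]].drop_duplicates()
        raise ValueError(f"missing CSF fraction for:\n{bad.to_string(index=False)}")
    frame = table.frame.copy()
    frame["concentration"] = csf_correct(
        merged["concentration"].to_numpy(), merged["f_csf"].to_numpy()
    )
    return StudyTable(frame)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every applicable stage and write results under ``config.out_dir``.

    Returns a dict with the variability report, inferential results, movement
    summary (when realignment inputs exist) and the provenance manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "mrsrepro",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "rng": "numpy default_rng (PCG64)",
        "stages": {},
    }

    # -- ingest -----------------------------------------------------------
    covariates = None
    try:
        if config.concentrations is None:
            from .synthetic import SyntheticConfig, generate_study

            study = generate_study(SyntheticConfig(seed=config.seed))
            table = study["table"]
            covariates = study["covariates"]
        else:
            table = read_concentration_table(config.concentrations)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("ingest", str(e)) from e
    manifest["stages"]["ingest"] = {"n_records": len(table)}
    log.info("ingest: %d records, %d subjects", len(table), len(table.subjects))

    if config.covariates is not None:
        covariates = pd.read_csv(config.covariates)

    # -- CSF correction ---------------------------------------------------
    fractions = None
    if config.csf_fractions is not None:
        fractions = pd.read_csv(config.csf_fractions)
    elif covariates is not None and "f_csf" in covariates.columns:
        fractions = covariates
    if config.apply_csf_correction and fractions is not None:
        try:
            table = apply_csf_correction(table, fractions)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("csf_correction", str(e)) from e
        manifest["stages"]["csf_correction"] = {"n_records": len(table)}
        log.info("csf_correction: applied to %d records", len(table))

    # -- quality filter ---------------------------------------------------
    policy = QualityPolicy(crlb_threshold_percent=config.crlb_threshold, rule=config.crlb_rule)
    filtered, exclusions = filter_by_crlb(table, policy)
    if filtered is None:
        raise PipelineError("quality_filter", "CRLB policy excluded every record")
    manifest["stages"]["quality_filter"] = {
        "n_records": len(filtered),
        "n_excluded_cells": len(exclusions),
    }
    log.info("quality_filter: %d records kept, %d cells excluded", len(filtered), len(exclusions))
    exclusions.to_frame().to_csv(out / "exclusions.csv", index=False)

    # -- movement ---------------------------------------------------------
    movement_summary = None
    if config.realignment:
        try:
            series = [read_realignment(p) for p in config.realignment]
            movement_summary = summarize_movement(series)
            movement_summary.to_frame().to_csv(out / "movement_summary.csv")
            manifest["stages"]["movement"] = {"n_sessions": movement_summary.n_sessions}
            log.info("movement: %d sessions summarized", movement_summary.n_sessions)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("movement", str(e)) from e

    # -- variability ------------------------------------------------------
    try:
        results = compute_cv_results(
            filtered,
            intra_method=config.intra_method,
            resampling=ResamplingConfig(n_iter=config.n_iter, seed=config.seed),
        )
        report = aggregate_report(results)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("variability", str(e)) from e
    manifest["stages"]["variability"] = {"n_cells": len(results)}
    log.info("variability: %d (region, metabolite) cells", len(results))
    render_report(report, out, format="csv")
    render_report(report, out, format="markdown")

    # -- inferential ------------------------------------------------------
    anova_rows = []
    if len(filtered.sessions) >= 2 and len(filtered.subjects) >= 2:
        for r in results:
            res = rm_anova_sessions(filtered, r.region, r.metabolite)
            anova_rows.append(
                {"region": res.region, "metabolite": res.metabolite, "term": "session",
                 "F": res.F, "df1": res.df_num, "df2": res.df_den, "p": res.p}
            )
        pd.DataFrame(anova_rows).to_csv(out / "rm_anova.csv", index=False)
    manifest["stages"]["rm_anova"] = {"n_tests": len(anova_rows)}

    ancova_results = []
    if covariates is not None and set(COVARIATES) <= set(covariates.columns):
        try:
            ancova_results = ancova_covariates(filtered, covariates)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("ancova", str(e)) from e
        rows = [
            {"metabolite": a.metabolite, "term": cname, **vals}
            for a in ancova_results
            for cname, vals in a.terms.items()
        ]
        pd.DataFrame(rows).to_csv(out / "ancova.csv", index=False)
    manifest["stages"]["ancova"] = {"n_models": len(ancova_results)}

    cell_crlb = filtered.frame.groupby(["region", "metabolite"])["crlb_percent"].mean()
    intra = pd.Series(
        {(r.region, r.metabolite): r.intra_cv_percent for r in results}
    )
    correlation = crlb_cv_correlation(cell_crlb, intra)
    manifest["stages"]["crlb_cv_correlation"] = {"r": correlation.r, "p": correlation.p,
                                                 "n": correlation.n}
    log.info("crlb_cv_correlation: r=%.3f p=%.2g over %d cells",
             correlation.r, correlation.p, correlation.n)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return {
        "table": filtered,
        "report": report,
        "rm_anova": anova_rows,
        "ancova": ancova_results,
        "correlation": correlation,
        "movement": movement_summary,
        "manifest": manifest,
    }


def render_report(report: VariabilityReport, out_dir: str | Path, format: str = "csv") -> Path:
    """Write the variability report as long-format CSV or a Markdown table.

    The Markdown layout mirrors the printed per-region summary: one row per
    (region, metabolite) with mean concentration, intra-subject SD/CV and
    inter-subject SD/CV, followed by the aggregate means.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not report.results:
        raise ValueError("empty report")
    if format == "csv":
        path = out_dir / "variability.csv"
        report.to_long_frame().to_csv(path, index=False, float_format="%.6g")
        return path
    if format != "markdown":
        raise ValueError(f"unknown format {format!r}")
    path = out_dir / "variability.md"
    lines = [
        "# Variability report",
        "",
        "| Region | Metabolite | Mean conc (AU) | Intra SD | Intra CV% | Inter SD | Inter CV% |",
        "|---|---|---|---|---|---|---|",
    ]
    for r in report.results:
        lines.append(
            f"| {r.region} | {r.metabolite} | {r.mean_concentration:.2f} | "
            f"{r.intra_sd:.2f} | {r.intra_cv_percent:.1f} | "
            f"{r.inter_sd:.2f} | {r.inter_cv_percent:.1f} |"
        )
    lines += ["", "## Region means (over metabolites)", "",
              "| Region | Intra CV% | Inter CV% |", "|---|---|---|"]
    for region, row in report.region_means.iterrows():
        lines.append(f"| {region} | {row['intra_cv_percent']:.2f} | {row['inter_cv_percent']:.2f} |")
    lines += ["", "## Metabolite means (over regions)", "",
              "| Metabolite | Intra CV% | Inter CV% |", "|---|---|---|"]
    for metab, row in report.metabolite_means.iterrows():
        lines.append(f"| {metab} | {row['intra_cv_percent']:.2f} | {row['inter_cv_percent']:.2f} |")
    lines += [
        "",
        f"Study-level mean intra CV: {report.study_intra_cv:.2f}%  ",
        f"Study-level mean inter CV: {report.study_inter_cv:.2f}%  ",
        f"Inter - intra gap: {report.intra_inter_gap:.2f}%",
        "",
    ]
    path.write_text("\n".join(lines))
    return path
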