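"""End-to-end analysis: simulate or load → preprocess → features → PCA-LDA →
statistics → report.

The pipeline is configured by :class:`PipelineConfig` (YAML-loadable,
schema-validated by pydantic before any computation) and is fully
deterministic given the configuration and seed: running it twice writes
byte-identical JSON reports.

Sources
-------
``published``
    Feature-level simulation from the published cohort summary.
``spectral``
    Spectral simulation (study-condition generator), full chain including
    band areas, LPR/LNR, per-band LD1 scores and LOOCV.
``files``
    Spectra (CSV/JCAMP-DX) or a precomputed feature table from disk.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import band_features, biomarker_stats, chemometrics, synthetic_data
from .preprocess import BandDefinition
from .spectra_io import SpectralDataset, read_spectra

__all__ = ["PipelineConfig", "AnalysisReport", "run_pipeline", "make_report_tables"]

log = logging.getLogger("evir.pipeline")

_DEFAULT_BANDS = {
    "carb_nucleic": (1000.0, 1200.0),
    "amide": (1470.0, 1700.0),
    "ester_co": (1720.0, 1760.0),
    "ch_stretch": (2800.0, 3000.0),
}


class PipelineConfig(BaseModel):
    """Validated configuration of one pipeline run."""

    source: Literal["published", "spectral", "files"] = "published"
    spectra_path: Optional[str] = None
    spectra_format: Literal["csv_wide", "csv_long", "jcampdx"] = "csv_wide"
    manifest_path: Optional[str] = None
    features_path: Optional[str] = None
    bands: dict[str, tuple[float, float]] = Field(default_factory=lambda: dict(_DEFAULT_BANDS))
    shape_bands: list[str] = Field(default_factory=lambda: ["amide", "ch_stretch", "ester_co"])
    n_components: int = 2
    ci_method: Literal["delong", "bootstrap"] = "delong"
    stepwise: bool = True
    orient_markers: bool = True
    run_loocv: bool = True
    seed: int = 0
    out_dir: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        for name, (lo, hi) in self.bands.items():
            if not lo < hi:
                raise ValueError(f"band {name!r}: lo must be < hi, got [{lo}, {hi}]")
        unknown = [b for b in self.shape_bands if b not in self.bands]
        if unknown:
            raise ValueError(
                f"shape_bands reference unknown band name(s) {unknown}; "
                f"defined bands: {sorted(self.bands)}"
            )
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.source == "files" and not (self.spectra_path or self.features_path):
            raise ValueError("source 'files' needs spectra_path or features_path")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def band_definitions(self) -> dict[str, BandDefinition]:
        return {name: BandDefinition(name, lo, hi) for name, (lo, hi) in self.bands.items()}


@dataclass
class AnalysisReport:
    """All numbers produced by one pipeline run, reproducible from config + seed."""

    config: dict
    group_summary: list[dict] = field(default_factory=list)
    auc_table: list[dict] = field(default_factory=list)
    loocv: dict[str, dict] = field(default_factory=dict)
    stepwise_model: dict = field(default_factory=dict)
    combined_operating_points: dict = field(default_factory=dict)
    roc_curves: dict[str, dict] = field(default_factory=dict)
    feature_table: pd.DataFrame | None = field(default=None, repr=False)

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "config": self.config,
            "group_summary": self.group_summary,
            "auc_table": self.auc_table,
            "loocv": self.loocv,
            "stepwise_model": self.stepwise_model,
            "combined_operating_points": self.combined_operating_points,
        }
        return json.dumps(payload, indent=indent, sort_keys=True)


def _marker_columns(table: pd.DataFrame) -> list[str]:
    return [
        c
        for c in table.columns
        if c not in ("subject_id", "group") and pd.api.types.is_numeric_dtype(table[c])
    ]


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def _build_features_from_spectra(
    dataset: SpectralDataset, config: PipelineConfig
) -> tuple[pd.DataFrame, dict[str, dict]]:
    bands = config.band_definitions()
    area_bands = list(bands.values())
    table = band_features.build_feature_table(dataset, area_bands)
    loocv_reports: dict[str, dict] = {}
    for name in config.shape_bands:
        window = bands[name]
        col = chemometrics.ld1_column(window)
        try:
            table[col] = chemometrics.pca_lda_scores(
                dataset, window, n_components=config.n_components
            )
        except ValueError as exc:
            raise RuntimeError(f"stage pca_lda ({name}): {exc}") from exc
        if config.run_loocv:
            report = chemometrics.loocv_classify(
                dataset, window, n_components=config.n_components
            )
            loocv_reports[col] = report.as_dict()
    return table, loocv_reports


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute every stage in order and return the collected report."""
    t0 = _stage("input")
    rng = np.random.default_rng(config.seed)
    loocv_reports: dict[str, dict] = {}
    if config.source == "published":
        table = synthetic_data.generate_feature_cohort(
            synthetic_data.FeatureCohortSpec(seed=config.seed)
        )
    elif config.source == "spectral":
        spec = synthetic_data.default_cohort_spec(seed=config.seed)
        dataset = synthetic_data.generate_cohort(spec)
        table, loocv_reports = _build_features_from_spectra(dataset, config)
    else:
        if config.features_path:
            table = pd.read_csv(config.features_path)
        else:
            dataset = read_spectra(
                config.spectra_path, config.spectra_format, manifest=config.manifest_path
            )
            table, loocv_reports = _build_features_from_spectra(dataset, config)
    log.info("input ready in %.2fs", time.perf_counter() - t0)

    groups = table["group"].to_numpy()
    labels = (groups == "case").astype(int)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise RuntimeError("stage evaluate: need both groups present")
    markers = _marker_columns(table)

    _stage("univariate")
    summary: list[dict] = []
    auc_rows: list[dict] = []
    roc_curves: dict[str, dict] = {}
    for m in markers:
        values = table[m].to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise RuntimeError(f"stage evaluate: non-finite values in marker {m!r}")
        ctrl, case = values[labels == 0], values[labels == 1]
        test = biomarker_stats.wilcoxon_rank_sum(ctrl, case)
        summary.append(
            {
                "marker": m,
                "mean_control": float(ctrl.mean()),
                "sd_control": float(ctrl.std(ddof=1)),
                "mean_case": float(case.mean()),
                "sd_case": float(case.std(ddof=1)),
                "p_value": test.p_value,
                "test_method": test.method,
            }
        )
        roc = biomarker_stats.roc_auc(
            values, labels, ci_method=config.ci_method,
            orient=config.orient_markers, rng=rng,
        )
        auc_rows.append(
            {
                "marker": m,
                "auc": roc.auc,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "direction": "case_low" if roc.flipped else "case_high",
            }
        )
        roc_curves[m] = {
            "thresholds": roc.thresholds.tolist(),
            "sensitivity": roc.sensitivity.tolist(),
            "specificity": roc.specificity.tolist(),
        }

    stepwise_info: dict = {}
    op_points: dict = {}
    if config.stepwise and len(markers) >= 2:
        _stage("stepwise")
        model = biomarker_stats.stepwise_select(table, labels, markers=markers)
        roc = biomarker_stats.combined_marker_roc(
            model, table, labels, ci_method=config.ci_method, rng=rng
        )
        youden = biomarker_stats.youden_threshold(roc)
        topleft = biomarker_stats.closest_topleft_threshold(roc)
        stepwise_info = {
            "selected_markers": model.markers,
            "intercept": model.intercept,
            "coefficients": model.coefficients,
            "p_values": model.p_values,
            "aic": model.aic,
            "converged": model.converged,
            "separated": model.separated,
            "trace": [list(t) for t in model.trace],
        }
        auc_rows.append(
            {
                "marker": "stepwise",
                "auc": roc.auc,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "direction": "case_high",
            }
        )
        roc_curves["stepwise"] = {
            "thresholds": roc.thresholds.tolist(),
            "sensitivity": roc.sensitivity.tolist(),
            "specificity": roc.specificity.tolist(),
        }
        op_points = {
            "youden": {
                "threshold": youden.threshold,
                "sensitivity": youden.sensitivity,
                "specificity": youden.specificity,
                "j": youden.youden_j,
            },
            "closest_topleft": {
                "threshold": topleft.threshold,
                "sensitivity": topleft.sensitivity,
                "specificity": topleft.specificity,
            },
        }

    report = AnalysisReport(
        config=json.loads(config.model_dump_json()),
        group_summary=summary,
        auc_table=auc_rows,
        loocv=loocv_reports,
        stepwise_model=stepwise_info,
        combined_operating_points=op_points,
        roc_curves=roc_curves,
        feature_table=table,
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json() + "\n")
        make_report_tables(report, out)
        log.info("report written to %s", out)
    return report


def make_report_tables(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Emit summary.csv (group summary), auc.csv and per-marker ROC CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary_path = out / "summary.csv"
    pd.DataFrame(report.group_summary).to_csv(summary_path, index=False)
    written.append(summary_path)
    auc_path = out / "auc.csv"
    pd.DataFrame(report.auc_table).to_csv(auc_path, index=False)
    written.append(auc_path)
    for marker, curve in report.roc_curves.items():
        safe = marker.replace("/", "_")
        path = out / f"roc_{safe}.csv"
        pd.DataFrame(curve).to_csv(path, index=False)
        written.append(path)
    if report.feature_table is not None:
        fpath = out / "features.csv"
        report.feature_table.to_csv(fpath, index=False)
        written.append(fpath)
    return written
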