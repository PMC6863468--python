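"""End-to-end orchestration: simulate (optional) -> fit curves -> mixed
models -> marginal trends -> acclimated surfaces -> homeostasis table.

Every stage is also runnable on its own from the intermediate CSVs (see
:mod:`rdacclim.cli`); this module wires them together under one
:class:`RunConfig` and collects the outputs into a :class:`RunReport` whose
tables mirror the analysis summaries: a Wald chi-square table per model
term and parameter, a per-tissue trend table, the homeostasis grid with
marginal averages, and (when V_cmax series are present) the ln-ratio trend
table.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ancova import assemble_parameter_table, fit_mixed_ancova
from .curves import fit_all_individuals
from .errors import RdAcclimError
from .io import SCHEMA_VERSION, read_measurements, write_measurements
from .surface import (
    HOMEO_TA_LEVELS,
    HomeostasisResult,
    ParameterTrendSet,
    build_surfaces,
    compute_ratio_records,
    homeostasis_table,
)
from .synthetic import (
    TrueParameterConfig,
    draw_true_parameters,
    make_design,
    simulate_measurements,
)

logger = logging.getLogger(__name__)


class PipelineStageError(RdAcclimError):
    """A pipeline stage failed; carries the stage name and any partial
    outputs produced before the failure."""

    def __init__(self, stage: str, original: Exception, partial: dict | None = None):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original
        self.partial = partial or {}


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    With ``input_csv`` unset a synthetic study is generated from
    ``design_preset`` and the noise/truth settings; otherwise measurements
    are read from the CSV and the truth settings are ignored.
    """

    design_preset: str = "table1"
    input_csv: str | None = None
    fitting_scale: str = "log_ols"
    df_method: str = "satterthwaite"
    t_ref: float = 25.0
    homeo_ta_levels: tuple[float, ...] = HOMEO_TA_LEVELS
    include_vcmax: bool = True
    noise_sd_log: float = 0.15
    species_offset_sd: float = 0.5
    individual_offset_sd: float = 0.2
    top_temp_jitter_sd: float = 0.5
    seed: int = 0
    outdir: str = "results"

    def __post_init__(self):
        if self.t_ref not in (*self.homeo_ta_levels, 25.0):
            # the reference must be an acclimation level of the study design
            raise ValueError("t_ref must be one of the acclimation temperatures")
        self.homeo_ta_levels = tuple(float(t) for t in self.homeo_ta_levels)
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["homeo_ta_levels"] = list(self.homeo_ta_levels)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunReport:
    """All tables produced by one run plus reproducibility metadata."""

    fits: pd.DataFrame
    fit_failures: pd.DataFrame
    table2: pd.DataFrame           # term-level Wald chi-square per parameter
    table3: pd.DataFrame           # per-tissue trend estimates per parameter
    homeostasis: HomeostasisResult
    table4: pd.DataFrame           # homeostasis grid with marginal averages
    contrasts: pd.DataFrame        # planned Ps vs non-Ps slope contrasts
    species_means: pd.DataFrame
    ratio_trends: pd.DataFrame | None
    metadata: dict


def _simulate_stage(config: RunConfig):
    design = make_design(config.design_preset, seed=config.seed)
    truth_cfg = TrueParameterConfig(
        noise_sd_log=config.noise_sd_log,
        species_offset_sd=config.species_offset_sd,
        individual_offset_sd=config.individual_offset_sd,
        top_temp_jitter_sd=config.top_temp_jitter_sd,
    )
    truth = draw_true_parameters(truth_cfg, seed=config.seed)
    study = simulate_measurements(design, truth)
    logger.info("simulated %d individuals, %d rd records, %d vcmax records",
                design.n_individuals, len(study.records), len(study.vcmax_records))
    return study


def run_pipeline(config: RunConfig,
                 records: pd.DataFrame | None = None,
                 vcmax_records: pd.DataFrame | None = None) -> RunReport:
    """Execute the full analysis; deterministic given (config, seed, input).

    ``records``/``vcmax_records`` may be passed directly (mass-basis
    measurement tables); otherwise ``config.input_csv`` is read, or a
    synthetic study is generated.
    """
    partial: dict = {}

    def stage(name):
        logger.info("stage: %s", name)
        return name

    truth = None
    try:
        name = stage("data")
        if records is None:
            if config.input_csv:
                all_records = read_measurements(config.input_csv)
                records = all_records[all_records["quantity"] == "rd"]
                vcmax_records = all_records[all_records["quantity"] == "vcmax"]
            else:
                study = _simulate_stage(config)
                records = study.records
                vcmax_records = study.vcmax_records
                truth = study.truth
        if vcmax_records is not None and len(vcmax_records) == 0:
            vcmax_records = None
        partial["records"] = records

        name = stage("fit-curves")
        fits, failures = fit_all_individuals(records, scale=config.fitting_scale)
        partial["fits"], partial["fit_failures"] = fits, failures

        name = stage("assemble-parameters")
        params = assemble_parameter_table(fits)
        partial["parameter_table"] = params

        name = stage("mixed-models")
        table2_rows, table3_rows, contrast_rows = [], [], []
        species_means = None
        for parameter in ("a", "b", "c"):
            model = fit_mixed_ancova(params, parameter, df_method=config.df_method)
            w = model.wald_table()
            w.insert(0, "parameter", parameter)
            table2_rows.append(w)
            table3_rows.append(model.lsm_trends())
            cr = model.planned_contrast()
            contrast_rows.append(dict(parameter=parameter, estimate=cr.estimate,
                                      se=cr.se, df=cr.df, t=cr.t, p=cr.p))
            if parameter == "a":
                species_means, _ = model.species_marginal_means()
        table2 = pd.concat(table2_rows, ignore_index=True)
        table3 = pd.concat(table3_rows, ignore_index=True)
        contrasts = pd.DataFrame(contrast_rows)
        partial["table2"], partial["table3"] = table2, table3

        name = stage("surfaces")
        trendset = ParameterTrendSet.from_trend_table(table3)
        surfaces = build_surfaces(trendset)
        homeo = homeostasis_table(surfaces, ta_levels=config.homeo_ta_levels,
                                  t_ref=config.t_ref)
        table4 = homeo.to_frame()
        partial["table4"] = table4

        ratio_trends = None
        if config.include_vcmax and vcmax_records is not None and len(vcmax_records):
            name = stage("vcmax-ratio")
            vfits, vfail = fit_all_individuals(vcmax_records,
                                               scale=config.fitting_scale)
            if len(vfail):
                failures = pd.concat([failures, vfail], ignore_index=True)
            ratio = compute_ratio_records(fits, vfits)
            rmodel = fit_mixed_ancova(ratio, "ln_ratio", df_method=config.df_method)
            ratio_trends = rmodel.lsm_trends()
            rcr = rmodel.planned_contrast()
            contrasts = pd.concat([contrasts, pd.DataFrame([dict(
                parameter="ln_ratio", estimate=rcr.estimate, se=rcr.se,
                df=rcr.df, t=rcr.t, p=rcr.p)])], ignore_index=True)
            rw = rmodel.wald_table()
            rw.insert(0, "parameter", "ln_ratio")
            table2 = pd.concat([table2, rw], ignore_index=True)

        name = stage("metadata")
        metadata = {
            "seed": config.seed,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "schema_version": SCHEMA_VERSION,
            "versions": {
                "rdacclim": _package_version(),
                "python": platform.python_version(),
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "n_records": int(len(records)),
            "n_fits": int(len(fits)),
            "n_fit_failures": int(len(failures)),
            "synthetic_truth": _truth_payload(truth) if truth is not None else None,
        }
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineStageError(name, exc, partial) from exc

    return RunReport(fits=fits, fit_failures=failures, table2=table2,
                     table3=table3, homeostasis=homeo, table4=table4,
                     contrasts=contrasts, species_means=species_means,
                     ratio_trends=ratio_trends, metadata=metadata)


def _package_version() -> str:
    from . import __version__

    return __version__


def _truth_payload(truth) -> dict:
    return {
        "trends": {t: {p: list(v) for p, v in tr.items()}
                   for t, tr in truth.trends.items()},
        "vcmax_trends": {p: list(v) for p, v in truth.vcmax_trends.items()},
        "species_offset_sd": truth.species_offset_sd,
        "individual_offset_sd": truth.individual_offset_sd,
        "noise_sd_log": truth.noise_sd_log,
        "temp_grid": list(truth.temp_grid),
        "top_temp_jitter_sd": truth.top_temp_jitter_sd,
    }


def write_report(report: RunReport, outdir) -> dict[str, Path]:
    """Write the report tables as CSVs plus a JSON metadata sidecar.

    Emitted headers are fixed (schema version recorded in the metadata);
    the homeostasis table is written in report layout — one row per
    acclimation temperature plus an Average row, one column per tissue
    class plus an Average column.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def emit(name: str, frame: pd.DataFrame, **kw):
        path = outdir / f"{name}.csv"
        frame.to_csv(path, **kw)
        paths[name] = path

    emit("fits", report.fits, index=False)
    emit("fit_failures", report.fit_failures, index=False)
    emit("table2", report.table2, index=False)
    emit("table3", report.table3, index=False)
    emit("table4", report.table4, index=True, index_label="T_a")
    emit("contrasts", report.contrasts, index=False)
    if report.species_means is not None:
        emit("species_means", report.species_means, index=False)
    if report.ratio_trends is not None:
        emit("ratio_trends", report.ratio_trends, index=False)

    meta_path = outdir / "metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(report.metadata, fh, indent=2, sort_keys=True)
    paths["metadata"] = meta_path
    logger.info("report written to %s (%d files)", outdir, len(paths))
    return paths
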