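"""Configured end-to-end pipeline and its YAML-backed configuration.

Runs, per input series: preprocessing (NDVI + anomaly), trend and
change-point tests, corrected R/S Hurst, structure-function and MF-DFA
spectra, and the shuffle/surrogate source decomposition, writing one
delimited summary per analysis family plus machine-readable spectra and a
JSON run manifest (config, seeds, version). Summary layouts mirror the
usual reporting tables of this kind of study: trend direction/tau/p;
HI vs H(2) by method; DeltaH by method; DeltaH of original, surrogate and
shuffle ensembles with Hcor/Hpdf.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .gsf import DEFAULT_LAGS, fit_scaling, structure_function
from .mfdfa import MfdfaConfig, fit_hq, fluctuation_function
from .preprocessing import preprocess, read_reflectance
from .rs_hurst import hurst_rs
from .series import EvenSeries, read_series, write_series
from .sources import decompose_sources
from .spectrum import DEFAULT_Q_GRID
from .synthetic import SimSpec, generate
from .trend import mann_kendall, pettitt

__all__ = ["PipelineConfig", "ConfigError", "parse_config", "run_pipeline"]

log = logging.getLogger("ndviscaling")

STAGES = ("preprocess", "trend", "hurst", "gsf", "mfdfa", "sources")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All pipeline knobs, with the study defaults baked in."""

    input_path: str | None = None
    input_kind: str = "value"          # "value" | "reflectance"
    simulate: dict = field(default_factory=dict)  # SimSpec overrides (used when no input_path)
    output_dir: str = "pipeline_out"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    gap_window: int = 7
    sg_window: int = 9
    sg_poly_order: int = 3
    q_grid: list = field(default_factory=lambda: DEFAULT_Q_GRID.tolist())
    gsf_lags: list = field(default_factory=lambda: DEFAULT_LAGS.tolist())
    mfdfa_scales: list = field(default_factory=lambda: [4, 8, 16, 32, 64])
    mfdfa_fit_scales: list | None = None
    detrend_order: int = 1
    n_realizations: int = 10

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s) {sorted(unknown)}; valid stages: {STAGES}")
        stages = {s: True for s in STAGES}
        stages.update(self.stages)
        self.stages = stages
        if self.input_kind not in ("value", "reflectance"):
            raise ConfigError(f"input_kind must be 'value' or 'reflectance', got {self.input_kind!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def mfdfa_config(self) -> MfdfaConfig:
        return MfdfaConfig(
            q_grid=np.asarray(self.q_grid, dtype=float),
            scales=np.asarray(self.mfdfa_scales, dtype=int),
            fit_scales=None if self.mfdfa_fit_scales is None else np.asarray(self.mfdfa_fit_scales, int),
            detrend_order=self.detrend_order,
        )


def parse_config(path) -> PipelineConfig:
    """Parse a YAML config; unknown keys are rejected by name."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: malformed YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**raw)


def _load_input(config: PipelineConfig) -> EvenSeries:
    if config.input_path:
        if config.input_kind == "reflectance":
            pair, year = read_reflectance(config.input_path)
            from .preprocessing import compute_ndvi

            return compute_ndvi(pair, start_year=year)
        return read_series(config.input_path)
    spec = SimSpec(**{"seed": config.seed, **config.simulate})
    return generate(spec)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the run report (also written
    as ``manifest.json``). Any stage failure is recorded under
    ``errors`` and downstream dependent stages are skipped."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": config.to_dict(),
                    "stages_run": [], "errors": [], "timings_s": {}, "outputs": {}}

    def fail(stage: str, exc: Exception) -> None:
        log.error("stage %s failed: %s", stage, exc)
        report["errors"].append({"stage": stage, "error": str(exc)})

    series = _load_input(config)
    write_series(series, out / "input_series.csv")

    labelled: dict[str, EvenSeries] = {}
    t0 = time.perf_counter()
    if config.stages["preprocess"]:
        try:
            ndvi, ndvia = preprocess(series, gap_window=config.gap_window,
                                     sg_window=config.sg_window,
                                     sg_poly_order=config.sg_poly_order)
            write_series(ndvi, out / "ndvi.csv")
            write_series(ndvia, out / "ndvia.csv")
            labelled = {"NDVI": ndvi, "NDVIa": ndvia}
            report["stages_run"].append("preprocess")
        except Exception as exc:
            fail("preprocess", exc)
            labelled = {}
    else:
        labelled = {"series": series}
    report["timings_s"]["preprocess"] = round(time.perf_counter() - t0, 3)

    mf_cfg = config.mfdfa_config()
    trend_rows, hurst_rows, dh_rows, src_rows = [], [], [], []
    spectra_frames = []

    for label, s in labelled.items():
        if config.stages["trend"]:
            t0 = time.perf_counter()
            try:
                mk = mann_kendall(s)
                pt = pettitt(s)
                trend_rows.append({
                    "series": label, **mk.summary_row(),
                    "change_index": pt.change_index,
                    "change_date": str(s.timestamps[pt.change_index - 1]),
                    "pettitt_p": pt.p_value,
                })
            except Exception as exc:
                fail(f"trend[{label}]", exc)
            report["timings_s"][f"trend[{label}]"] = round(time.perf_counter() - t0, 3)

        hi = g_h2 = m_h2 = g_dh = m_dh = None
        if config.stages["hurst"]:
            t0 = time.perf_counter()
            try:
                res = hurst_rs(s)
                hi = res.hurst
            except Exception as exc:
                fail(f"hurst[{label}]", exc)
            report["timings_s"][f"hurst[{label}]"] = round(time.perf_counter() - t0, 3)

        if config.stages["gsf"]:
            t0 = time.perf_counter()
            try:
                table = structure_function(s, q_grid=np.asarray(config.q_grid),
                                           lags=np.asarray(config.gsf_lags, int))
                spec = fit_scaling(table)
                g_h2, g_dh = spec.h_at(2.0), spec.delta_h
                df = spec.to_frame()
                df.insert(0, "series", label)
                df.insert(1, "method", "gsf")
                spectra_frames.append(df)
            except Exception as exc:
                fail(f"gsf[{label}]", exc)
            report["timings_s"][f"gsf[{label}]"] = round(time.perf_counter() - t0, 3)

        mfdfa_ok = False
        if config.stages["mfdfa"]:
            t0 = time.perf_counter()
            try:
                table = fluctuation_function(s, q_grid=mf_cfg.q_grid, scales=mf_cfg.scales,
                                             detrend_order=mf_cfg.detrend_order)
                spec = fit_hq(table, fit_scales=mf_cfg.fit_scales)
                m_h2, m_dh = spec.h_at(2.0), spec.delta_h
                mfdfa_ok = True
                df = spec.to_frame()
                df.insert(0, "series", label)
                df.insert(1, "method", "mfdfa")
                spectra_frames.append(df)
            except Exception as exc:
                fail(f"mfdfa[{label}]", exc)
            report["timings_s"][f"mfdfa[{label}]"] = round(time.perf_counter() - t0, 3)

        hurst_rows.append({"series": label, "HI": hi, "GSF_H2": g_h2, "MFDFA_H2": m_h2})
        dh_rows.append({"series": label, "GSF_delta_h": g_dh, "MFDFA_delta_h": m_dh})

        if config.stages["sources"]:
            if not config.stages["mfdfa"] or not mfdfa_ok:
                fail(f"sources[{label}]",
                     RuntimeError("sources stage depends on a successful mfdfa stage"))
            else:
                t0 = time.perf_counter()
                try:
                    dec = decompose_sources(s, config=mf_cfg,
                                            n_realizations=config.n_realizations,
                                            seed=config.seed)
                    src_rows.append({"series": label, **dec.summary_row()})
                except Exception as exc:
                    fail(f"sources[{label}]", exc)
                report["timings_s"][f"sources[{label}]"] = round(time.perf_counter() - t0, 3)

    def emit(rows_or_df, name: str, stage: str) -> None:
        df = pd.DataFrame(rows_or_df) if isinstance(rows_or_df, list) else rows_or_df
        if len(df):
            path = out / name
            df.to_csv(path, index=False, float_format="%.6g")
            report["outputs"][stage] = str(path)
            if stage not in report["stages_run"]:
                report["stages_run"].append(stage)

    emit(trend_rows, "trend_summary.csv", "trend")
    emit(hurst_rows, "hurst_summary.csv", "hurst")
    emit(dh_rows, "delta_h_summary.csv", "delta_h")
    emit(src_rows, "sources_summary.csv", "sources")
    if spectra_frames:
        emit(pd.concat([d.reset_index() for d in spectra_frames]), "spectra.csv", "spectra")

    (out / "manifest.json").write_text(json.dumps(report, indent=2, default=str))
    return report
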