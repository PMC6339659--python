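"""Batch orchestration: sample sheet or measurement CSV -> fits, limits, report.

:func:`run_pipeline` is the programmatic core behind the ``lfaquant
analyze`` command.  Per-strip failures are logged and excluded — a bad
photo never aborts the batch; the run fails only if no strip succeeds.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .calibration import (
    CalibrationResult,
    DetectionLimits,
    fit_calibration,
    limits_to_frame,
)
from .densitometry import (
    QuantifySettings,
    StripMeasurement,
    frame_to_measurements,
    measurements_to_frame,
    quantify_strip,
)
from .errors import DesignError, LfaError, Method2UnavailableError
from .io import LaneGeometry, load_strip_image
from .report import AnalysisReport, render_report

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("lfaquant")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class RunConfig:
    """Flat run configuration; every field has a working default.

    An empty config plus a sample sheet (columns ``image_path``,
    ``concentration_nM``, ``replicate``, ``device``) is runnable.
    ``mode``/``limits_method`` accept ``'both'``.
    """

    mode: str = "normalized"  # normalized | standardized | both
    channel: str = "green"
    baseline: str = "flank_linear"
    baseline_window_mm: float = 3.0
    line_spacing_mm: float = 5.0
    band_width_mm: float = 1.0
    roi_width_fraction: float = 0.6
    orientation_hint: str = "auto"
    limits_method: str = "both"  # 1 | 2 | both
    sample_sheet: str | None = None
    measurements_csv: str | None = None
    out_dir: str = "lfaquant_out"
    seed: int = 0
    report_format: str = "html"

    def geometry(self) -> LaneGeometry:
        return LaneGeometry(
            line_spacing_mm=self.line_spacing_mm,
            band_width_mm=self.band_width_mm,
            roi_width_fraction=self.roi_width_fraction,
        )

    def quantify_settings(self) -> QuantifySettings:
        return QuantifySettings(
            channel=self.channel,
            baseline_method=self.baseline,
            baseline_window_mm=self.baseline_window_mm,
            orientation_hint=self.orientation_hint,
        )

    def modes(self) -> list[str]:
        return ["normalized", "standardized"] if self.mode == "both" else [self.mode]

    def limits_methods(self) -> list[int]:
        return [1, 2] if str(self.limits_method) == "both" else [int(self.limits_method)]


@dataclass
class PipelineResult:
    """Everything a pipeline run produced, plus where it was written."""

    report: AnalysisReport
    measurements: list[StripMeasurement]
    fits: dict[str, CalibrationResult]
    limits: list[DetectionLimits]
    paths: dict[str, Path] = field(default_factory=dict)


def _measure_sample_sheet(
    cfg: RunConfig,
) -> tuple[list[StripMeasurement], list[str]]:
    """Quantify every strip in the sample sheet; collect per-strip failures."""
    sheet_path = Path(cfg.sample_sheet)
    sheet = pd.read_csv(sheet_path)
    required = {"image_path", "concentration_nM"}
    if missing := required - set(sheet.columns):
        raise LfaError(f"sample sheet missing column(s): {sorted(missing)}")
    if (pd.to_numeric(sheet["concentration_nM"], errors="coerce") < 0).any() or (
        pd.to_numeric(sheet["concentration_nM"], errors="coerce").isna().any()
    ):
        raise LfaError("sample sheet concentrations must be nonnegative reals")

    geom = cfg.geometry()
    settings = cfg.quantify_settings()
    measurements, rejects = [], []
    for idx, row in sheet.iterrows():
        img_path = Path(str(row["image_path"]))
        if not img_path.is_absolute():
            img_path = sheet_path.parent / img_path
        try:
            img = load_strip_image(img_path, source_label=str(row.get("device", "")))
            m = quantify_strip(img, geom, settings)
            m.concentration_nM = float(row["concentration_nM"])
            m.replicate = int(row.get("replicate", 0) or 0)
            m.device = str(row.get("device", "") or "")
            m.sample_id = img_path.stem
            measurements.append(m)
            log.info("strip ok  %s  tl=%.4g cl=%.4g flags=%s",
                     img_path.name, m.tl_intensity, m.cl_intensity, m.flags)
        except (LfaError, OSError) as exc:
            rejects.append(f"{img_path.name}: {exc}")
            log.warning("strip FAILED  %s: %s", img_path.name, exc)
    return measurements, rejects


def run_pipeline(cfg: RunConfig, write: bool = True) -> PipelineResult:
    """Run quantification, calibration, limits and report rendering.

    Reads either a directory of images via ``cfg.sample_sheet`` or a
    pre-extracted measurement CSV (e.g. ImageJ output) via
    ``cfg.measurements_csv``.  Raises only if no strip at all succeeds;
    individual failures end up in the report's rejects section.
    """
    inputs, rejects = [], []
    if cfg.measurements_csv:
        df = pd.read_csv(cfg.measurements_csv)
        measurements = frame_to_measurements(df)
        inputs.append(f"measurement CSV: {cfg.measurements_csv} ({len(measurements)} rows)")
    elif cfg.sample_sheet:
        measurements, rejects = _measure_sample_sheet(cfg)
        inputs.append(f"sample sheet: {cfg.sample_sheet}")
        if not measurements:
            raise LfaError(
                "no strip could be quantified; causes: " + "; ".join(rejects)
            )
    else:
        raise LfaError("either sample_sheet or measurements_csv is required")

    notes: list[str] = []
    fits: dict[str, CalibrationResult] = {}
    for mode in cfg.modes():
        try:
            fits[mode] = fit_calibration(measurements, mode=mode)
        except DesignError as exc:
            notes.append(f"{mode} fit unavailable: {exc}")

    limits: list[DetectionLimits] = []
    primary = next(iter(fits.values()), None)
    if primary is not None:
        for method in cfg.limits_methods():
            try:
                limits.append(primary.detection_limits(method))
            except LfaError as exc:
                kind = "method 2 unavailable" if isinstance(
                    exc, Method2UnavailableError
                ) else f"method {method} unavailable"
                notes.append(f"limits {kind}: {exc}")

    mtable = measurements_to_frame(measurements)
    settings_echo = asdict(cfg)
    report = AnalysisReport(
        inputs=inputs,
        settings=settings_echo,
        measurements=mtable,
        fits=fits,
        limits=limits,
        notes=notes,
        rejects=rejects,
    )

    paths: dict[str, Path] = {}
    if write:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mtable.to_csv(out / "measurements.csv", index=False)
        paths["measurements"] = out / "measurements.csv"
        if fits:
            pd.concat([f.to_frame() for f in fits.values()]).to_csv(
                out / "fit.csv", index=False
            )
            paths["fit"] = out / "fit.csv"
        if limits:
            limits_to_frame(limits).to_csv(out / "limits.csv", index=False)
            paths["limits"] = out / "limits.csv"
        paths["report"] = render_report(report, out, cfg.report_format)
        log.info("report written to %s", paths["report"])
    return PipelineResult(
        report=report, measurements=measurements, fits=fits, limits=limits, paths=paths
    )
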