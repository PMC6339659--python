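"""Self-contained analysis reports (HTML or Markdown).

The report mirrors what a lab notebook entry needs to replay the run: an
input inventory, the full settings echo, the per-strip measurement table,
the calibration fit(s), the LOB/LOD/LOQ tables and an inline calibration
plot.  Reports are never overwritten: the filename carries a run
identifier, so earlier reports are preserved.  Two runs on identical
inputs and configuration produce byte-identical files apart from the
single timestamp line.
"""

from __future__ import annotations

import base64
import datetime as _dt
import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .calibration import CalibrationResult, DetectionLimits, limits_to_frame

__all__ = ["AnalysisReport", "render_report"]


@dataclass
class AnalysisReport:
    """Everything the rendered report contains, in structured form."""

    inputs: list[str]
    settings: dict
    measurements: pd.DataFrame
    fits: dict[str, CalibrationResult]  # keyed by mode
    limits: list[DetectionLimits]
    notes: list[str] = field(default_factory=list)
    rejects: list[str] = field(default_factory=list)
    version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = _dt.datetime.now(_dt.timezone.utc).isoformat(
                timespec="seconds"
            )
        if not self.version:
            from . import __version__

            self.version = __version__


def _plot_data_uri(report: AnalysisReport) -> str | None:
    """Calibration plot of the first fit as a base64 PNG data URI."""
    if not report.fits:
        return None
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = next(iter(report.fits.values()))
    fig, ax = plt.subplots(figsize=(5.5, 3.5), dpi=110)
    fit.plot(ax=ax)
    fig.tight_layout()
    buf = _io.BytesIO()
    fig.savefig(buf, format="png")
    plt.close(fig)
    return "data:image/png;base64," + base64.b64encode(buf.getvalue()).decode("ascii")


def _settings_block(settings: dict) -> str:
    import yaml

    return yaml.safe_dump(settings, default_flow_style=False, sort_keys=True)


def _markdown_body(report: AnalysisReport) -> str:
    parts = [
        "# LFA analysis report",
        "",
        f"Generated: {report.timestamp}",
        "",
        f"lfaquant version: {report.version}",
        "",
        "## Inputs",
        "",
        *(f"- {line}" for line in report.inputs),
        "",
        "## Settings",
        "",
        "```yaml",
        _settings_block(report.settings).rstrip(),
        "```",
        "",
        "## Per-strip measurements",
        "",
        "```",
        report.measurements.to_string(index=False),
        "```",
        "",
    ]
    for mode, fit in report.fits.items():
        parts += [
            f"## Calibration fit ({mode})",
            "",
            "```",
            fit.summary(),
            "```",
            "",
        ]
    if report.limits:
        parts += [
            "## Detection limits",
            "",
            "```",
            limits_to_frame(report.limits).to_string(index=False),
            "```",
            "",
        ]
    if report.notes:
        parts += ["## Notes", "", *(f"- {n}" for n in report.notes), ""]
    if report.rejects:
        parts += ["## Rejected inputs", "", *(f"- {r}" for r in report.rejects), ""]
    uri = _plot_data_uri(report)
    if uri:
        parts += ["## Calibration plot", "", f"![calibration plot]({uri})", ""]
    return "\n".join(parts)


def _html_body(report: AnalysisReport) -> str:
    import html as _html

    def pre(text: str) -> str:
        return f"<pre>{_html.escape(text)}</pre>"

    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset='utf-8'><title>LFA analysis report</title>",
        "<style>body{font-family:sans-serif;max-width:60em;margin:2em auto;}"
        "pre{background:#f6f6f6;padding:0.8em;overflow-x:auto;}</style></head><body>",
        "<h1>LFA analysis report</h1>",
        f"<p class='timestamp'>Generated: {report.timestamp}</p>",
        f"<p>lfaquant version: {_html.escape(report.version)}</p>",
        "<h2>Inputs</h2><ul>"
        + "".join(f"<li>{_html.escape(line)}</li>" for line in report.inputs)
        + "</ul>",
        "<h2>Settings</h2>",
        pre(_settings_block(report.settings)),
        "<h2>Per-strip measurements</h2>",
        pre(report.measurements.to_string(index=False)),
    ]
    for mode, fit in report.fits.items():
        parts += [f"<h2>Calibration fit ({_html.escape(mode)})</h2>", pre(fit.summary())]
    if report.limits:
        parts += [
            "<h2>Detection limits</h2>",
            pre(limits_to_frame(report.limits).to_string(index=False)),
        ]
    if report.notes:
        parts += [
            "<h2>Notes</h2><ul>"
            + "".join(f"<li>{_html.escape(n)}</li>" for n in report.notes)
            + "</ul>"
        ]
    if report.rejects:
        parts += [
            "<h2>Rejected inputs</h2><ul>"
            + "".join(f"<li>{_html.escape(r)}</li>" for r in report.rejects)
            + "</ul>"
        ]
    uri = _plot_data_uri(report)
    if uri:
        parts += ["<h2>Calibration plot</h2>", f"<img src='{uri}' alt='calibration plot'>"]
    parts.append("</body></html>")
    return "\n".join(parts)


def render_report(
    report: AnalysisReport, out_dir: str | Path, fmt: str = "html"
) -> Path:
    """Write a single self-contained report file; never overwrite.

    The filename carries a run identifier (the report timestamp, plus a
    counter if that file already exists), so previous reports survive.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if fmt not in ("html", "markdown"):
        raise ValueError(f"format must be 'html' or 'markdown', got {fmt!r}")
    ext = "html" if fmt == "html" else "md"
    run_id = report.timestamp.replace(":", "").replace("+0000", "Z")
    path = out_dir / f"report_{run_id}.{ext}"
    n = 1
    while path.exists():
        path = out_dir / f"report_{run_id}_{n}.{ext}"
        n += 1
    body = _html_body(report) if fmt == "html" else _markdown_body(report)
    path.write_text(body, encoding="utf-8")
    return path
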