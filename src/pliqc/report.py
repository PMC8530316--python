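"""QC report assembly and JSON/HTML emission.

The JSON report carries an ``id``/``section`` pair and a flat ``metrics``
block so generic aggregators (e.g. MultiQC custom content) can ingest it
without a plugin.  The HTML report is a single self-contained file
rendered with a stdlib string template; console, JSON and HTML all show
the same numbers.
"""

from __future__ import annotations

import json
import string
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

__all__ = ["assemble_report", "write_reports", "validate_report", "flatten_metrics"]

TOOL_ID = "pliqc"
VERSION = "0.1.0"

_HTML_TEMPLATE = string.Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>$title</title>
<style>
body { font-family: sans-serif; margin: 2em; color: #222; }
table { border-collapse: collapse; margin: 1em 0; }
td, th { border: 1px solid #bbb; padding: 4px 10px; text-align: left; }
th { background: #eef; }
h1 { font-size: 1.4em; }
.meta { color: #666; font-size: 0.9em; }
</style></head><body>
<h1>$title</h1>
<p class="meta">mode: $mode &middot; version: $version &middot; generated: $timestamp</p>
<h2>Parameters</h2>
<table>$param_rows</table>
<h2>Metrics</h2>
<table><tr><th>metric</th><th>value</th></tr>$metric_rows</table>
</body></html>
"""
)


def flatten_metrics(results: dict, prefix: str = "") -> dict[str, float | int | str]:
    """Flatten nested numeric results into dotted keys for aggregators."""
    flat: dict[str, float | int | str] = {}
    for key, val in results.items():
        name = f"{prefix}{key}"
        if isinstance(val, dict):
            flat.update(flatten_metrics(val, prefix=f"{name}."))
        elif isinstance(val, (int, float, str, bool)):
            flat[name] = val
    return flat


def assemble_report(mode: str, parameters: dict, results: dict) -> dict:
    """Build the full QC report object."""
    skip = {"histogram", "flags", "junctions", "rejections", "class_counts"}
    metrics = flatten_metrics({k: v for k, v in results.items() if k not in skip})
    return {
        "id": TOOL_ID,
        "section": f"{TOOL_ID}_{mode}",
        "mode": mode,
        "version": VERSION,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "parameters": parameters,
        "results": results,
        "metrics": metrics,
    }


_REQUIRED = {
    "id": str,
    "section": str,
    "mode": str,
    "version": str,
    "parameters": dict,
    "results": dict,
    "metrics": dict,
}


def validate_report(report: dict) -> None:
    """Check the report against the shipped schema (required keys/types,
    fractions in [0, 1])."""
    schema = json.loads(
        resources.files("pliqc").joinpath("report_schema.json").read_text()
    )
    for key, typename in schema["required"].items():
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
        if type(report[key]).__name__ != typename:
            raise ValueError(
                f"report key {key!r} has type {type(report[key]).__name__}, "
                f"expected {typename}"
            )
    for name, value in report["metrics"].items():
        if any(name.endswith(s) for s in schema["fraction_suffixes"]):
            if not isinstance(value, (int, float)) or not 0.0 <= value <= 1.0:
                raise ValueError(f"metric {name!r} = {value!r} outside [0, 1]")


def write_reports(
    report: dict,
    outdir: str | Path,
    json_out: bool = True,
    html_out: bool = True,
    basename: str = "report",
) -> dict[str, Path]:
    """Emit report.json and/or report.html; returns written paths."""
    validate_report(report)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if json_out:
        p = outdir / f"{basename}.json"
        p.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        paths["json"] = p
    if html_out:
        param_rows = "".join(
            f"<tr><th>{k}</th><td>{v}</td></tr>" for k, v in report["parameters"].items()
        )
        metric_rows = "".join(
            f"<tr><td>{k}</td><td>{v}</td></tr>" for k, v in report["metrics"].items()
        )
        html = _HTML_TEMPLATE.substitute(
            title=f"{TOOL_ID} {report['mode']} QC report",
            mode=report["mode"],
            version=report["version"],
            timestamp=report["timestamp"],
            param_rows=param_rows,
            metric_rows=metric_rows,
        )
        p = outdir / f"{basename}.html"
        p.write_text(html)
        paths["html"] = p
    return paths


def console_summary(report: dict) -> str:
    lines = [f"[{TOOL_ID} {report['mode']} mode]"]
    for key, val in report["metrics"].items():
        if isinstance(val, float):
            lines.append(f"  {key:<32s} {val:.6g}")
        else:
            lines.append(f"  {key:<32s} {val}")
    return "\n".join(lines)
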