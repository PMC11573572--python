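"""Deterministic CSV/JSON report emission."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .stats import EnsembleSummary

FLOAT_FORMAT = "%.10g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, float_format=FLOAT_FORMAT, lineterminator="\n")


def write_report(
    summary: EnsembleSummary,
    correlations: pd.DataFrame,
    out_dir,
    config: dict | None = None,
) -> list[Path]:
    """Write summary tables and a manifest; byte-identical under fixed inputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    for name, df in (
        ("cluster_probability", summary.cluster_probability),
        ("bridging_probability", summary.bridging_probability),
        ("mode_percentages", summary.mode_pct),
    ):
        path = out / f"{name}.csv"
        _write_csv(df.sort_index(), path)
        written.append(path)

    adsorbed = pd.DataFrame(
        {
            "quantity": ["adsorbed_pct", "desorbed_pct"],
            "mean": [summary.adsorbed_pct, summary.desorbed_pct],
            "sd": [summary.adsorbed_sd, summary.adsorbed_sd],
        }
    ).set_index("quantity")
    path = out / "adsorbed.csv"
    _write_csv(adsorbed, path)
    written.append(path)

    if summary.coverage is not None:
        path = out / "coverage.csv"
        _write_csv(summary.coverage, path)
        written.append(path)

    path = out / "correlations.csv"
    _write_csv(
        correlations.sort_values(["response", "descriptor"]).reset_index(drop=True), path
    )
    written.append(path)

    from . import __version__

    manifest = {
        "package": "maomtools",
        "version": __version__,
        "n_replicas": summary.n_replicas,
        "config": config or {},
        "files": sorted(p.name for p in written),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    written.append(path)
    return written
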