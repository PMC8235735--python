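"""End-to-end pipeline orchestration: library → match → quantify → stats.

A single config (YAML-serialisable) drives the whole workflow and every
output directory carries provenance metadata (config, thresholds
actually applied, package version, seed), so a rerun with identical
inputs reproduces identical statistics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .library import build_library, write_library_tsv
from .matching import (
    assemble_matrix,
    filter_snr,
    match_features,
    read_features_csv,
    read_manifest,
)
from .stats import (
    DEFAULT_FREQ_THRESHOLD,
    DEFAULT_P_THRESHOLD,
    DEFAULT_PREFILTER_FREQ,
    class_summaries,
    compute_marker_stats,
    fit_combined_panel,
    frequency_filter,
    select_markers,
    site_map_report,
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and a hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        text = f"[{stage}] {message}"
        if hint:
            text += f" — {hint}"
        super().__init__(text)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; defaults are the platform's
    standard operating point (10 ppm, S/N 5.0, 70%/90% frequency,
    p < 1e-5, fully tryptic)."""

    fasta: str = ""
    glycans: str = ""
    features: str = ""
    manifest: str = ""
    out_dir: str = "glycomud_run"
    ppm_tolerance: float = 10.0
    snr_threshold: float = 5.0
    prefilter_frequency: float = DEFAULT_PREFILTER_FREQ
    marker_frequency: float = DEFAULT_FREQ_THRESHOLD
    p_threshold: float = DEFAULT_P_THRESHOLD
    max_missed_cleavages: int = 0
    positive_group: str = "cancer"
    frequency_scope: str = "pooled"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.ppm_tolerance <= 0:
            raise ValueError("ppm_tolerance must be > 0")
        if self.snr_threshold < 0:
            raise ValueError("snr_threshold must be >= 0")
        for name in ("prefilter_frequency", "marker_frequency"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 < self.p_threshold <= 1:
            raise ValueError("p_threshold must lie in (0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest_hex(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute build-library → match → quantify → stats → panels → reports.

    Returns the run directory.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for name, p in (("fasta", config.fasta), ("glycans", config.glycans),
                    ("features", config.features), ("manifest", config.manifest)):
        if not p or not Path(p).exists():
            raise PipelineError(
                "inputs", f"missing {name} file: {p!r}",
                "check the paths in the pipeline config",
            )

    try:
        library = build_library(
            config.fasta, config.glycans, config.max_missed_cleavages
        )
        write_library_tsv(library, out / "library.tsv")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("build-library", str(exc),
                            "check the FASTA and glycan CSV") from exc

    try:
        features = read_features_csv(config.features)
        features = filter_snr(features, config.snr_threshold)
        matched = match_features(features, library, config.ppm_tolerance)
        matched.to_csv(out / "matches.csv", index=False)
    except Exception as exc:
        raise PipelineError("match", str(exc),
                            "check the feature CSV dialect") from exc

    try:
        manifest = read_manifest(config.manifest)
        matrix = assemble_matrix(matched, manifest, library)
        matrix.write_csv(out / "matrix.csv", out / "manifest.csv")
    except Exception as exc:
        raise PipelineError("quantify", str(exc),
                            "check that every sample appears in the manifest") from exc

    try:
        filtered = frequency_filter(matrix, config.prefilter_frequency)
        stats_df = compute_marker_stats(
            filtered,
            positive_group=config.positive_group,
            p_threshold=config.p_threshold,
            freq_threshold=config.marker_frequency,
            frequency_scope=config.frequency_scope,
        )
        stats_df.to_csv(out / "marker_stats.tsv", sep="\t", index=False)
        markers = select_markers(
            stats_df, config.p_threshold, config.marker_frequency
        )
    except Exception as exc:
        raise PipelineError("stats", str(exc),
                            "need two cohorts with >= 2 samples each") from exc

    try:
        panels = {}
        for group in sorted({matrix.entry_group(k) for k in markers}):
            keys = [k for k in markers if matrix.entry_group(k) == group]
            panels[group] = fit_combined_panel(
                filtered, keys, positive_group=config.positive_group,
                group_label=group,
            ).to_dict()
        with (out / "panels.json").open("w") as fh:
            json.dump(panels, fh, indent=1)
    except Exception as exc:
        raise PipelineError("panel", str(exc)) from exc

    try:
        summary, rel = class_summaries(
            matrix, positive_group=config.positive_group
        )
        summary.to_csv(out / "class_summary.tsv", sep="\t", index=False)
        rel.to_csv(out / "class_relative_abundance.csv")
        site_map_report(matrix).to_csv(out / "site_map.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError("reports", str(exc)) from exc

    report = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.digest_hex(),
        "n_library_entries": len(library),
        "n_features_after_snr": int(len(features)),
        "n_matched_unambiguous": int(
            (matched["entry_key"].notna() & ~matched["ambiguous"]).sum()
        ),
        "n_samples": len(matrix.sample_ids),
        "n_entries_quantified": len(matrix.entry_keys),
        "n_entries_after_frequency_filter": len(filtered.entry_keys),
        "n_selected_markers": len(markers),
        "selected_markers": markers,
        "panel_auc": {g: p["combined_auc"] for g, p in panels.items()},
        "thresholds": {
            "ppm_tolerance": config.ppm_tolerance,
            "snr_threshold": config.snr_threshold,
            "prefilter_frequency": config.prefilter_frequency,
            "marker_frequency": config.marker_frequency,
            "p_threshold": config.p_threshold,
        },
        "notes": dict(matrix.metadata),
    }
    with (out / "report.json").open("w") as fh:
        json.dump(report, fh, indent=1)
    with (out / "summary.txt").open("w") as fh:
        fh.write(
            f"glycomud {__version__} run (config {report['config_hash']})\n"
            f"library entries: {len(library)}\n"
            f"samples: {len(matrix.sample_ids)}; quantified glycoforms: "
            f"{len(matrix.entry_keys)}\n"
            f"after {config.prefilter_frequency:.0%} frequency filter: "
            f"{len(filtered.entry_keys)}\n"
            f"selected markers (p<{config.p_threshold:g}, "
            f"freq>={config.marker_frequency:.0%}): {len(markers)}\n"
            + "".join(
                f"  {g}: combined panel AUC {a:.3f}\n"
                for g, a in report["panel_auc"].items()
            )
        )
    return out
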