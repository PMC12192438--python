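"""End-to-end pipeline: screen → coverage → normalize → profiles → transport → fluxcor.

``RunConfig`` points at the six input tables plus a directory of per-sample
depth files and carries every analysis knob. ``run_pipeline`` executes all
stages, writes the stage TSVs plus a ``summary.json`` of headline counts,
and is a pure function of (inputs, config): reruns are byte-identical.
``validate_inputs`` cross-checks sample ids across metadata, depth files and
flux without mutating anything.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .coverage import (
    CoverageTable,
    NormMode,
    coverage_table,
    detect,
    fraction_reads_mapped,
    normalize,
)
from .errors import ConfigError, GvShuttleError
from .fluxnet import (
    build_modules,
    gene_significance,
    module_trait_correlation,
    select_flux_correlated,
)
from .markers import screen_contigs, taxonomy_table
from .profiles import amg_depth_profiles, depth_time_mean, taxon_profile
from .shuttle import classify_export_pulse, transport_report

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run."""

    contigs: str
    markers: str
    metadata: str
    depth_dir: str
    outdir: str
    amg: str | None = None
    flux: str | None = None
    min_markers: int = 1
    min_identity: float = 30.0
    alpha: float = 0.05
    beta: float = 6.0
    min_module_size: int = 5
    cut_height: float = 0.25
    identified_only: bool = False
    require_module_gate: bool = False
    bh_correction: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("contigs", "markers", "metadata", "amg", "flux"):
            p = getattr(self, name)
            if p is not None and not Path(p).is_file():
                raise ConfigError(f"config path {name}={p!r} does not exist")
        if not Path(self.depth_dir).is_dir():
            raise ConfigError(f"depth_dir {self.depth_dir!r} is not a directory")


def _depth_file_map(depth_dir: str | Path) -> dict[str, Path]:
    """sample id → depth file, from ``<sample>.depth.tsv`` names."""
    out = {}
    for p in sorted(Path(depth_dir).glob("*.depth.tsv")):
        out[p.name.removesuffix(".depth.tsv")] = p
    return out


def validate_inputs(config: RunConfig, strict: bool = False) -> list[dict]:
    """Cross-check sample/contig ids across the bundle; returns issue dicts."""
    issues: list[dict] = []
    config.validate_paths()
    metadata = pd.read_csv(config.metadata, sep="\t")
    depth_files = _depth_file_map(config.depth_dir)
    meta_ids = list(metadata["sample_id"])
    dup = metadata["sample_id"][metadata["sample_id"].duplicated()]
    for s in dup.unique():
        issues.append({"level": "error", "issue": "duplicate sample id",
                       "id": s, "sources": ["metadata"]})
    for s in meta_ids:
        if s not in depth_files:
            issues.append({"level": "warning", "issue": "no depth file for sample",
                           "id": s, "sources": ["metadata", "depth_dir"]})
    for s in depth_files:
        if s not in set(meta_ids):
            issues.append({"level": "warning", "issue": "depth file without metadata",
                           "id": s, "sources": ["depth_dir"]})
    if config.flux:
        flux = pd.read_csv(config.flux, sep="\t")
        flux_ids = set(flux["sample_id"])
        trap_ids = set(metadata.loc[metadata["habitat"] == "sediment_trap", "sample_id"])
        for s in sorted(trap_ids - flux_ids):
            issues.append({"level": "warning", "issue": "trap sample without flux",
                           "id": s, "sources": ["metadata", "flux"]})
        for s in sorted(flux_ids - trap_ids):
            issues.append({"level": "warning", "issue": "flux row without trap sample",
                           "id": s, "sources": ["flux", "metadata"]})
    if strict and any(i["level"] == "error" for i in issues):
        raise ConfigError(f"validation failed with {len(issues)} issue(s)")
    return issues


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; writes stage TSVs + summary.json under outdir."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        catalog = pd.read_csv(config.contigs, sep="\t")
        hit_table = pd.read_csv(config.markers, sep="\t")
        metadata = pd.read_csv(config.metadata, sep="\t")
        depth_files = _depth_file_map(config.depth_dir)

        stage = "screen"
        kept = screen_contigs(hit_table, min_markers=config.min_markers)
        catalog = catalog[catalog["contig_id"].isin(kept)].reset_index(drop=True)
        taxonomy = taxonomy_table(hit_table, min_identity=config.min_identity)
        taxonomy = taxonomy.reindex(kept)

        stage = "coverage"
        table = coverage_table(depth_files, catalog)
        table.to_tsv(outdir / "coverage_q2q3.tsv")
        rel = normalize(table, NormMode.SUM_TO_ONE)
        pct_mapped = fraction_reads_mapped(metadata)
        depth_time_mean(pct_mapped, metadata).to_csv(
            outdir / "reads_mapped_profile.tsv", sep="\t", index=False)

        stage = "profiles"
        tprof = taxon_profile(rel, taxonomy, identified_only=config.identified_only)
        tprof.to_csv(outdir / "taxon_profile.tsv", sep="\t")
        if config.amg:
            amg = pd.read_csv(config.amg, sep="\t")
            amg_depth_profiles(rel, amg, metadata).to_csv(
                outdir / "amg_profiles.tsv", sep="\t", index=False)

        stage = "transport"
        report = transport_report(table, metadata)
        report.to_csv(outdir / "transport_report.tsv", sep="\t", index=False)
        n_transported = int(report["transported"].sum())

        counts = {
            "n_contigs": int(len(catalog)),
            "n_samples": int(len(metadata)),
            "n_trap_detected": n_transported,
        }

        if config.flux:
            stage = "fluxcor"
            flux = pd.read_csv(config.flux, sep="\t")
            pulses = classify_export_pulse(flux)
            pulses.to_csv(outdir / "flux_pulses.tsv", sep="\t", index=False)
            trap_ids = [
                s for s in metadata.loc[metadata["habitat"] == "sediment_trap", "sample_id"]
                if s in rel.values.columns
            ]
            trap_rel = rel.values[trap_ids]
            gs = gene_significance(trap_rel, flux)
            gs.to_csv(outdir / "gene_significance.tsv", sep="\t", index=False)
            modules = None
            if config.require_module_gate:
                modules = build_modules(
                    trap_rel, beta=config.beta,
                    min_module_size=config.min_module_size,
                    cut_height=config.cut_height)
                module_trait_correlation(modules, flux)
                modules.labels.rename_axis("contig_id").to_frame().to_csv(
                    outdir / "modules.tsv", sep="\t")
            chosen = select_flux_correlated(
                gs, modules, alpha=config.alpha,
                require_module_gate=config.require_module_gate,
                bh_correction=config.bh_correction)
            pd.DataFrame({"contig_id": chosen}).to_csv(
                outdir / "flux_correlated_contigs.tsv", sep="\t", index=False)
            counts["n_flux_correlated"] = len(chosen)
            counts["n_pulse_samples"] = int(pulses["pulse"].sum())
    except GvShuttleError as exc:
        raise GvShuttleError(f"pipeline stage {stage!r} failed: {exc}") from exc

    summary = {
        "version": __version__,
        "config": asdict(config),
        "counts": counts,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("pipeline complete: %s", counts)
    return summary
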