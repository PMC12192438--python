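"""Vertical-transport calls, depth of origin, and export-pulse classification.

A contig counts as vertically transported when it is detected (non-zero Q2Q3
coverage) in at least one sediment-trap sample. Its *depth of origin* is the
planktonic depth where its time-averaged relative abundance peaks (ties go to
the shallower depth); the shallowest depth of any detection is reported
alongside, since the two readings of "origin" can differ for broad niches.
Trap-only contigs (never seen in the water column) get origin NA.

A trap sample is a summer export pulse when its particulate carbon flux is at
least 150% of the long-term baseline mean (inclusive boundary).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coverage import CoverageTable, NormMode, detect, normalize
from .errors import ConfigError, InputError

__all__ = ["transported_set", "depth_of_origin", "classify_export_pulse", "transport_report"]

PULSE_FACTOR = 1.5


def _split_samples(metadata: pd.DataFrame) -> tuple[list[str], list[str]]:
    meta = metadata.set_index("sample_id")
    plank = list(meta.index[meta["habitat"] == "planktonic"])
    trap = list(meta.index[meta["habitat"] == "sediment_trap"])
    return plank, trap


def transported_set(table: CoverageTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-contig trap detection: transported flag and trap-detection count.

    ``table`` must be raw-mode (detection is defined on raw Q2Q3 values).
    """
    _, trap = _split_samples(metadata)
    if not trap:
        raise ConfigError("no sediment_trap samples in metadata")
    missing = [s for s in trap if s not in table.values.columns]
    if missing:
        raise InputError(f"trap samples absent from coverage table: {missing[:5]}")
    det = detect(table)[trap]
    n_det = det.sum(axis=1).astype(int)
    return pd.DataFrame(
        {
            "contig_id": table.values.index,
            "n_trap_detections": n_det.to_numpy(),
            "transported": (n_det > 0).to_numpy(),
        }
    )


def depth_of_origin(table: CoverageTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Peak depth of the time-averaged planktonic relative abundance.

    Input is the raw table; planktonic columns are sum-to-one normalized,
    averaged through time within each nominal depth, and the argmax depth
    taken per contig (ties → shallower). Contigs never detected in the water
    column get NA for both fields.
    """
    plank, _ = _split_samples(metadata)
    if not plank:
        raise ConfigError("no planktonic samples in metadata")
    sub = CoverageTable(table.values[plank], NormMode.RAW)
    rel = normalize(sub, NormMode.SUM_TO_ONE)
    depths = metadata.set_index("sample_id").loc[plank, "depth_m"].astype(float)
    by_depth = rel.values.T.groupby(depths.to_numpy()).mean().T  # contig × depth
    by_depth = by_depth[sorted(by_depth.columns)]

    det = detect(sub)
    any_det = det.any(axis=1)
    arr = by_depth.to_numpy()
    # ties resolve to the shallower depth because argmax returns the first
    # maximum and columns are sorted ascending
    peak_idx = arr.argmax(axis=1)
    depth_grid = np.asarray(by_depth.columns, dtype=float)
    origin = np.where(any_det, depth_grid[peak_idx], np.nan)

    det_depth = det.T.groupby(depths.to_numpy()).any().T
    det_depth = det_depth[sorted(det_depth.columns)]
    darr = det_depth.to_numpy()
    first = np.where(darr.any(axis=1), darr.argmax(axis=1), 0)
    shallowest = np.where(any_det, depth_grid[first], np.nan)
    return pd.DataFrame(
        {
            "contig_id": table.values.index,
            "depth_of_origin_m": origin,
            "shallowest_detection_m": shallowest,
        }
    )


def classify_export_pulse(flux: pd.DataFrame) -> pd.DataFrame:
    """Flag summer export pulses: flux >= 1.5 × long-term baseline mean."""
    for col in ("sample_id", "flux", "baseline_mean"):
        if col not in flux.columns:
            raise InputError(f"flux table missing column {col!r}")
    if (flux["baseline_mean"] <= 0).any():
        raise InputError("baseline_mean must be positive")
    out = flux.copy()
    out["pulse"] = out["flux"] >= PULSE_FACTOR * out["baseline_mean"]
    return out


def transport_report(
    table: CoverageTable,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Full per-contig transport report (trap detection + origin fields)."""
    trans = transported_set(table, metadata)
    origin = depth_of_origin(table, metadata)
    rep = trans.merge(origin, on="contig_id")
    rep["trap_only"] = rep["transported"] & rep["depth_of_origin_m"].isna()
    return rep
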