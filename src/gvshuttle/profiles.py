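"""Spatiotemporal aggregation: depth profiles, taxon profiles, AMG proportions.

A depth profile averages a per-sample quantity through time within each
nominal depth (mean ± SE, SE = sd/√n with the n−1 sd, NA at n = 1). Taxon
profiles sum member-contig relative abundances per assigned species, with an
optional renormalization over identified species only. AMG proportions are
abundance-weighted fractions of the community annotated with a category.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .coverage import CoverageTable, NormMode
from .errors import ConfigError, InputError
from .markers import NOVEL

__all__ = ["depth_time_mean", "taxon_profile", "amg_proportion", "amg_depth_profiles"]

log = logging.getLogger(__name__)


def depth_time_mean(
    values: pd.Series,
    metadata: pd.DataFrame,
    habitat: str | None = "planktonic",
) -> pd.DataFrame:
    """Group per-sample values by nominal depth: mean, SE and n per depth.

    ``values`` is indexed by sample id. By default only planktonic samples
    contribute; pass ``habitat=None`` to aggregate everything. SE is NA when
    a depth has a single sample.
    """
    meta = metadata.set_index("sample_id")
    missing = [s for s in values.index if s not in meta.index]
    if missing:
        raise InputError(f"samples missing from metadata: {missing[:5]}")
    sel = meta.loc[values.index]
    if habitat is not None:
        keep = sel["habitat"] == habitat
        values, sel = values[keep.to_numpy()], sel[keep.to_numpy()]
    df = pd.DataFrame({"depth_m": sel["depth_m"].to_numpy(), "value": values.to_numpy()})
    grouped = df.groupby("depth_m")["value"]
    out = grouped.agg(mean="mean", n="count")
    sd = grouped.std(ddof=1)
    out["se"] = sd / np.sqrt(out["n"])
    out.loc[out["n"] == 1, "se"] = np.nan
    return out.reset_index()[["depth_m", "mean", "se", "n"]]


def taxon_profile(
    table: CoverageTable,
    taxonomy: pd.Series,
    identified_only: bool = False,
) -> pd.DataFrame:
    """Taxon × sample relative abundances from a sum-to-one contig table.

    Each contig's relative abundance is credited to its assigned species;
    contigs missing from ``taxonomy`` are treated as NOVEL with a warning.
    With ``identified_only`` the NOVEL row is dropped and each sample column
    renormalized over identified species (columns with no identified
    abundance stay zero).
    """
    if table.mode is not NormMode.SUM_TO_ONE:
        raise ConfigError("taxon_profile expects a sum_to_one table")
    tax = taxonomy.reindex(table.values.index)
    n_missing = int(tax.isna().sum())
    if n_missing:
        log.warning("%d contigs missing taxonomy; treated as %s", n_missing, NOVEL)
        tax = tax.fillna(NOVEL)
    prof = table.values.groupby(tax.to_numpy()).sum()
    prof.index.name = "taxon"
    if identified_only:
        prof = prof.drop(index=NOVEL, errors="ignore")
        if prof.empty:
            log.warning("no taxonomically identified contigs; empty taxon profile")
            return prof
        colsum = prof.sum(axis=0)
        prof = prof.div(colsum.where(colsum > 0, 1.0), axis=1)
    return prof.sort_index()


def amg_proportion(
    table: CoverageTable,
    amg: pd.DataFrame,
    category: str,
    count_based: bool = False,
) -> pd.Series:
    """Per-sample proportion of the community carrying one AMG category.

    Default is abundance-weighted: the summed relative abundance of carrier
    contigs in each sample (requires a sum-to-one table). ``count_based``
    instead reports the fraction of *detected* contigs that are carriers.
    """
    if table.mode is not NormMode.SUM_TO_ONE:
        raise ConfigError("amg_proportion expects a sum_to_one table")
    known = sorted(amg["amg_category"].unique())
    if category not in known:
        raise ConfigError(f"unknown AMG category {category!r}; known: {known}")
    carriers = set(amg.loc[amg["amg_category"] == category, "contig_id"])
    mask = table.values.index.isin(carriers)
    if count_based:
        detected = table.values > 0
        denom = detected.sum(axis=0)
        num = detected[mask].sum(axis=0)
        return (num / denom.where(denom > 0, 1)).rename(category)
    return table.values[mask].sum(axis=0).rename(category)


def amg_depth_profiles(
    table: CoverageTable,
    amg: pd.DataFrame,
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Long-format depth profile of every AMG category (mean ± SE over time)."""
    rows = []
    for cat in sorted(amg["amg_category"].unique()):
        prop = amg_proportion(table, amg, cat)
        prof = depth_time_mean(prop, metadata)
        prof.insert(0, "amg_category", cat)
        rows.append(prof)
    if not rows:
        return pd.DataFrame(columns=["amg_category", "depth_m", "mean", "se", "n"])
    return pd.concat(rows, ignore_index=True)
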