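"""NCLDV contig curation from marker-gene hit tables.

Giant-virus (NCLDV) contigs are recognised by five conserved core genes:
A32-like packaging ATPase (A32), family-B DNA polymerase (PolB), late
transcription factor 3 (VLTF3), the NCLDV major capsid protein (MCP) and the
superfamily II helicase (SFII). A contig enters the catalog when it carries
at least ``min_markers`` distinct canonical markers; a genome bin passes the
GVMAG quality gate when it carries at least four of the five.

Species-level taxonomy is assigned from the reference taxon of each marker
hit by majority vote over hits at or above an identity threshold, with ties
broken by higher mean identity; contigs without any qualifying hit are
labelled NOVEL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .errors import InputError

__all__ = [
    "CANONICAL_MARKERS",
    "NOVEL",
    "ContigRecord",
    "normalize_marker",
    "screen_contigs",
    "gvmag_quality",
    "assign_taxonomy",
    "taxonomy_table",
]

CANONICAL_MARKERS = frozenset({"A32", "PolB", "VLTF3", "MCP", "SFII"})
NOVEL = "NOVEL"

# Case-insensitive synonym map; tool outputs vary in capitalisation and
# punctuation ("polb", "vltf-3", "mcp").
_SYNONYMS = {
    "a32": "A32",
    "a32-like": "A32",
    "atpase": "A32",
    "polb": "PolB",
    "dnapolb": "PolB",
    "vltf3": "VLTF3",
    "vltf-3": "VLTF3",
    "mcp": "MCP",
    "capsid": "MCP",
    "sfii": "SFII",
    "sf2": "SFII",
    "helicase": "SFII",
}


def normalize_marker(name: str) -> str:
    """Map a marker name (any case, common synonyms) to its canonical token."""
    key = str(name).strip().lower().replace("_", "-")
    canon = _SYNONYMS.get(key) or _SYNONYMS.get(key.replace("-", ""))
    if canon is None:
        raise InputError(f"unknown marker name {name!r}; expected one of "
                         f"{sorted(CANONICAL_MARKERS)} (case-insensitive)")
    return canon


@dataclass
class ContigRecord:
    """One catalog entry: id, length, marker complement, taxon, AMG labels."""

    contig_id: str
    length_bp: int
    markers: frozenset[str] = frozenset()
    taxon: str = NOVEL
    amg_categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise InputError(f"contig {self.contig_id!r}: length_bp must be >= 1")
        self.markers = frozenset(normalize_marker(m) for m in self.markers)


def _validated_hits(hit_table: pd.DataFrame) -> pd.DataFrame:
    required = {"contig_id", "marker"}
    missing = required - set(hit_table.columns)
    if missing:
        raise InputError(f"hit table missing columns {sorted(missing)}")
    out = hit_table.copy()
    canon = []
    for idx, name in out["marker"].items():
        try:
            canon.append(normalize_marker(name))
        except InputError as exc:
            raise InputError(f"hit table row {idx}: {exc}") from exc
    out["marker"] = canon
    return out


def screen_contigs(hit_table: pd.DataFrame, min_markers: int = 1) -> list[str]:
    """Contig ids with >= ``min_markers`` distinct canonical markers, sorted."""
    if min_markers < 1:
        raise InputError("min_markers must be >= 1")
    hits = _validated_hits(hit_table)
    if hits.empty:
        return []
    n_distinct = hits.groupby("contig_id")["marker"].nunique()
    return sorted(n_distinct.index[n_distinct >= min_markers])


def gvmag_quality(marker_set: Iterable[str]) -> bool:
    """GVMAG quality rule: at least four of the five canonical markers."""
    canon = {normalize_marker(m) for m in marker_set}
    return len(canon) >= 4


def assign_taxonomy(contig_hits: pd.DataFrame, min_identity: float = 30.0) -> str:
    """Species assignment for one contig's marker hits, or NOVEL.

    Hits below ``min_identity`` percent identity are discarded; the taxon
    with the most remaining marker hits wins; ties go to the taxon with the
    higher mean identity (then lexicographic for full determinism). With no
    qualifying hit the contig is NOVEL.
    """
    if contig_hits.empty:
        return NOVEL
    for col in ("ref_taxon", "pct_identity"):
        if col not in contig_hits.columns:
            raise InputError(f"hit table missing column {col!r}")
    ident = pd.to_numeric(contig_hits["pct_identity"], errors="coerce")
    if ident.isna().any() or (ident < 0).any() or (ident > 100).any():
        raise InputError("pct_identity must be numeric in [0, 100]")
    keep = contig_hits.loc[ident >= min_identity].assign(pct_identity=ident[ident >= min_identity])
    keep = keep.dropna(subset=["ref_taxon"])
    if keep.empty:
        return NOVEL
    stats = keep.groupby("ref_taxon")["pct_identity"].agg(["count", "mean"])
    stats = stats.sort_values(["count", "mean"], ascending=False)
    top = stats[(stats["count"] == stats["count"].iloc[0]) & (stats["mean"] == stats["mean"].iloc[0])]
    if len(top) == 1:
        return str(stats.index[0])
    return str(sorted(top.index)[0])


def taxonomy_table(hit_table: pd.DataFrame, min_identity: float = 30.0) -> pd.Series:
    """Per-contig taxonomy over a whole hit table (contig id → taxon/NOVEL)."""
    hits = _validated_hits(hit_table)
    if hits.empty:
        return pd.Series(dtype=object, name="taxon")
    out = {
        contig: assign_taxonomy(grp, min_identity=min_identity)
        for contig, grp in hits.groupby("contig_id")
    }
    s = pd.Series(out, name="taxon").sort_index()
    s.index.name = "contig_id"
    return s
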