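"""Per-contig Q2Q3 coverage from per-base depths, normalization and detection.

The abundance statistic throughout the pipeline is *Q2Q3 coverage*: the mean
per-base read depth over the central two quartiles of position ranks, i.e. the
lowest 25% and highest 25% of per-base depths are discarded before averaging.
This trims both uncovered contig edges and spuriously high-coverage islands
(conserved motifs, repeats), giving a robust per-sample abundance proxy for a
contig. A direct consequence is a breadth rule: a contig whose covered
positions number no more than ``floor(L/4)`` has Q2Q3 = 0 and is treated as
undetected.

Depth input follows the ``samtools depth`` dialect: three tab-separated
columns (contig id, 1-based position, depth), no header, with zero-depth
positions optionally omitted — consumers zero-fill against the catalog
length.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

__all__ = [
    "NormMode",
    "CoverageTable",
    "q2q3",
    "read_depth_file",
    "coverage_table",
    "normalize",
    "detect",
    "fraction_reads_mapped",
]


class NormMode(str, enum.Enum):
    """Normalization applied to a coverage table, column (= sample) wise."""

    RAW = "raw"
    SUM_TO_ONE = "sum_to_one"
    MAX_OF_SAMPLE = "max_of_sample"


@dataclass
class CoverageTable:
    """Contig × sample matrix of Q2Q3 coverage values.

    ``values`` is a DataFrame indexed by contig id with sample ids as
    columns; ``mode`` records which normalization (if any) has been applied.
    """

    values: pd.DataFrame
    mode: NormMode = NormMode.RAW

    def __post_init__(self) -> None:
        self.mode = NormMode(self.mode)
        arr = self.values.to_numpy()
        if arr.size and (arr < 0).any():
            raise InputError("coverage values must be non-negative")

    @property
    def contigs(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="contig_id")

    @classmethod
    def from_tsv(cls, path: str | Path, mode: NormMode | str = NormMode.RAW) -> "CoverageTable":
        df = pd.read_csv(path, sep="\t", index_col="contig_id")
        return cls(df, NormMode(mode))


def q2q3(depth_vector: Iterable[float]) -> float:
    """Mean depth over the central two quartiles of position ranks.

    The vector must span the full contig length (zero-filled). With
    ``L = len(depth_vector)`` and ``k = floor(L/4)``, depths are sorted
    ascending and the mean of ranks ``k .. L-k-1`` (0-based) is returned.
    For ``L < 4`` trimming is undefined and the plain mean is returned.
    """
    d = np.asarray(list(depth_vector) if not isinstance(depth_vector, np.ndarray) else depth_vector, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise InputError("depth vector must be a non-empty 1-D sequence")
    if (d < 0).any():
        raise InputError("per-base depths must be non-negative")
    L = d.size
    if L < 4:
        return float(d.mean())
    k = L // 4
    s = np.sort(d)
    return float(s[k : L - k].mean())


def read_depth_file(path: str | Path) -> pd.DataFrame:
    """Read a samtools-depth dialect TSV into (contig, pos, depth) columns."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["contig", "pos", "depth"],
            dtype={"contig": str, "pos": np.int64, "depth": np.int64},
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame({"contig": pd.Series(dtype=str),
                             "pos": pd.Series(dtype=np.int64),
                             "depth": pd.Series(dtype=np.int64)})
    except (ValueError, TypeError) as exc:
        raise InputError(f"malformed depth file {path}: {exc}") from exc
    if len(df) and ((df["pos"] < 1).any() or (df["depth"] < 0).any()):
        bad = df[(df["pos"] < 1) | (df["depth"] < 0)].index[0]
        raise InputError(f"depth file {path}: invalid position/depth at row {bad}")
    return df


def coverage_table(
    depth_files: Mapping[str, str | Path],
    catalog: pd.DataFrame,
) -> CoverageTable:
    """Build a raw contig × sample Q2Q3 table from per-sample depth files.

    ``depth_files`` maps sample id → depth TSV path; ``catalog`` must carry
    ``contig_id`` and ``length_bp`` columns. Positions absent from a depth
    file count as depth 0; contigs absent entirely get Q2Q3 = 0. A position
    beyond the cataloged contig length is an input error naming the file.
    """
    if "contig_id" not in catalog.columns or "length_bp" not in catalog.columns:
        raise InputError("catalog needs contig_id and length_bp columns")
    lengths = catalog.set_index("contig_id")["length_bp"].astype(int)
    if (lengths < 1).any():
        raise InputError("contig lengths must be >= 1")
    contigs = list(lengths.index)
    samples = list(depth_files)
    out = np.zeros((len(contigs), len(samples)))
    contig_pos = {c: i for i, c in enumerate(contigs)}

    for j, sample in enumerate(samples):
        df = read_depth_file(depth_files[sample])
        if df.empty:
            continue
        unknown = set(df["contig"]) - set(contig_pos)
        if unknown:
            raise InputError(
                f"depth file for sample {sample!r} references contigs not in "
                f"the catalog: {sorted(unknown)[:5]}"
            )
        for contig, grp in df.groupby("contig", sort=False):
            L = int(lengths[contig])
            pos = grp["pos"].to_numpy()
            if pos.max() > L:
                raise InputError(
                    f"depth file for sample {sample!r}: position {int(pos.max())} "
                    f"exceeds length {L} of contig {contig!r}"
                )
            full = np.zeros(L)
            full[pos - 1] = grp["depth"].to_numpy()
            out[contig_pos[contig], j] = q2q3(full)
    return CoverageTable(pd.DataFrame(out, index=contigs, columns=samples), NormMode.RAW)


def normalize(table: CoverageTable, mode: NormMode | str) -> CoverageTable:
    """Column-wise normalization of a raw table.

    ``sum_to_one`` divides each sample column by its sum (relative
    abundance); ``max_of_sample`` divides by the column maximum. All-zero
    columns pass through unchanged — no NaNs are produced.
    """
    try:
        mode = NormMode(mode)
    except ValueError as exc:
        raise ConfigError(f"unknown normalization mode {mode!r}") from exc
    if table.mode is not NormMode.RAW:
        raise ConfigError("normalize expects a raw-mode table")
    if mode is NormMode.RAW:
        return CoverageTable(table.values.copy(), NormMode.RAW)
    arr = table.values.to_numpy(dtype=float, copy=True)
    denom = arr.sum(axis=0) if mode is NormMode.SUM_TO_ONE else arr.max(axis=0, initial=0.0)
    safe = np.where(denom > 0, denom, 1.0)
    arr /= safe
    return CoverageTable(
        pd.DataFrame(arr, index=table.values.index, columns=table.values.columns), mode
    )


def detect(table: CoverageTable) -> pd.DataFrame:
    """Boolean detection matrix: Q2Q3 strictly greater than zero.

    Computed on the raw table; because normalization preserves the zero
    pattern the result is identical either way, but the raw-mode requirement
    keeps the provenance unambiguous.
    """
    if table.mode is not NormMode.RAW:
        raise ConfigError("detect expects a raw-mode table")
    return table.values > 0


def fraction_reads_mapped(metadata: pd.DataFrame) -> pd.Series:
    """Percent of reads recruited to the contig catalog, per sample.

    ``metadata`` needs ``sample_id``, ``total_reads`` and ``mapped_reads``
    columns; returns a Series of percentages indexed by sample id.
    """
    for col in ("sample_id", "total_reads", "mapped_reads"):
        if col not in metadata.columns:
            raise InputError(f"metadata missing column {col!r}")
    total = metadata["total_reads"].astype(float)
    mapped = metadata["mapped_reads"].astype(float)
    if (total <= 0).any():
        raise InputError("total_reads must be positive")
    if (mapped > total).any():
        bad = metadata.loc[mapped > total, "sample_id"].iloc[0]
        raise InputError(f"sample {bad!r}: mapped_reads exceeds total_reads")
    if (mapped < 0).any():
        raise InputError("mapped_reads must be non-negative")
    pct = 100.0 * mapped / total
    pct.index = metadata["sample_id"]
    return pct.rename("pct_reads_mapped")
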