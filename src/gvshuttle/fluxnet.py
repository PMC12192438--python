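"""Flux-correlated population detection: gene significance and co-abundance modules.

*Gene significance* (GS) is the Pearson correlation of a contig's trap-sample
relative abundance with particulate carbon flux, with a two-sided p-value
from t = r·√(n−2)/√(1−r²) on n−2 degrees of freedom. The selection rule for
flux-associated populations is r > 0 and p < α (raw p-values by default;
Benjamini–Hochberg available behind a flag).

The optional co-abundance module stage mirrors weighted correlation-network
analysis: soft-thresholded adjacency |cor|^β, topological-overlap similarity,
average-linkage clustering of 1−TOM with a static cut, module eigengenes
(first PC of standardized member profiles, sign-oriented toward the members),
and module–trait correlation. When the module gate is enabled, selected
contigs must additionally belong to a module whose eigengene correlates
positively and significantly with flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import InputError

__all__ = [
    "gene_significance",
    "build_modules",
    "select_flux_correlated",
    "ModuleAssignment",
]

UNASSIGNED = "grey"


def _pearson_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from the exact t transform of a Pearson correlation."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    return p


def gene_significance(trap_table: pd.DataFrame, flux: pd.DataFrame) -> pd.DataFrame:
    """Per-contig Pearson r/p against flux across trap samples.

    ``trap_table`` is contig × trap-sample (any consistent abundance scale;
    the pipeline feeds sum-to-one relative abundance); ``flux`` carries
    sample_id and flux. Rows are aligned to flux by sample id; at least 4
    paired samples are required. Constant contig profiles (including
    all-zero) are flagged and get NaN statistics.
    """
    fser = flux.set_index("sample_id")["flux"] if isinstance(flux, pd.DataFrame) else flux
    common = [s for s in trap_table.columns if s in fser.index]
    n = len(common)
    if n < 4:
        raise InputError(f"need >= 4 trap samples with flux, have {n}")
    X = trap_table[common].to_numpy(dtype=float)
    y = fser.loc[common].to_numpy(dtype=float)

    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    xnorm = np.sqrt((Xc**2).sum(axis=1))
    ynorm = np.sqrt((yc**2).sum())
    constant = xnorm == 0
    if ynorm == 0:
        raise InputError("flux series is constant; correlation undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ yc) / (xnorm * ynorm)
    r[constant] = np.nan
    p = np.full_like(r, np.nan)
    ok = ~constant
    p[ok] = _pearson_p(r[ok], n)
    return pd.DataFrame(
        {
            "contig_id": trap_table.index,
            "r": r,
            "p": p,
            "n": n,
            "flagged_constant": constant,
        }
    )


@dataclass
class ModuleAssignment:
    """Module labels plus eigengenes and module–trait statistics."""

    labels: pd.Series                      # contig id → module label or "grey"
    eigengenes: pd.DataFrame               # sample × module
    module_trait: pd.DataFrame = field(default_factory=pd.DataFrame)  # module, r, p

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])


def _tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological-overlap matrix of an adjacency with zeroed diagonal."""
    a = adj.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def build_modules(
    trap_table: pd.DataFrame,
    beta: float = 6.0,
    min_module_size: int = 5,
    cut_height: float = 0.25,
) -> ModuleAssignment:
    """Co-abundance modules via soft-threshold adjacency + TOM clustering.

    Constant rows are pre-assigned to "grey". Contigs are processed in
    sorted-id order and modules labelled M1, M2, ... by decreasing size
    (then smallest member id), so the result is invariant to input order.
    """
    if beta < 1:
        raise InputError("beta must be >= 1")
    if len(trap_table) < 2:
        raise InputError("need >= 2 contigs to build modules")
    table = trap_table.sort_index()
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=1)
    variable = sd > 0
    if variable.sum() < 2:
        raise InputError("co-abundance matrix is degenerate (all-constant profiles)")
    ids = np.asarray(table.index)
    Xv = X[variable]

    corr = np.corrcoef(Xv)
    corr = np.nan_to_num(np.clip(corr, -1.0, 1.0))
    adj = np.abs(corr) ** beta
    tom = _tom_similarity(adj)
    dist = 1.0 - tom
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    clusters = fcluster(Z, t=cut_height, criterion="distance")

    labels = pd.Series(UNASSIGNED, index=ids, dtype=object, name="module")
    var_ids = ids[variable]
    raw = pd.Series(clusters, index=var_ids)
    sizes = raw.value_counts()
    keep = [c for c in sizes.index if sizes[c] >= min_module_size]
    # deterministic naming: by size desc, then smallest member id
    keep.sort(key=lambda c: (-sizes[c], min(raw.index[raw == c])))
    for rank, c in enumerate(keep, start=1):
        labels.loc[raw.index[raw == c]] = f"M{rank}"

    eig = {}
    for mod in [f"M{r}" for r in range(1, len(keep) + 1)]:
        members = labels.index[labels == mod]
        M = table.loc[members].to_numpy(dtype=float)
        Ms = (M - M.mean(axis=1, keepdims=True)) / M.std(axis=1, keepdims=True)
        u, s, vt = np.linalg.svd(Ms, full_matrices=False)
        e = vt[0]  # sample-space first principal component
        member_corr = np.array([np.corrcoef(e, row)[0, 1] for row in Ms])
        if member_corr.mean() < 0:
            e = -e
        eig[mod] = e
    eigengenes = pd.DataFrame(eig, index=table.columns)
    return ModuleAssignment(labels=labels, eigengenes=eigengenes)


def module_trait_correlation(modules: ModuleAssignment, flux: pd.DataFrame) -> pd.DataFrame:
    """Eigengene–flux Pearson r and p for every module."""
    fser = flux.set_index("sample_id")["flux"] if isinstance(flux, pd.DataFrame) else flux
    rows = []
    for mod in modules.eigengenes.columns:
        e = modules.eigengenes[mod]
        common = [s for s in e.index if s in fser.index]
        if len(common) < 4:
            raise InputError("need >= 4 samples for module-trait correlation")
        r, p = stats.pearsonr(e.loc[common], fser.loc[common])
        rows.append((mod, r, p, len(common)))
    df = pd.DataFrame(rows, columns=["module", "r", "p", "n"])
    modules.module_trait = df
    return df


def select_flux_correlated(
    gs: pd.DataFrame,
    modules: ModuleAssignment | None = None,
    alpha: float = 0.05,
    require_module_gate: bool = False,
    bh_correction: bool = False,
) -> list[str]:
    """Contigs positively and significantly correlated with export flux.

    The base rule is r > 0 and p < alpha on the gene-significance table
    (constant-flagged rows excluded). With the module gate, a contig must
    also belong to a module whose eigengene–flux correlation is positive
    with p < alpha. ``bh_correction`` applies Benjamini–Hochberg to the GS
    p-values before thresholding.
    """
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    ok = gs.loc[~gs["flagged_constant"]].copy()
    pvals = ok["p"].to_numpy()
    if bh_correction and len(pvals):
        pvals = stats.false_discovery_control(pvals, method="bh")
    selected = ok.loc[(ok["r"] > 0) & (pvals < alpha), "contig_id"]
    chosen = set(selected)
    if require_module_gate:
        if modules is None:
            raise InputError("module gate requested but no ModuleAssignment given")
        if modules.eigengenes.empty:
            return []  # no modules survived the cut: nothing passes the gate
        if modules.module_trait.empty:
            raise InputError("module gate requested but module_trait not computed")
        good = set(
            modules.module_trait.loc[
                (modules.module_trait["r"] > 0) & (modules.module_trait["p"] < alpha),
                "module",
            ]
        )
        gated = {c for c in chosen if modules.labels.get(c, UNASSIGNED) in good}
        chosen = gated
    return sorted(chosen)
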