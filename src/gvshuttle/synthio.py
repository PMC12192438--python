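"""Synthetic metagenomic coverage bundles with a planted transport/flux signal.

Emulates the statistical structure of a multi-year oligotrophic-gyre time
series: planktonic metagenomes on a fixed depth grid (5–4000 m) sampled
monthly, plus a block of deep sediment-trap metagenomes carrying particulate
carbon flux measurements. Each contig receives a Gaussian abundance niche on
the log10-depth axis (reproducing epipelagic / deep-chlorophyll-maximum /
mesopelagic peak structure); a planted subset is additionally given non-zero
trap coverage ("transported"), and a planted subset of those has trap
abundance coupled to the standardized flux ("flux-coupled"):

    trap coverage = baseline × max(0, 1 + effect × z_flux) × lognormal noise

Per-base realisation: a covered contig×sample cell is a constant integer
depth over a contiguous covered prefix of the contig, so its Q2Q3 statistic
has an exact closed form and depth files round-trip losslessly through the
coverage module.

Randomness derives from one global seed via per-component and per-sample
``numpy.random.SeedSequence`` spawn keys, so adding samples never perturbs
earlier ones and identical configs are byte-identical on disk.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .coverage import CoverageTable, NormMode
from .errors import ConfigError
from .markers import CANONICAL_MARKERS, NOVEL

__all__ = ["SimConfig", "SimBundle", "simulate", "write_depth_files"]

DEFAULT_DEPTHS_M = (5, 25, 45, 75, 100, 125, 150, 175, 200, 225, 250, 500, 770, 1000, 4000)

# Reference species pool for taxonomic hits, weighted roughly by how often
# each appears among identified contigs in open-ocean NCLDV catalogs.
REFERENCE_TAXA = (
    ("Bathycoccus sp. RCC716 virus", 0.21),
    ("Mimiviridae sp. ChoanoV1", 0.20),
    ("Chrysochromulina ericina virus", 0.16),
    ("Organic lake phycodnavirus", 0.12),
    ("Pentanymphon antarcticum iridovirus", 0.08),
    ("Prasinovirus sp.", 0.06),
    ("Phaeocystis globosa virus 14T", 0.05),
    ("Aureococcus anophagefferens virus", 0.05),
    ("Chlorella virus XW01", 0.04),
    ("Pyramimonas orientalis virus", 0.03),
)

AMG_CATEGORIES = (
    "photosynthesis",
    "central_carbon_metabolism",
    "rhodopsin",
    "nitrogen_cycle",
    "ammonium_transporter",
    "phosphate_transporter",
)

_MARKER_LIST = tuple(sorted(CANONICAL_MARKERS))


@dataclass(frozen=True)
class SimConfig:
    """Study design and signal parameters for one synthetic bundle.

    Defaults mirror the emulated field campaign: 1496 cataloged contigs, 15
    nominal depths from 5 to 4000 m sampled monthly over a 36-month window,
    63 sediment-trap samples at 4000 m, 468/1496 of contigs reaching the
    traps and 101/1496 of them flux-coupled, and ~20.9% of contigs
    taxonomically identifiable.
    """

    seed: int = 0
    depths_m: tuple[float, ...] = DEFAULT_DEPTHS_M
    n_months: int = 36
    n_trap_samples: int = 63
    n_contigs: int = 1496
    contig_length_range: tuple[int, int] = (5_000, 20_000)
    frac_transported: float = 468 / 1496
    frac_flux_coupled: float = 101 / 1496
    coupling_effect: float = 1.0
    noise_sd: float = 0.3
    pulse_months: tuple[int, ...] = (6, 7, 8)  # month-of-year, 0-based (Jul–Sep)
    baseline_flux: float = 25.0  # mg C m^-2 d^-1 scale; units only need consistency
    frac_identified: float = 0.209
    mean_mapped_frac: float = 0.005
    min_coverage: float = 0.5  # planktonic niche floor below which coverage is 0
    start_year: int = 2014

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ConfigError("n_contigs must be >= 1")
        for name in ("frac_transported", "frac_flux_coupled", "frac_identified"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        depths = tuple(float(d) for d in self.depths_m)
        if len(depths) == 0:
            raise ConfigError("depths_m must be non-empty")
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ConfigError("depths_m must be strictly increasing")
        if min(depths) <= 0:
            raise ConfigError("depths must be positive (metres below surface)")
        lo, hi = self.contig_length_range
        if lo < 4 or hi < lo:
            raise ConfigError("contig_length_range must satisfy 4 <= lo <= hi")
        if self.n_months < 1 or self.n_trap_samples < 0:
            raise ConfigError("n_months >= 1 and n_trap_samples >= 0 required")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.baseline_flux <= 0:
            raise ConfigError("baseline_flux must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["depths_m"] = list(self.depths_m)
        d["contig_length_range"] = list(self.contig_length_range)
        d["pulse_months"] = list(self.pulse_months)
        return d


@dataclass
class SimBundle:
    """All tables of one simulated campaign plus the planted ground truth.

    ``coverage`` holds the realized raw Q2Q3 matrix (the same values a
    consumer recovers by parsing the serialized depth files). ``depth_int``
    and ``n_cov`` are the per-cell constant depth and covered-prefix length
    that define the per-base profiles.
    """

    config: SimConfig
    contigs: pd.DataFrame      # contig_id, length_bp
    markers: pd.DataFrame      # contig_id, marker, ref_taxon, pct_identity
    amg: pd.DataFrame          # contig_id, amg_category
    metadata: pd.DataFrame     # sample_id, collection_date, depth_m, habitat, reads
    flux: pd.DataFrame         # sample_id, flux, baseline_mean
    truth: pd.DataFrame        # contig_id, transported, flux_coupled, ...
    coverage: CoverageTable
    depth_int: np.ndarray = field(repr=False, default=None)
    n_cov: np.ndarray = field(repr=False, default=None)

    @property
    def transported_ids(self) -> set[str]:
        return set(self.truth.loc[self.truth["transported"], "contig_id"])

    @property
    def flux_coupled_ids(self) -> set[str]:
        return set(self.truth.loc[self.truth["flux_coupled"], "contig_id"])

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Serialize every table plus per-sample depth files; returns a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, str] = {}

        def _put(name: str, df: pd.DataFrame) -> None:
            p = outdir / name
            df.to_csv(p, sep="\t", index=False)
            paths[name.removesuffix(".tsv")] = str(p)

        _put("contigs.tsv", self.contigs)
        _put("markers.tsv", self.markers)
        _put("amg.tsv", self.amg)
        _put("metadata.tsv", self.metadata)
        _put("flux.tsv", self.flux)
        _put("truth.tsv", self.truth)
        depth_dir = outdir / "depth"
        paths["depth_files"] = {
            s: str(p) for s, p in write_depth_files(self, depth_dir).items()
        }
        # manifest records paths relative to the bundle root so that two
        # bundles from the same config are byte-identical wherever they live
        rel = {
            k: ({s: str(Path(p).relative_to(outdir)) for s, p in v.items()}
                if isinstance(v, dict) else str(Path(v).relative_to(outdir)))
            for k, v in paths.items()
        }
        manifest = {"config": self.config.to_dict(), "paths": rel}
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        paths["manifest"] = str(outdir / "manifest.yaml")
        return paths


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _q2q3_const_profile(L: np.ndarray, n_cov: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Closed-form Q2Q3 for a constant depth ``d`` over ``n_cov`` covered positions.

    Sorted depths are (L - n_cov) zeros followed by n_cov copies of d; the
    trimmed window keeps ranks k .. L-k-1 with k = floor(L/4). For L < 4 the
    statistic is the plain mean.
    """
    L = np.asarray(L, dtype=np.int64)
    n_cov = np.asarray(n_cov, dtype=np.int64)
    d = np.asarray(d, dtype=float)
    k = L // 4
    kept = np.maximum(L - 2 * k, 1)
    zeros_kept = np.clip(L - n_cov - k, 0, kept)
    trimmed = d * (kept - zeros_kept) / kept
    plain = d * n_cov / np.maximum(L, 1)
    return np.where(L < 4, plain, trimmed)


def _month_date(start_year: int, month_float: float) -> str:
    year = start_year + int(month_float) // 12
    month = int(month_float) % 12 + 1
    day = min(28, 1 + int((month_float % 1.0) * 28))
    return f"{year:04d}-{month:02d}-{day:02d}"


def _simulate_flux(config: SimConfig) -> tuple[pd.DataFrame, np.ndarray]:
    """Trap-sample flux series: seasonal sinusoid plus amplified pulse months."""
    rng = _rng(config.seed, 2)
    n = config.n_trap_samples
    month_pos = np.linspace(0.0, config.n_months, n, endpoint=False)
    moy = (month_pos.astype(int)) % 12
    is_pulse_month = np.isin(moy, np.asarray(config.pulse_months, dtype=int))
    seasonal = 1.0 + 0.25 * np.sin(2 * np.pi * moy / 12.0)
    noise = np.exp(rng.normal(0.0, 0.08, size=n))
    flux = config.baseline_flux * seasonal * noise
    # pulse months are drawn at >= 1.6x the long-term mean so that both pulse
    # and non-pulse samples are guaranteed to exist
    flux[is_pulse_month] = config.baseline_flux * rng.uniform(1.6, 2.2, size=int(is_pulse_month.sum()))
    sample_ids = [f"trap_{i:03d}" for i in range(n)]
    df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "flux": flux,
            "baseline_mean": config.baseline_flux,
        }
    )
    return df, month_pos


def simulate(config: SimConfig) -> SimBundle:
    """Generate one full dataset bundle from a :class:`SimConfig`."""
    n = config.n_contigs
    depths = np.asarray(config.depths_m, dtype=float)

    # --- contig attributes (stream 0) -------------------------------------
    crng = _rng(config.seed, 0)
    lo, hi = config.contig_length_range
    lengths = crng.integers(lo, hi + 1, size=n)
    contig_ids = np.array([f"ctg_{i:05d}" for i in range(n)])
    log_lo, log_hi = np.log10(depths[0]), np.log10(depths[-1])
    mu = crng.uniform(log_lo, log_hi, size=n)          # niche center, log10 m
    sigma = crng.uniform(0.15, 0.45, size=n)           # niche width, log10 units
    amp = np.exp(crng.normal(np.log(50.0), 0.5, size=n))   # peak coverage depth

    n_trans = int(round(config.frac_transported * n))
    n_coupled = min(int(round(config.frac_flux_coupled * n)), n_trans)
    transported_idx = crng.choice(n, size=n_trans, replace=False)
    coupled_idx = (
        crng.choice(transported_idx, size=n_coupled, replace=False)
        if n_coupled
        else np.empty(0, dtype=int)
    )
    transported = np.zeros(n, dtype=bool)
    transported[transported_idx] = True
    coupled = np.zeros(n, dtype=bool)
    coupled[coupled_idx] = True
    trap_base = np.exp(crng.normal(np.log(30.0), 0.4, size=n))  # trap coverage scale

    # --- marker hits / taxonomy (stream 1) --------------------------------
    mrng = _rng(config.seed, 1)
    n_markers = mrng.choice([1, 2, 3, 4, 5], size=n, p=[0.50, 0.20, 0.12, 0.10, 0.08])
    identified = mrng.random(n) < config.frac_identified
    taxa = np.array([t for t, _ in REFERENCE_TAXA])
    weights = np.array([w for _, w in REFERENCE_TAXA])
    weights = weights / weights.sum()
    true_taxon = np.where(identified, mrng.choice(taxa, size=n, p=weights), NOVEL)

    marker_rows = []
    for i in range(n):
        picks = mrng.choice(_MARKER_LIST, size=n_markers[i], replace=False)
        for m in picks:
            if identified[i]:
                # occasional off-target marker hit exercises the majority vote
                if n_markers[i] > 1 and mrng.random() < 0.10:
                    other = mrng.choice(taxa[taxa != true_taxon[i]])
                    marker_rows.append((contig_ids[i], m, other, round(mrng.uniform(31, 50), 1)))
                else:
                    marker_rows.append((contig_ids[i], m, true_taxon[i], round(mrng.uniform(40, 95), 1)))
            else:
                ref = mrng.choice(taxa)
                marker_rows.append((contig_ids[i], m, ref, round(mrng.uniform(10, 28), 1)))
    markers_df = pd.DataFrame(marker_rows, columns=["contig_id", "marker", "ref_taxon", "pct_identity"])

    # --- AMG annotations, niche-biased (stream 3) --------------------------
    arng = _rng(config.seed, 3)
    span = max(log_hi - log_lo, 1e-9)
    shallow = (mu - log_lo) / span  # 0 = surface niche, 1 = abyssal
    amg_rows = []
    # photosynthesis carriers bump near the DCM (~100 m, shallow ~ 0.45);
    # transporters tilt deep where nutrients or competitors concentrate
    probs = {
        "photosynthesis": 0.08 + 0.25 * np.exp(-((shallow - 0.45) ** 2) / 0.03),
        "central_carbon_metabolism": np.full(n, 0.12),
        "rhodopsin": 0.15 * np.exp(-((shallow - 0.35) ** 2) / 0.05),
        "nitrogen_cycle": np.full(n, 0.05),
        "ammonium_transporter": 0.12 * shallow,
        "phosphate_transporter": 0.10 * (1 - shallow),
    }
    for cat in AMG_CATEGORIES:
        hit = arng.random(n) < probs[cat]
        for cid in contig_ids[hit]:
            amg_rows.append((cid, cat))
    amg_df = pd.DataFrame(sorted(amg_rows), columns=["contig_id", "amg_category"])

    # --- flux series --------------------------------------------------------
    flux_df, trap_month_pos = _simulate_flux(config)
    fvals = flux_df["flux"].to_numpy()
    z = (fvals - fvals.mean()) / fvals.std() if len(fvals) > 1 and fvals.std() > 0 else np.zeros_like(fvals)

    # --- planktonic samples (per-sample streams, spawn key (10, depth, month))
    plank_ids, plank_meta = [], []
    n_plank = len(depths) * config.n_months
    total_samples = n_plank + config.n_trap_samples
    depth_int = np.zeros((n, total_samples), dtype=np.int64)
    n_cov = np.zeros((n, total_samples), dtype=np.int64)

    col = 0
    for month in range(config.n_months):
        for di, D in enumerate(depths):
            srng = _rng(config.seed, 10, di, month)
            niche = amp * np.exp(-((np.log10(D) - mu) ** 2) / (2 * sigma**2))
            c = niche * np.exp(srng.normal(0.0, config.noise_sd, size=n))
            c[c < config.min_coverage] = 0.0
            d = np.where(c > 0, np.maximum(1, np.rint(c)).astype(np.int64), 0)
            breadth = srng.uniform(0.6, 1.0, size=n)
            nc = np.where(d > 0, np.maximum(1, np.rint(breadth * lengths)).astype(np.int64), 0)
            depth_int[:, col] = d
            n_cov[:, col] = nc
            sid = f"plk_m{month:02d}_d{int(D):04d}"
            plank_ids.append(sid)
            total_reads = int(np.exp(srng.normal(np.log(1e7), 0.3)))
            shape = 0.7 + 0.9 * np.exp(-((np.log10(D) - np.log10(180.0)) ** 2) / (2 * 0.15**2))
            mfrac = config.mean_mapped_frac * shape * np.exp(srng.normal(0.0, 0.2))
            plank_meta.append(
                (sid, _month_date(config.start_year, month + 0.5), float(D), "planktonic",
                 total_reads, min(total_reads, int(round(total_reads * mfrac)))))
            col += 1

    # --- trap samples (spawn key (11, i)) -----------------------------------
    trap_meta = []
    for i in range(config.n_trap_samples):
        srng = _rng(config.seed, 11, i)
        c = np.zeros(n)
        noise = np.exp(srng.normal(0.0, config.noise_sd, size=n))
        c[transported] = trap_base[transported] * noise[transported]
        gain = max(0.0, 1.0 + config.coupling_effect * z[i]) if len(z) else 1.0
        c[coupled] *= gain
        d = np.where(c > 0, np.maximum(1, np.rint(c)).astype(np.int64), 0)
        depth_int[:, col] = d
        n_cov[:, col] = np.where(d > 0, lengths, 0)  # traps: full-breadth coverage
        sid = f"trap_{i:03d}"
        total_reads = int(np.exp(srng.normal(np.log(5e6), 0.3)))
        mfrac = config.mean_mapped_frac * 0.6 * np.exp(srng.normal(0.0, 0.2))
        trap_meta.append(
            (sid, _month_date(config.start_year, float(trap_month_pos[i])), 4000.0,
             "sediment_trap", total_reads, min(total_reads, int(round(total_reads * mfrac)))))
        col += 1

    sample_ids = plank_ids + [m[0] for m in trap_meta]
    metadata = pd.DataFrame(
        plank_meta + trap_meta,
        columns=["sample_id", "collection_date", "depth_m", "habitat", "total_reads", "mapped_reads"],
    )

    L_col = lengths[:, None]
    cov_values = _q2q3_const_profile(
        np.broadcast_to(L_col, depth_int.shape), n_cov, depth_int.astype(float)
    )
    coverage = CoverageTable(
        pd.DataFrame(cov_values, index=list(contig_ids), columns=sample_ids), NormMode.RAW
    )

    expected_origin = np.array(
        [depths[np.argmin(np.abs(np.log10(depths) - m))] for m in mu]
    )
    truth = pd.DataFrame(
        {
            "contig_id": contig_ids,
            "transported": transported,
            "flux_coupled": coupled,
            "taxon": true_taxon,
            "niche_depth_m": np.round(10.0**mu, 1),
            "expected_origin_m": expected_origin,
        }
    )
    contigs_df = pd.DataFrame({"contig_id": contig_ids, "length_bp": lengths})

    return SimBundle(
        config=config,
        contigs=contigs_df,
        markers=markers_df,
        amg=amg_df,
        metadata=metadata,
        flux=flux_df,
        truth=truth,
        coverage=coverage,
        depth_int=depth_int,
        n_cov=n_cov,
    )


def write_depth_files(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """One samtools-depth dialect TSV per sample; zero-depth rows omitted.

    The covered prefix of each contig (positions 1..n_cov) is written at the
    cell's constant depth, exactly the profile whose Q2Q3 the bundle's
    in-memory coverage matrix records.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contig_ids = bundle.contigs["contig_id"].to_numpy()
    paths: dict[str, Path] = {}
    for j, sample in enumerate(bundle.coverage.samples):
        p = outdir / f"{sample}.depth.tsv"
        d = bundle.depth_int[:, j]
        nc = bundle.n_cov[:, j]
        covered = np.nonzero(d > 0)[0]
        if covered.size:
            reps = nc[covered]
            contig_col = np.repeat(contig_ids[covered], reps)
            pos_col = np.concatenate([np.arange(1, r + 1) for r in reps])
            depth_col = np.repeat(d[covered], reps)
            pd.DataFrame({"c": contig_col, "p": pos_col, "d": depth_col}).to_csv(
                p, sep="\t", header=False, index=False
            )
        else:
            p.write_text("")
        paths[sample] = p
    return paths


def bundle_hash(outdir: str | Path) -> str:
    """SHA-256 over every file under ``outdir`` (sorted paths); determinism aid."""
    h = hashlib.sha256()
    for p in sorted(Path(outdir).rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(outdir)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()
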