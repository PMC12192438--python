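# Methods notes

## The pipeline's model of the data

The unit of observation is a (contig, sample) pair summarized by Q2Q3
coverage: the interquartile mean of the zero-filled per-base depth vector.
With contig length *L* and *k* = ⌊*L*/4⌋, the statistic is the mean of
sorted depths at ranks *k* … *L*−*k*−1 (0-based). Trimming is *rank-based*
on positions, not value-quantile based: it is deterministic, needs no
interpolation, and gives the exact breadth rule that a contig covered on
≤ *k* positions scores 0. For *L* < 4 trimming is undefined and the plain
mean is used. Q2Q3 is scale-equivariant (q2q3(c·d) = c·q2q3(d)) and bounded
by min and max depth, properties the test suite asserts.

Detection is Q2Q3 > 0, with no additional minimum-breadth flag: the breadth
requirement (> ~25% of positions covered) is already implied by the
trimming. Normalization is column-wise (per sample), either to sum 1 or to
max 1; all-zero columns pass through unchanged so degenerate samples never
produce NaNs, and normalization preserves the zero pattern, so detection
commutes with it.

Depth files follow the `samtools depth` three-column dialect (contig,
1-based position, depth), no header, zero rows omissible. Consumers always
zero-fill against the catalog length; a position beyond the catalog length
is an error naming the offending sample.

## Marker screening and taxonomy

Contigs are admitted to the NCLDV catalog by carrying ≥ 1 of the five
canonical core genes (A32, PolB, VLTF3, MCP, SFII; names matched
case-insensitively with common synonyms). Genome bins pass the
quality gate at ≥ 4 of 5. Contigs whose only hits are non-canonical are
excluded — the five-gene vocabulary is the catalog's definition.

Species assignment from marker hits is deliberately conservative and fully
deterministic: hits below 30% identity (configurable) are discarded, the
taxon with the most marker hits wins, ties break by higher mean identity
and then lexicographically. Best-hit and LCA schemes are defensible
alternatives; majority voting was chosen because it is order-independent
and robust to a single spurious high-identity hit. Raising the identity
threshold can only move contigs toward NOVEL, never away — a property test
guards this monotonicity.

## Transport, origin and pulses

Transported ⇔ detected in ≥ 1 of the trap samples. "Depth of origin" is
not a mechanistic quantity; it is operationalized as the argmax over
planktonic depths of the time-averaged sum-to-one relative abundance, with
ties resolved shallower, and the shallowest detection depth emitted
alongside so users can choose either reading. Trap samples never contribute
to origin (origin is a water-column concept), and trap-only contigs are
flagged rather than forced onto the grid.

The export-pulse rule is a fixed multiplicative threshold — flux ≥ 1.5 ×
the long-term baseline mean, boundary inclusive — and is invariant under a
common rescaling of flux and baseline, so the flux units only need to be
internally consistent.

## Flux correlation

Gene significance is plain Pearson correlation of trap-sample relative
abundance with flux, p from the exact t transform on n−2 df. The input is
per-sample sum-to-one normalized trap coverage. Constant rows (including
the all-zero rows of never-transported contigs) are flagged and excluded
from selection rather than given arbitrary statistics. The default
selection rule is per-contig r > 0, p < .05 with *raw* p-values; this is a
deliberately liberal screen in keeping with how such population sets are
usually reported, and Benjamini–Hochberg is available behind a flag for
users who want FDR control.

The co-abundance module stage is a compact reimplementation of the weighted
correlation-network recipe: unsigned adjacency |cor|^β (β = 6 default),
topological-overlap similarity, average-linkage clustering of 1−TOM, a
static cut at a fixed dendrogram height, modules below min_module_size
(default 5) left unassigned ("grey"). Eigengenes are the first principal
component of the standardized member profiles (via SVD), sign-oriented so
the mean member correlation is positive. Determinism: contigs are processed
in sorted-id order and modules named M1, M2, … by decreasing size then
smallest member id, so labels are invariant to input order. The default
static cut (0.25) suits tightly correlated blocks; field-like noisy
profiles sit at much larger 1−TOM distances, and the analysis drivers pass
a looser cut (0.95) when they want modules out of noisy data. Module gating
is off by default: the per-contig positive-correlation rule is the primary
selection; the gate reproduces the network-analysis framing when enabled.

## The synthetic generator

`synthio` emulates the sampling design the analysis targets: a 15-depth
planktonic grid (5–4000 m) sampled monthly, a 63-sample sediment-trap block
with a particulate flux series, ~1500 cataloged contigs, ~31% of them
planted as transported and ~7% as flux-coupled, ~21% taxonomically
identifiable. Its structural choices:

- **Depth niche**: each contig's expected coverage is Gaussian in
  log10(depth) (center uniform over the grid span, width 0.15–0.45 log10
  units, lognormal amplitude around 50×), reproducing
  epipelagic/DCM/mesopelagic peak structure. Values below a floor (0.5×)
  are zeroed so contigs are detected only in a band around their niche.
- **Noise**: multiplicative lognormal (σ = 0.3 default) — coverage is
  positive and heavy-tailed; additive Gaussian noise would produce negative
  values and the wrong tail.
- **Flux series**: baseline × (1 + 0.25·sin(2π·month/12)) × lognormal(0.08),
  with designated summer months (Jul–Sep) redrawn at 1.6–2.2 × baseline so
  both pulse and non-pulse samples are guaranteed to exist.
- **Coupling**: flux-coupled contigs' trap coverage is
  baseline × max(0, 1 + effect × z) × noise, with z the standardized flux;
  the clip at 0 keeps coverage non-negative when effect × z < −1.
- **Per-base realization**: a covered cell is a constant integer depth over
  a contiguous covered prefix (breadth 0.6–1.0 of the contig for planktonic
  samples, full breadth in traps). Q2Q3 of such a profile has a closed
  form, which is what the in-memory coverage matrix stores — so depth files
  round-trip *exactly* through the coverage module, and the planted
  transported set is recovered verbatim by construction, not approximately.
- **Seeding**: one global seed; every component and every sample draws from
  a `SeedSequence` spawn key, so identical configs are byte-identical on
  disk and extending the campaign by months reuses the exact draws of the
  shared planktonic samples (trap samples are re-dated across the window,
  so flux-coupled trap values legitimately change).

What the generator does *not* emulate: assembly artifacts and chimeras,
strain-level coverage heterogeneity along a contig (per-cell depth is
constant), compositional coupling between contigs sharing hosts,
autocorrelated seasonality in the planktonic niches, and read-level
processes (no sequences or FASTQ are produced). Tests passing on this
generator therefore validate the *statistical machinery* — trimming,
normalization, detection logic, correlation calibration — not the
upstream bioinformatics of real metagenomes.

## Problem sizes and numerical choices

Statistical checks (null calibration, planted recovery) run in memory at
1000 contigs × 63 trap samples; serialization-heavy end-to-end runs use
60–150 contigs of 200–1200 bp over 12 months, sizes at which a full
simulate → write → parse → analyze cycle completes in seconds while still
exercising every code path. Null calibration uses frac_transported = 1 so
all 1000 contigs contribute non-constant rows to the null rate.

Degenerate inputs are handled explicitly rather than by NaN propagation:
empty depth vectors, all-zero sample columns, constant abundance rows,
all-constant co-abundance matrices, traps without flux rows, and catalogs
with a single depth each have a defined behavior and a test.

## Known limitations

- The taxonomy rule is a stand-in for phylogenetic placement; it assigns
  the best-supported reference species, not a clade.
- Depth of origin assumes the time-averaged profile is unimodal on the
  grid; broad or bimodal niches land on one of their peaks.
- Gene significance assumes an approximately linear abundance–flux
  relationship on the relative-abundance scale and n large enough for the
  t approximation (the permutation cross-check in the tests guards the
  calibration at the sizes used).
- The module stage exposes β, cut height and minimum size but does not
  auto-select the soft threshold or implement dynamic tree cutting.
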