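"""Shared paths and the study-scale configuration for the analysis scripts.

The campaign bundle (per-base depth files and all input tables) lives under
scratch/ because the serialized depth files are large; the small summary
tables each script derives go under results/.
"""

from pathlib import Path

from gvshuttle.synthio import SimConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
BUNDLE_DIR = SCRATCH / "bundle"
RESULTS = ROOT / "results"

# One simulated year on the 15-depth grid with the full 63-trap block.
# Contig count and lengths are scaled down so depth-file serialization stays
# in seconds; planted fractions keep the catalog-level proportions
# (~31% transported, ~7% flux-coupled, ~21% identifiable).
CAMPAIGN = SimConfig(seed=11, n_contigs=150, n_months=12,
                     contig_length_range=(300, 1200))


def ensure_dirs() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
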