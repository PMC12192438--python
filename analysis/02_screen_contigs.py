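"""Curate the NCLDV catalog: marker screen, GVMAG quality rule, taxonomy.

Reads the marker hit table, keeps contigs with at least one canonical marker,
flags the genome-quality subset (>= 4 of 5 markers) and assigns species-level
taxonomy or NOVEL. Writes a per-taxon census to results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

import pandas as pd  # noqa: E402

from gvshuttle.markers import gvmag_quality, screen_contigs, taxonomy_table  # noqa: E402


def main() -> None:
    common.ensure_dirs()
    hits = pd.read_csv(common.BUNDLE_DIR / "markers.tsv", sep="\t")
    kept = screen_contigs(hits, min_markers=1)
    marker_sets = hits.groupby("contig_id")["marker"].apply(set)
    n_gvmag = sum(gvmag_quality(s) for s in marker_sets[kept])
    taxonomy = taxonomy_table(hits)

    census = taxonomy.value_counts().rename_axis("taxon").reset_index(name="n_contigs")
    census.to_csv(common.RESULTS / "taxon_census.tsv", sep="\t", index=False)

    n_id = int((taxonomy != "NOVEL").sum())
    print(f"{len(kept)} contigs pass the marker screen; "
          f"{n_gvmag} carry >= 4/5 markers (genome-quality); "
          f"{n_id} ({100 * n_id / len(kept):.1f}%) taxonomically identified")
    print(census.head(8).to_string(index=False))


if __name__ == "__main__":
    main()
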