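"""Depth distribution of auxiliary metabolic gene (AMG) carriers.

For each AMG category, computes the abundance-weighted proportion of the
community carrying it per sample, then averages through time at each depth
(mean ± SE). The generator biases photosynthesis genes toward shallow-niche
contigs and ammonium transporters toward deep ones, so the profiles should
separate by depth.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

import pandas as pd  # noqa: E402

from gvshuttle.coverage import CoverageTable, NormMode, normalize  # noqa: E402
from gvshuttle.profiles import amg_depth_profiles  # noqa: E402


def main() -> None:
    common.ensure_dirs()
    table = CoverageTable.from_tsv(common.SCRATCH / "coverage_q2q3.tsv")
    metadata = pd.read_csv(common.BUNDLE_DIR / "metadata.tsv", sep="\t")
    amg = pd.read_csv(common.BUNDLE_DIR / "amg.tsv", sep="\t")

    rel = normalize(table, NormMode.SUM_TO_ONE)
    prof = amg_depth_profiles(rel, amg, metadata)
    prof.to_csv(common.RESULTS / "amg_profiles.tsv", sep="\t", index=False)

    peaks = prof.loc[prof.groupby("amg_category")["mean"].idxmax(),
                     ["amg_category", "depth_m", "mean"]]
    print("abundance-weighted AMG carrier proportion peaks:")
    print(peaks.to_string(index=False))


if __name__ == "__main__":
    main()
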