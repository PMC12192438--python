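import pytest

from gvshuttle.synthio import SimConfig, simulate


@pytest.fixture(scope="session")
def small_config():
    # one simulated year, 63 traps, short contigs: fast to serialize
    return SimConfig(
        seed=3, n_contigs=60, n_months=12, contig_length_range=(200, 800)
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def written_bundle(small_bundle, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    paths = small_bundle.write(outdir)
    return small_bundle, outdir, paths
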