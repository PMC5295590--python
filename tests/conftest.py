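import pytest

from evilmap.pipeline import map_dataset
from evilmap.simulate import SimParams, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default study design (5 Mb, 100 genes, five lines), seed 1."""
    return simulate_dataset(SimParams(), seed=1)


@pytest.fixture(scope="session")
def default_report(default_dataset):
    ds = default_dataset
    return map_dataset(
        ds.manifest,
        ds.genome,
        ds.genes,
        ds.calls,
        ds.counts,
        indel_sites=ds.truth.indel_sites,
    )


@pytest.fixture(scope="session")
def small_params():
    """A fast, reduced design for tests that only need structure."""
    return SimParams(
        n_chroms=1,
        chrom_length_bp=400_000,
        n_genes=12,
        n_error_prone=10,
        n_shared_background=10,
        n_indel_sites=15,
    )


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return simulate_dataset(small_params, seed=11)
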