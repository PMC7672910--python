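import pytest

from pmlseq.model import VariantCall
from pmlseq.synthetic_data import GenomeModel, SimulationConfig, simulate_cohort


@pytest.fixture
def make_variant():
    """Factory for VariantCall records with sensible defaults."""

    def _make(chrom="chr1", pos=100, ref="A", alt="T", **kwargs):
        return VariantCall(chrom=chrom, pos=pos, ref=ref, alt=alt, **kwargs)

    return _make


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale simulation shared by read-only tests."""
    return SimulationConfig(seed=11, n_artifacts=1000)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return GenomeModel(small_config)
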