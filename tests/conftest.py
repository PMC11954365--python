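import numpy as np
import pytest
from hypothesis import settings

from chromtriad.genomic_core import GenomicInterval, Peak
from chromtriad.synthetic_data import SimulationConfig

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_sim_config():
    """Scaled-down study design for fast unit/integration tests."""
    return SimulationConfig(
        seed=11,
        n_chroms=2,
        chrom_length=400_000,
        n_genes=60,
        n_per_category=5,
        n_bound_unresolved_per_direction=2,
        n_unbound_de_per_direction=3,
        n_bound_atac_only_per_direction=2,
        n_unbound_atac_only_per_direction=2,
        n_bound_quiet=8,
        reads_per_sample=30_000,
    )


def iv(chrom, start, end, strand="."):
    return GenomicInterval(chrom, start, end, strand)


def pk(chrom, start, end, **kw):
    return Peak(interval=GenomicInterval(chrom, start, end), **kw)


@pytest.fixture
def make_interval():
    return iv


@pytest.fixture
def make_peak():
    return pk
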