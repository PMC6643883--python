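import numpy as np
import pytest

from tetradkit.genotype_io import GenotypeMatrix, MarkerMap, default_centromeres
from tetradkit.sim_meiosis import SimConfig, simulate


def matrix_from_calls(calls, chrom="chr1", positions=None, spore_ids=None):
    """Build a GenotypeMatrix from a raw spores x markers int array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_spores, n_markers = calls.shape
    if positions is None:
        positions = np.arange(1, n_markers + 1)
    markers = MarkerMap(
        ids=[f"{chrom}:{p}" for p in positions],
        chromosomes=np.array([chrom] * n_markers, dtype=object),
        positions=np.asarray(positions, dtype=np.int64),
    )
    if spore_ids is None:
        spore_ids = [f"s{i}" for i in range(n_spores)]
    return GenotypeMatrix(spore_ids=spore_ids, markers=markers, calls=calls)


@pytest.fixture(scope="session")
def centromeres():
    return default_centromeres()


@pytest.fixture(scope="session")
def clean_sim():
    """Noise-free 20-tetrad simulation shared across tests."""
    return simulate(
        SimConfig(n_tetrads=20, n_markers=400, noise_rate=0.0, missing_rate=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def noisy_sim():
    """The flagship simulated regime: 1% noise, 5% missing."""
    return simulate(
        SimConfig(n_tetrads=20, n_markers=400, noise_rate=0.01, missing_rate=0.05, seed=11)
    )
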