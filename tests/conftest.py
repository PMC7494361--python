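import numpy as np
import pandas as pd
import pytest

from meiohot.coverage import CoverageTrack
from meiohot.simulate import (SimulationConfig, simulate_genome_and_coverage,
                              simulate_protein_family)


@pytest.fixture(scope="session")
def protein_family():
    """Default-condition protein family (100 species, 20% decoys)."""
    return simulate_protein_family(SimulationConfig(seed=3))


@pytest.fixture(scope="session")
def genome_sim():
    """Default-condition WT genome simulation."""
    return simulate_genome_and_coverage(SimulationConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def flat_tracks():
    """Deterministic constant coverage: IP == control everywhere."""
    arr = np.full(20_000, 2.0)
    return (CoverageTrack({"1": arr.copy()}), CoverageTrack({"1": arr.copy()}))


@pytest.fixture()
def toy_regions():
    return pd.DataFrame({
        "chrom": ["1", "1", "1"],
        "center": [5_000, 9_000, 15_000],
        "strand": ["+", "-", "+"],
    })
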