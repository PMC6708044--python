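import numpy as np
import pytest

from hifmap.genetics import GeneticMap, Marker


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def small_map():
    """One chromosome, 9 markers, 12.5 cM spacing (Haldane cM)."""
    markers = [
        Marker(f"M{j}", "1A", 1_000_000 + j * 10_000_000, pos_cM=j * 12.5)
        for j in range(9)
    ]
    return GeneticMap(markers=markers, map_function="haldane")


@pytest.fixture
def two_marker_map():
    markers = [
        Marker("L", "1A", 1_000_000, pos_cM=0.0),
        Marker("R", "1A", 51_000_000, pos_cM=50.0),
    ]
    return GeneticMap(markers=markers, map_function="haldane")
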