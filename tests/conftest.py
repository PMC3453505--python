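import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from aimsel.io_formats import GenotypeMatrix, PopulationLabels
from aimsel.synthetic import SimulationConfig, simulate_dataset


@pytest.fixture
def two_pop_labels():
    return PopulationLabels(
        [f"s{i}" for i in range(8)],
        ["CHB"] * 4 + ["JPT"] * 4,
    )


@pytest.fixture
def tiny_genotypes():
    """4 samples x 3 markers; marker m3 sits on chrX."""
    calls = np.array(
        [
            [0, 1, 0],
            [0, 1, 1],
            [2, -1, 1],
            [2, 1, 2],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        ["s0", "s1", "s2", "s3"],
        ["m1", "m2", "m3"],
        calls,
        np.array(["1", "2", "X"], dtype=object),
    )


@pytest.fixture
def planted_dataset():
    """Two populations (30+30) with one fixed-difference SNP among noise."""
    cfg = SimulationConfig(
        populations=[("P1", 30), ("P2", 30)],
        n_noise_snps=40,
        n_info_snps=1,
        info_snp_freqs=np.array([[0.0, 1.0]]),
        n_noise_ge=20,
        n_info_ge=0,
        seed=11,
    )
    return simulate_dataset(cfg)
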