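import numpy as np
import pandas as pd
import pytest

from ssgcn import SimulationConfig, PlantedBlock, SurvivalParams, generate_annotation


@pytest.fixture
def small_config():
    """2 chromosomes x 4 genes, 2 cytobands each."""
    return SimulationConfig(
        n_genes=8,
        chromosome_sizes=(4, 4),
        cytobands_per_chromosome=2,
        n_samples=20,
        seed=7,
    )


@pytest.fixture
def block_config():
    """60 genes with a planted 30-gene block at rho = 0.8, 500 samples."""
    return SimulationConfig(
        n_genes=60,
        chromosome_sizes=(30, 30),
        cytobands_per_chromosome=1,
        n_samples=500,
        planted_blocks=(PlantedBlock("1", "1p11", 30, 0.8),),
        seed=11,
    )


@pytest.fixture
def toy_annotation():
    """Hand-built annotation: chr8 (two cytobands) and chr17 (one)."""
    return pd.DataFrame(
        {
            "chromosome": ["8", "8", "8", "8", "17", "17"],
            "cytoband": ["8q24.3", "8q24.3", "8q24.3", "8p11.23", "17q11.2", "17q11.2"],
            "start": [1, 100, 200, 300, 1, 100],
            "end": [50, 150, 250, 350, 50, 150],
            "gc_fraction": [0.5] * 6,
            "length": [50] * 6,
        },
        index=pd.Index(["A", "B", "C", "D", "E", "F"], name="gene_id"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
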