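import numpy as np
import pandas as pd
import pytest

from devcomp.expression import ExpressionMatrix
from devcomp.simulate import (
    HeterochronySpec,
    SimulationConfig,
    SpeciesSpec,
    simulate_dataset,
)

STAGES4 = ["S01", "S02", "S03", "S04"]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tpm_matrix():
    """Small 5-gene x 4-stage TPM matrix without replicates."""
    data = pd.DataFrame(
        {
            "S01": [0.0, 1.9, 2.0, 2.1, 50.0],
            "S02": [0.0, 1.0, 1.0, 1.0, 10.0],
            "S03": [0.0, 0.5, 0.1, 0.0, 5.0],
            "S04": [0.0, 1.5, 2.0, 0.3, 80.0],
        },
        index=["g_zero", "g_low", "g_edge", "g_peak", "g_high"],
    )
    return ExpressionMatrix("toy", data, "tpm", STAGES4)


@pytest.fixture
def replicate_matrix():
    """3 genes x 2 stages x 2 replicates, TPM layer."""
    data = pd.DataFrame(
        {
            "S01_r1": [2.0, 10.0, 0.0],
            "S01_r2": [4.0, 12.0, 0.0],
            "S02_r1": [6.0, 1.0, 3.0],
            "S02_r2": [8.0, 3.0, 5.0],
        },
        index=["g1", "g2", "g3"],
    )
    return ExpressionMatrix(
        "toy", data, "tpm", ["S01", "S02"],
        replicate_map={"S01": ["S01_r1", "S01_r2"], "S02": ["S02_r1", "S02_r2"]},
    )


@pytest.fixture(scope="session")
def two_species_bundle():
    """Small two-species dataset with planted heterochrony (session-wide)."""
    cfg = SimulationConfig(
        species=[
            SpeciesSpec("A", n_stages=8, n_replicates=2, n_specific=30, late_from=4),
            SpeciesSpec("B", n_stages=8, n_replicates=2, n_specific=30, late_from=4),
        ],
        n_orthologous=800,
        n_archetypes=4,
        archetype_peaks=[0 / 7, 2 / 7, 4 / 7, 6 / 7],  # integer stage ordinals
        archetype_width=0.12,
        heterochrony=HeterochronySpec(fraction=0.05, shift=4, species="B"),
        seed=2024,
    )
    return cfg, simulate_dataset(cfg)
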