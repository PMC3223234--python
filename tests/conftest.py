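import numpy as np
import pandas as pd
import pytest

from synergynet import (
    ExpressionDataset,
    PlantedPair,
    SimulationConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def planted_dataset() -> ExpressionDataset:
    """Mixed-pattern dataset: 2 gap, 1 substitute, 1 on/off pair + noise."""
    config = SimulationConfig(
        n_genes=20,
        n_samples_per_phenotype=30,
        planted_pairs=(
            PlantedPair("gap"),
            PlantedPair("gap"),
            PlantedPair("substitute"),
            PlantedPair("onoff"),
        ),
        n_redundant_genes=2,
        seed=42,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def null_dataset() -> ExpressionDataset:
    """Background-only dataset: no gene carries phenotype information."""
    return simulate_dataset(
        SimulationConfig(n_genes=30, n_samples_per_phenotype=20, seed=7)
    )


@pytest.fixture()
def tiny_dataset() -> ExpressionDataset:
    """Hand-built 3-gene dataset with transparent structure."""
    samples = [f"S{i}" for i in range(8)]
    values = pd.DataFrame(
        {
            s: col
            for s, col in zip(
                samples,
                np.array(
                    [
                        [1.0, 2.0, 3.0],
                        [1.1, 2.1, 3.1],
                        [0.9, 1.9, 2.9],
                        [1.2, 2.2, 3.2],
                        [5.0, 6.0, 7.0],
                        [5.1, 6.1, 7.1],
                        [4.9, 5.9, 6.9],
                        [5.2, 6.2, 7.2],
                    ]
                ),
            )
        },
        index=["gA", "gB", "gC"],
    )
    condition = pd.Series(
        ["BSA", "BSA", "PA", "PA", "PA", "PA", "OA", "OA"], index=samples
    )
    phenotype = pd.Series(
        ["nontoxic"] * 4 + ["toxic"] * 4, index=samples
    )
    return ExpressionDataset(values, condition, phenotype)
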