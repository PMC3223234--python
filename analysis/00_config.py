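"""Shared locations and study conditions for the analysis scripts.

The scripts run in order (01 → 07) and communicate through the files
under results/analysis/.  All of them accept --seed (default 0).
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "analysis" / "data"
OUT = ROOT / "results" / "analysis"

PERMUTATIONS = 200
ALPHA = 0.05

# the simulated cohort: a planted pathway whose hub gene cooperates with
# three members, one intra-pathway and one background cooperative pair,
# redundant (marginally shifted) genes, and a trend-structured background
PATHWAY_MEMBERS = tuple(f"G{i:04d}" for i in range(1, 7))
HUB = "G0015"


def cohort_config(seed: int):
    from synergynet import PathwaySpec, PlantedPair, SimulationConfig

    trend_background = {
        f"G{i:04d}": ("I", "II", "III", "IV")[i % 4] for i in range(20, 40)
    }
    return SimulationConfig(
        n_genes=40,
        n_samples_per_phenotype=30,
        planted_pairs=(
            PlantedPair("gap", genes=("G0004", "G0005")),
            PlantedPair("gap", genes=("G0010", "G0011")),
        ),
        n_redundant_genes=2,
        pathway_spec=(
            PathwaySpec("PLANTED", members=PATHWAY_MEMBERS, hub=HUB),
            PathwaySpec("DECOY", members=tuple(trend_background)[:5]),
        ),
        trend_assignment=trend_background,
        seed=seed,
    )
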