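"""Generate the simulated study cohort and write it as TSV/GMT fixtures.

Produces a phenotype-labelled expression matrix (toxic = palmitate
samples) with planted cooperative structure, plus the pathway
annotations, under results/analysis/data/.
"""

import argparse
import importlib.util
import sys
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "config", Path(__file__).parent / "00_config.py"
)
config = importlib.util.module_from_spec(spec)
spec.loader.exec_module(config)

from synergynet import simulate_dataset, write_fixture  # noqa: E402


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    ds = simulate_dataset(config.cohort_config(args.seed))
    paths = write_fixture(ds, ds.truth["gene_sets"], config.DATA)
    print(f"cohort: {ds.n_genes} genes x {ds.n_samples} samples")
    print(f"planted pairs: {[(p['gene1'], p['gene2']) for p in ds.truth['pairs']]}")
    print(f"pathway hub: {ds.truth['hubs']['PLANTED']}")
    for name, path in paths.items():
        print(f"wrote {name}: {path.relative_to(config.ROOT)}")


if __name__ == "__main__":
    sys.exit(main())
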