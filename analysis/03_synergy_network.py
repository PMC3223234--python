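"""Pairwise information synergy and the gene-cooperation network.

Scores every pair of selected genes, assesses significance by phenotype
permutation with BH control, classifies the significant pairs into
gap/substitute/on-off configurations, and writes the pair table, the
edge list and a SIF file under results/analysis/.
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

from synergynet import build_network, synergy_scan  # noqa: E402
from synergynet.io import read_expression, read_table, write_sif, write_table  # noqa: E402
from synergynet.network import annotate_patterns  # noqa: E402


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    ds = read_expression(config.DATA / "expression.tsv", config.DATA / "samples.tsv")
    report = read_table(config.OUT / "selection.tsv")
    selected = report[report["kept"]]["gene"].tolist()
    sub = ds.subset_genes(selected)

    results = synergy_scan(sub, B=config.PERMUTATIONS, seed=args.seed)
    net = build_network(results, alpha=config.ALPHA)
    results = annotate_patterns(results, sub, config.ALPHA)
    write_table(results, config.OUT / "synergy_pairs.tsv")
    edges = net.edge_table()
    write_table(edges, config.OUT / "network_edges.tsv")
    write_sif(edges, config.OUT / "network.sif")

    patterns = results[results["pattern"] != ""]["pattern"].value_counts().to_dict()
    print(
        f"tested {len(results)} pairs -> network of {len(net.nodes)} genes, "
        f"{net.n_edges} edges; patterns: {patterns}"
    )
    print(f"wrote {(config.OUT / 'network_edges.tsv').relative_to(config.ROOT)}")


if __name__ == "__main__":
    sys.exit(main())
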