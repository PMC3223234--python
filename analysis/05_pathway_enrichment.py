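"""Hypergeometric pathway over-representation among network genes.

Tests every annotated gene set against the selected-gene background and
writes results/analysis/enrichment.tsv.
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

from synergynet import build_network, enrich_pathways  # noqa: E402
from synergynet.io import read_gene_sets, read_table, write_table  # noqa: E402


def main() -> None:
    argparse.ArgumentParser().parse_args()
    pairs = read_table(config.OUT / "synergy_pairs.tsv")
    net = build_network(pairs, alpha=config.ALPHA)
    report = read_table(config.OUT / "selection.tsv")
    background = report[report["kept"]]["gene"].tolist()
    sets = read_gene_sets(config.DATA / "gene_sets.gmt")

    df = enrich_pathways(net.nodes, background, sets, alpha=config.ALPHA)
    write_table(df, config.OUT / "enrichment.tsv")
    for row in df.itertuples(index=False):
        flag = "significant" if row.significant else "ns"
        print(
            f"{row.pathway}: {row.n_in_network}/{row.n_in_background} in "
            f"network, p={row.p:.3g}, p_adj={row.p_adj:.3g} [{flag}]"
        )
    print(f"wrote {(config.OUT / 'enrichment.tsv').relative_to(config.ROOT)}")


if __name__ == "__main__":
    sys.exit(main())
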