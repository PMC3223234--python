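"""Pathway-neighbor association: rank the enriched pathways' neighbors.

For each significantly enriched pathway, tests every network gene
connected to >= 3 pathway members with the hypergeometric tail and
writes results/analysis/association.tsv.  The planted hub should top
the planted pathway's ranking.
"""

import argparse
import importlib.util
import sys
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "config", Path(__file__).parent / "00_config.py"
)
config = importlib.util.module_from_spec(spec)
spec.loader.exec_module(config)

from synergynet import associate_neighbors, build_network  # noqa: E402
from synergynet.io import read_gene_sets, read_table, write_table  # noqa: E402


def main() -> None:
    argparse.ArgumentParser().parse_args()
    pairs = read_table(config.OUT / "synergy_pairs.tsv")
    net = build_network(pairs, alpha=config.ALPHA)
    sets = read_gene_sets(config.DATA / "gene_sets.gmt")
    enrichment = read_table(config.OUT / "enrichment.tsv")

    frames = []
    for name in enrichment[enrichment["significant"]]["pathway"]:
        df = associate_neighbors(
            net, sets.members(name), min_connections=3, alpha=config.ALPHA
        )
        df.insert(0, "pathway", name)
        frames.append(df)
        for row in df.itertuples(index=False):
            print(
                f"{name} neighbor {row.gene}: {row.x}/{row.n} pathway links "
                f"at degree {row.k}, p={row.p:.3g}, p_adj={row.p_adj:.3g}, "
                f"rank {row.rank}"
            )
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["pathway", "gene", "x", "N", "n", "k", "p", "p_adj",
                     "rank", "significant"]
        )
    )
    write_table(out, config.OUT / "association.tsv")
    print(f"wrote {(config.OUT / 'association.tsv').relative_to(config.ROOT)}")


if __name__ == "__main__":
    sys.exit(main())
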