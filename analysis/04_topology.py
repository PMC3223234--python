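"""Degree distribution of the cooperation network vs a random graph.

Compares the inferred network's degree sequence with an Erdos-Renyi
G(n, m) graph of identical size via the two-sample KS statistic and
writes results/analysis/topology.tsv.
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

from synergynet import build_network, topology_report  # noqa: E402
from synergynet.io import read_table, write_table  # noqa: E402


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    pairs = read_table(config.OUT / "synergy_pairs.tsv")
    net = build_network(pairs, alpha=config.ALPHA)
    report = topology_report(net, seed=args.seed)
    df = pd.DataFrame(
        {"degree": report["degrees"], "er_degree": report["er_degrees"]}
    )
    df["ks_stat"] = report["ks_stat"]
    df["ks_p"] = report["ks_p"]
    write_table(df, config.OUT / "topology.tsv")
    print(
        f"network degree histogram {report['degree_hist']} vs "
        f"ER {report['er_degree_hist']}; KS={report['ks_stat']:.3f} "
        f"(p={report['ks_p']:.3g})"
    )
    print(f"wrote {(config.OUT / 'topology.tsv').relative_to(config.ROOT)}")


if __name__ == "__main__":
    sys.exit(main())
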