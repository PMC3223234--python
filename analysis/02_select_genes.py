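"""Trend-guided gene selection on the simulated cohort.

Matches per-condition mean expression to the four metabolite trends and
drops genes without differential expression between any two conditions;
writes the per-gene report to results/analysis/selection.tsv.
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

from synergynet import select_genes  # noqa: E402
from synergynet.io import read_expression, write_table  # noqa: E402


def main() -> None:
    argparse.ArgumentParser().parse_args()
    ds = read_expression(config.DATA / "expression.tsv", config.DATA / "samples.tsv")
    kept, report = select_genes(ds, alpha=config.ALPHA)
    write_table(report, config.OUT / "selection.tsv")
    by_trend = report[report["kept"]]["trend"].value_counts().to_dict()
    print(f"kept {len(kept)} / {ds.n_genes} genes; by trend: {by_trend}")
    print(f"wrote {(config.OUT / 'selection.tsv').relative_to(config.ROOT)}")


if __name__ == "__main__":
    sys.exit(main())
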