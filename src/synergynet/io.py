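"""Readers and writers for the pipeline's plain-text formats.

Expression matrices and sample metadata travel as TSV, gene sets as GMT
(set name, description, then member genes, tab-separated), networks as an
edge-list TSV plus a SIF-style file.  All writers emit a header row and
every output re-parses through this module losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, GeneSetCollection

__all__ = [
    "read_expression",
    "write_expression",
    "read_gene_sets",
    "write_gene_sets",
    "write_table",
    "read_table",
    "write_sif",
]

# expression values round-trip exactly; report tables use a compact format
FLOAT_FMT = "%.17g"
REPORT_FLOAT_FMT = "%.6g"


def read_expression(expr_path: str | Path, meta_path: str | Path) -> ExpressionDataset:
    """Read an expression TSV plus its sample-metadata TSV.

    The expression file has gene ids in the first column and one column
    per sample; the metadata file has columns sample_id, condition,
    phenotype.  Raises with the offending gene/sample/cell named on
    duplicate ids, metadata mismatches and malformed numbers.
    """
    expr_path, meta_path = Path(expr_path), Path(meta_path)
    raw = pd.read_csv(expr_path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"{expr_path}: duplicate gene id {dup!r}")
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            gene = raw.index[bad][0]
            raise ValueError(
                f"{expr_path}: malformed numeric cell at gene {gene!r}, "
                f"sample {col!r}: {raw.loc[gene, col]!r}"
            )
        if converted.isna().any():
            gene = raw.index[converted.isna()][0]
            raise ValueError(f"{expr_path}: missing value at gene {gene!r}, sample {col!r}")
    # numpy's string->float conversion is correctly rounded (pandas
    # to_numeric is not), so the %.17g writer round-trips bit-exactly
    values = raw.astype(float)
    values.index.name = None

    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    required = {"sample_id", "condition", "phenotype"}
    if not required.issubset(meta.columns):
        raise ValueError(
            f"{meta_path}: metadata must have columns {sorted(required)}"
        )
    meta = meta.set_index("sample_id")
    missing = values.columns.difference(meta.index)
    if len(missing):
        raise ValueError(f"{meta_path}: no metadata for sample {missing[0]!r}")
    extra = meta.index.difference(values.columns)
    if len(extra):
        raise ValueError(f"{meta_path}: metadata for unknown sample {extra[0]!r}")
    return ExpressionDataset(values, meta["condition"], meta["phenotype"])


def write_expression(
    dataset: ExpressionDataset, expr_path: str | Path, meta_path: str | Path
) -> None:
    expr_path, meta_path = Path(expr_path), Path(meta_path)
    out = dataset.values.copy()
    out.index.name = "gene"
    out.to_csv(expr_path, sep="\t", float_format=FLOAT_FMT)
    meta = pd.DataFrame(
        {
            "sample_id": dataset.sample_ids,
            "condition": dataset.condition.to_numpy(),
            "phenotype": dataset.phenotype.to_numpy(),
        }
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file; malformed or duplicate lines are rejected by number."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    first_line: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, needs >= 3"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in sets:
                raise ValueError(
                    f"{path}:{lineno}: duplicate gene-set name {name!r} "
                    f"(first defined on line {first_line[name]})"
                )
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
            first_line[name] = lineno
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(gene_sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in gene_sets.names:
            desc = gene_sets.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *gene_sets.members(name)]) + "\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV with a header (standard float format)."""
    df.to_csv(Path(path), sep="\t", index=False, float_format=REPORT_FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")


def write_sif(edges: pd.DataFrame, path: str | Path, relation: str = "syn") -> None:
    """SIF-style edge file: ``gene1 <relation> gene2`` per line."""
    with open(path, "w") as fh:
        for row in edges.itertuples(index=False):
            fh.write(f"{row.gene1}\t{relation}\t{row.gene2}\n")
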