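"""Core in-memory containers: expression datasets and gene-set collections.

An :class:`ExpressionDataset` holds a log2-scale expression matrix
(genes x samples) together with per-sample treatment condition and binary
phenotype labels.  A :class:`GeneSetCollection` holds named pathway
memberships as read from / written to GMT files.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

CONDITIONS = ("BSA", "PA", "OA")
PHENOTYPES = ("toxic", "nontoxic")


class ExpressionDataset:
    """Log2 expression matrix with condition and phenotype labels.

    Parameters
    ----------
    values:
        DataFrame of shape (n_genes, n_samples); index = gene ids,
        columns = sample ids.  Values are log2-scale expression.
    condition:
        Per-sample treatment label, indexed by sample id.
    phenotype:
        Per-sample phenotype class label, indexed by sample id.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        condition: pd.Series | Mapping[str, str],
        phenotype: pd.Series | Mapping[str, str],
    ) -> None:
        values = pd.DataFrame(values)
        condition = pd.Series(condition, dtype=object)
        phenotype = pd.Series(phenotype, dtype=object)

        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if values.isna().any().any():
            gene = values.index[values.isna().any(axis=1)][0]
            col = values.columns[values.isna().any(axis=0)][0]
            raise ValueError(f"missing value at gene {gene!r}, sample {col!r}")

        for name, labels in (("condition", condition), ("phenotype", phenotype)):
            missing = values.columns.difference(labels.index)
            if len(missing):
                raise ValueError(
                    f"sample {missing[0]!r} has no {name} label"
                )
            if labels.reindex(values.columns).isna().any():
                bad = labels.reindex(values.columns)
                raise ValueError(
                    f"sample {bad.index[bad.isna()][0]!r} has no {name} label"
                )

        self.values = values.astype(float)
        self.condition = condition.reindex(values.columns)
        self.phenotype = phenotype.reindex(values.columns)
        #: optional ground-truth annotation attached by the simulator
        self.truth: dict = {}

    # -- basic introspection -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def phenotype_indicator(self, positive: str = "toxic") -> np.ndarray:
        """Binary 0/1 vector over samples, 1 for the ``positive`` class."""
        return (self.phenotype.to_numpy() == positive).astype(np.int64)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy()

    def gene(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy()

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionDataset":
        ds = ExpressionDataset(
            self.values.loc[list(genes)], self.condition, self.phenotype
        )
        ds.truth = self.truth
        return ds

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionDataset):
            return NotImplemented
        return (
            self.values.equals(other.values)
            and self.condition.equals(other.condition)
            and self.phenotype.equals(other.phenotype)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionDataset({self.n_genes} genes x {self.n_samples} samples, "
            f"phenotypes={sorted(set(self.phenotype))})"
        )


class GeneSetCollection:
    """Ordered mapping of pathway name -> member genes (GMT semantics)."""

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]],
        descriptions: Mapping[str, str] | None = None,
    ) -> None:
        self._sets: dict[str, tuple[str, ...]] = {}
        for name, members in sets.items():
            members = tuple(dict.fromkeys(members))  # dedupe, keep order
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self._sets[name] = members
        self.descriptions = dict(descriptions or {})

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def members(self, name: str) -> tuple[str, ...]:
        return self._sets[name]

    def restrict(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets that empty out."""
        uni = set(universe)
        kept = {
            name: [g for g in members if g in uni]
            for name, members in self._sets.items()
        }
        kept = {name: m for name, m in kept.items() if m}
        return GeneSetCollection(kept, self.descriptions)

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> tuple[str, ...]:
        return self._sets[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._sets == other._sets

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GeneSetCollection({len(self)} sets)"
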