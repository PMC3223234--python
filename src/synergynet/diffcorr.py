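"""Differential-correlation network: the comparison baseline.

Edges are gene pairs whose within-phenotype correlation coefficients
differ significantly between the toxic and nontoxic classes, assessed by
the Fisher z two-sample test

    z = (atanh r_toxic - atanh r_nontoxic) / sqrt(1/(n1-3) + 1/(n2-3))

with a two-sided normal p-value and BH control across all pairs.  Unlike
the synergy score, this statistic never sees the phenotype labels jointly
with the expression - it only contrasts the two within-class correlation
structures - so cooperative pairs that shift the joint mean while leaving
within-class correlations untouched are invisible to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ExpressionDataset
from .network import SynergyNetwork
from .synergy import all_pairs, bh_adjust, _phenotype_to_binary

__all__ = ["DiffCorrResult", "diffcorr_test", "build_diffcorr_network"]

# Fisher z is undefined at |r| = 1; clip just inside
_R_CLIP = 1.0 - 1e-15
_P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class DiffCorrResult:
    gene1: str
    gene2: str
    r_toxic: float
    r_nontoxic: float
    z: float
    p: float


def _class_split(dataset: ExpressionDataset, positive: str = "toxic"):
    y = _phenotype_to_binary(dataset.phenotype.to_numpy())
    if positive not in set(dataset.phenotype):
        raise ValueError(f"phenotype class {positive!r} not present")
    pos = dataset.phenotype.to_numpy() == positive
    return np.flatnonzero(pos), np.flatnonzero(~pos)


def _fisher_z(r1: np.ndarray, r2: np.ndarray, n1: int, n2: int):
    z1 = np.arctanh(np.clip(r1, -_R_CLIP, _R_CLIP))
    z2 = np.arctanh(np.clip(r2, -_R_CLIP, _R_CLIP))
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), _P_FLOOR)
    return z, p


def diffcorr_test(g1, g2, phenotype) -> DiffCorrResult:
    """Fisher z test for a correlation difference between phenotypes."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    y = _phenotype_to_binary(phenotype)
    idx1, idx2 = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    for name, idx in (("first", idx1), ("second", idx2)):
        if idx.size <= 3:
            raise ValueError(
                f"{name} phenotype class has {idx.size} samples; need > 3"
            )
    for vec, label in ((g1, "g1"), (g2, "g2")):
        for idx, cls in ((idx1, "class 1"), (idx2, "class 0")):
            if vec[idx].std() == 0:
                raise ValueError(f"zero variance for {label} within {cls}")
    r1 = float(np.corrcoef(g1[idx1], g2[idx1])[0, 1])
    r2 = float(np.corrcoef(g1[idx2], g2[idx2])[0, 1])
    z, p = _fisher_z(np.array(r1), np.array(r2), idx1.size, idx2.size)
    return DiffCorrResult("g1", "g2", r1, r2, float(z), float(p))


def build_diffcorr_network(
    dataset: ExpressionDataset,
    alpha: float = 0.05,
    method: str = "pearson",
) -> tuple[SynergyNetwork, pd.DataFrame]:
    """Test all gene pairs and assemble the differential-correlation network.

    Returns the network (edges: BH-adjusted p < alpha) and the per-pair
    results table (gene1, gene2, r_toxic, r_nontoxic, z, p, p_adj).
    ``method`` is ``"pearson"`` or ``"spearman"`` (rank-transformed).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    idx_tox, idx_non = _class_split(dataset)
    n1, n2 = idx_tox.size, idx_non.size
    if min(n1, n2) <= 3:
        raise ValueError("need > 3 samples in each phenotype class")

    mat = dataset.matrix()
    if method == "spearman":
        mat = np.apply_along_axis(stats.rankdata, 1, mat)
    sub1, sub2 = mat[:, idx_tox], mat[:, idx_non]
    for name, sub in (("toxic", sub1), ("nontoxic", sub2)):
        sd = sub.std(axis=1)
        if (sd == 0).any():
            gene = dataset.gene_ids[int(np.flatnonzero(sd == 0)[0])]
            raise ValueError(
                f"gene {gene!r} has zero variance within the {name} class"
            )
    c1 = np.corrcoef(sub1)
    c2 = np.corrcoef(sub2)

    genes = dataset.gene_ids
    pair_list = all_pairs(genes)
    gi = {g: i for i, g in enumerate(genes)}
    ij = np.array([(gi[a], gi[b]) for a, b in pair_list])
    r1 = c1[ij[:, 0], ij[:, 1]]
    r2 = c2[ij[:, 0], ij[:, 1]]
    z, p = _fisher_z(r1, r2, n1, n2)
    p_adj = bh_adjust(p)

    results = pd.DataFrame(
        {
            "gene1": [a for a, _ in pair_list],
            "gene2": [b for _, b in pair_list],
            "r_toxic": r1,
            "r_nontoxic": r2,
            "z": z,
            "p": p,
            "p_adj": p_adj,
        }
    )
    import networkx as nx

    g = nx.Graph()
    sig = results[results["p_adj"] < alpha]
    for row in sig.itertuples(index=False):
        g.add_edge(row.gene1, row.gene2, z=float(row.z), p_adj=float(row.p_adj))
    return SynergyNetwork(g, alpha), results
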