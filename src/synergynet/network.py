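"""Gene-cooperation network assembly, joint-pattern taxonomy, topology.

Edges of the synergy network are gene pairs with positive synergy that
survive the permutation test at the chosen BH-adjusted level.  Each
positive pair can be classified into one of the three joint-expression
configurations seen in synergistic pairs:

gap
    genes positively correlated; phenotype separates along the
    difference axis (G1 - G2);
substitute
    genes negatively correlated; phenotype separates along the sum axis;
on/off
    a joint silent state versus a dispersed active state.

The topology report contrasts the network's degree distribution with an
Erdos-Renyi G(n, m) graph of identical size, summarised by a two-sample
Kolmogorov-Smirnov statistic on the degree sequences.
"""

from __future__ import annotations

from collections.abc import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .synergy import DegeneratePhenotypeError, _phenotype_to_binary

__all__ = [
    "SynergyNetwork",
    "build_network",
    "classify_pattern",
    "topology_report",
]


class SynergyNetwork:
    """Undirected graph of genes whose pairs show significant synergy."""

    def __init__(self, graph: nx.Graph, alpha: float) -> None:
        self.graph = graph
        self.alpha = alpha

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def neighbors(self, gene: str) -> set[str]:
        return set(self.graph.neighbors(gene))

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene1": min(u, v), "gene2": max(u, v), **data}
            for u, v, data in self.graph.edges(data=True)
        ]
        if not rows:
            return pd.DataFrame(columns=["gene1", "gene2", "syn", "p_adj"])
        df = pd.DataFrame(rows)
        return df.sort_values(["gene1", "gene2"], ignore_index=True)

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SynergyNetwork({self.graph.number_of_nodes()} genes, "
            f"{self.n_edges} edges, alpha={self.alpha})"
        )


def build_network(results: pd.DataFrame, alpha: float = 0.05) -> SynergyNetwork:
    """Assemble the cooperation network from a pair-results table.

    Edges are pairs with ``syn > 0`` and ``p_adj < alpha``; genes without
    any significant pair are excluded from the node set.  Raises on a
    duplicated unordered pair.
    """
    keys = [frozenset((a, b)) for a, b in zip(results["gene1"], results["gene2"])]
    if len(keys) != len(set(keys)):
        seen: set = set()
        for key in keys:
            if key in seen:
                raise ValueError(f"duplicate pair {tuple(sorted(key))}")
            seen.add(key)
    g = nx.Graph()
    sig = results[(results["syn"] > 0) & (results["p_adj"] < alpha)]
    for row in sig.itertuples(index=False):
        g.add_edge(row.gene1, row.gene2, syn=float(row.syn), p_adj=float(row.p_adj))
    return SynergyNetwork(g, alpha)


def classify_pattern(g1: np.ndarray, g2: np.ndarray, phenotype) -> str:
    """Classify a synergistic pair as ``"gap"``, ``"substitute"`` or ``"onoff"``.

    Decision rule, on per-gene standardized coordinates (z1, z2): compare
    the absolute two-sample t statistics of the phenotype along the
    difference axis (z1-z2)/sqrt(2), the sum axis (z1+z2)/sqrt(2), and the
    radial axis sqrt(z1^2+z2^2).  A radial separation dominating both
    linear axes is the hallmark of the joint silent/active configuration
    (on/off).  Otherwise the pair is a gap when the genes correlate
    positively (r >= 0 over all samples) and the difference axis dominates
    and discriminates (Welch p < 0.05), and a substitute when r < 0 and
    the sum axis dominates and discriminates; anything left is on/off.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    y = _phenotype_to_binary(phenotype)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise DegeneratePhenotypeError("need >= 2 samples per phenotype class")
    z1 = (g1 - g1.mean()) / g1.std() if g1.std() > 0 else np.zeros_like(g1)
    z2 = (g2 - g2.mean()) / g2.std() if g2.std() > 0 else np.zeros_like(g2)
    diff = (z1 - z2) / np.sqrt(2.0)
    total = (z1 + z2) / np.sqrt(2.0)
    radial = np.hypot(z1, z2)

    def axis_test(axis: np.ndarray) -> tuple[float, float]:
        res = stats.ttest_ind(axis[y == 1], axis[y == 0], equal_var=False)
        if not np.isfinite(res.statistic):
            return 0.0, 1.0
        return float(abs(res.statistic)), float(res.pvalue)

    t_diff, p_diff = axis_test(diff)
    t_sum, p_sum = axis_test(total)
    t_rad, _ = axis_test(radial)
    if g1.std() == 0 or g2.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(g1, g2)[0, 1])
    if t_rad > max(t_diff, t_sum):
        return "onoff"
    if r >= 0 and t_diff > t_sum and p_diff < 0.05:
        return "gap"
    if r < 0 and t_sum > t_diff and p_sum < 0.05:
        return "substitute"
    return "onoff"


def annotate_patterns(
    results: pd.DataFrame, dataset, alpha: float = 0.05
) -> pd.DataFrame:
    """Add a ``pattern`` column for significant positive-synergy pairs."""
    out = results.copy()
    patterns = []
    phen = dataset.phenotype.to_numpy()
    for row in out.itertuples(index=False):
        if row.syn > 0 and row.p_adj < alpha:
            patterns.append(
                classify_pattern(dataset.gene(row.gene1), dataset.gene(row.gene2), phen)
            )
        else:
            patterns.append("")
    out["pattern"] = patterns
    return out


def topology_report(net: SynergyNetwork, seed: int = 0) -> dict:
    """Degree histograms of the network and of one size-matched ER graph.

    Returns the two degree sequences, their histograms, and the two-sample
    KS statistic between them.  Raises on an empty network.
    """
    if net.n_edges == 0:
        raise ValueError("empty network")
    n = net.graph.number_of_nodes()
    m = net.n_edges
    er = nx.gnm_random_graph(n, m, seed=seed)
    deg = np.array(sorted(d for _, d in net.graph.degree()))
    er_deg = np.array(sorted(d for _, d in er.degree()))
    ks = stats.ks_2samp(deg, er_deg)

    def hist(d: np.ndarray) -> dict[int, int]:
        vals, counts = np.unique(d, return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    return {
        "degrees": deg,
        "er_degrees": er_deg,
        "degree_hist": hist(deg),
        "er_degree_hist": hist(er_deg),
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
    }
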