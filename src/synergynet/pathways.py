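"""Hypergeometric pathway enrichment and pathway-neighbor association.

Both tests use the upper hypergeometric tail

    P(X >= x) = sum_{i=x}^{min(n,k)} C(n,i) C(N-n, k-i) / C(N,k)

For enrichment: N = background universe size, n = pathway genes in the
background, k = network genes, x = pathway genes in the network.  For a
pathway-neighbor association: N = genes in the network, n = pathway genes
in the network, k = the neighbor's degree, x = pathway genes adjacent to
the neighbor.  Within each analysis p-values are Benjamini-Hochberg
adjusted (per pathway for neighbor associations).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import GeneSetCollection
from .network import SynergyNetwork
from .synergy import bh_adjust

__all__ = ["hypergeom_tail", "enrich_pathways", "associate_neighbors"]

log = logging.getLogger(__name__)


def hypergeom_tail(x: int, N: int, n: int, k: int) -> float:
    """Upper tail P(X >= x) of Hypergeometric(N, n, k).

    Probability that drawing ``k`` genes without replacement from ``N``,
    of which ``n`` belong to the pathway, yields at least ``x`` pathway
    genes.  Evaluated in log space by scipy for numerical stability.
    """
    x, N, n, k = int(x), int(N), int(n), int(k)
    if not (0 <= n <= N and 0 <= k <= N):
        raise ValueError(f"invalid parameters N={N}, n={n}, k={k}")
    if not 0 <= x <= min(n, k):
        raise ValueError(f"x={x} outside [0, min(n={n}, k={k})]")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, n, k))


def enrich_pathways(
    network_genes: Iterable[str],
    background_genes: Iterable[str],
    gene_sets: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of each gene set among the network genes.

    The background universe defaults (at the pipeline level) to the gene
    set entering the synergy analysis.  Gene sets that do not intersect
    the background are dropped with a log notice.  Returns one row per
    tested pathway: pathway, n_in_background, n_in_network, p, p_adj,
    significant; sorted by (p_adj, p, pathway).
    """
    network = set(network_genes)
    background = set(background_genes)
    stray = network - background
    if stray:
        raise ValueError(
            f"network gene {sorted(stray)[0]!r} absent from the background universe"
        )
    N = len(background)
    k = len(network)
    rows = []
    for name in gene_sets.names:
        members = set(gene_sets.members(name)) & background
        if not members:
            log.debug("gene set %r does not intersect the background; skipped", name)
            continue
        n = len(members)
        x = len(members & network)
        rows.append(
            {
                "pathway": name,
                "n_in_background": n,
                "n_in_network": x,
                "p": hypergeom_tail(x, N, n, k),
            }
        )
    df = pd.DataFrame(rows, columns=["pathway", "n_in_background", "n_in_network", "p"])
    if len(df):
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
        df["significant"] = df["p_adj"] < alpha
        df = df.sort_values(["p_adj", "p", "pathway"], ignore_index=True)
    else:
        df["p_adj"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


def associate_neighbors(
    net: SynergyNetwork,
    pathway_genes: Sequence[str],
    min_connections: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank the pathway's multiply-connected neighbor genes.

    Tested neighbors are the non-pathway network genes adjacent to at
    least ``min_connections`` pathway genes; each gets the hypergeometric
    tail with x = its pathway connections, N = network size, n = pathway
    genes in the network, k = its degree.  P-values are BH-adjusted across
    the tested neighbors of this pathway; rows are ranked by
    (p_adj, p, gene).
    """
    if net.n_edges == 0:
        raise ValueError("empty network")
    nodes = set(net.graph.nodes)
    in_net = [g for g in pathway_genes if g in nodes]
    absent = [g for g in pathway_genes if g not in nodes]
    if absent:
        log.info(
            "%d pathway gene(s) not in the network (e.g. %r); dropped",
            len(absent), absent[0],
        )
    pathway = set(in_net)
    N = len(nodes)
    n = len(pathway)
    degree = net.degree

    rows = []
    for gene in sorted(nodes - pathway):
        x = len(net.neighbors(gene) & pathway)
        if x >= min_connections:
            rows.append(
                {
                    "gene": gene,
                    "x": x,
                    "N": N,
                    "n": n,
                    "k": degree[gene],
                    "p": hypergeom_tail(x, N, n, degree[gene]),
                }
            )
    df = pd.DataFrame(rows, columns=["gene", "x", "N", "n", "k", "p"])
    if len(df):
        df["p_adj"] = bh_adjust(df["p"].to_numpy())
        df = df.sort_values(["p_adj", "p", "gene"], ignore_index=True)
        df["rank"] = np.arange(1, len(df) + 1)
        df["significant"] = df["p_adj"] < alpha
    else:
        df["p_adj"] = pd.Series(dtype=float)
        df["rank"] = pd.Series(dtype=int)
        df["significant"] = pd.Series(dtype=bool)
    return df
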