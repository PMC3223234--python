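"""Information synergy of gene pairs with respect to a binary phenotype.

For genes G1, G2 and phenotype P the synergy score is

    syn(G1, G2; P) = I(G1,G2; P) - I(G1; P) - I(G2; P)

with all mutual informations estimated from discretized expression states
and normalized by the phenotype entropy H(P), which places the score on a
[-1, 1] scale for binary phenotypes: positive scores mean the joint
expression carries more phenotype information than the two genes
individually (cooperation), negative scores mean the genes are redundant.

Marginal (1-D) expression states come from an exact minimum-variance
partition into ``n_states`` bins; joint (2-D) states come either from
k-means on the standardized pair (``method="cluster"``, ``n_states**2``
clusters) or from the product of the two marginal partitions
(``method="grid"``).  Statistical significance is assessed by permuting the
phenotype labels, with the same permutations reused for every pair, and
controlled by Benjamini-Hochberg FDR across pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from collections.abc import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._cluster import batched_kmeans, optimal_1d_labels
from .datasets import ExpressionDataset

__all__ = [
    "ContingencyTable",
    "SynergyEstimator",
    "mutual_information",
    "discretize",
    "synergy_score",
    "synergy_scan",
    "permutation_test",
    "bh_adjust",
    "all_pairs",
]

_COLLINEAR_TOL = 1e-12


class DegeneratePhenotypeError(ValueError):
    """Raised when the phenotype has a single class (H(P) = 0)."""


# ---------------------------------------------------------------------------
# contingency tables and mutual information
# ---------------------------------------------------------------------------

class ContingencyTable:
    """Joint counts of discretized expression states vs phenotype classes."""

    def __init__(self, counts: np.ndarray) -> None:
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D (states x phenotype classes)")
        if (counts < 0).any():
            raise ValueError("negative cell count")
        if counts.sum() <= 0:
            raise ValueError("empty table")
        self.counts = counts

    @classmethod
    def from_labels(
        cls, states: np.ndarray, phenotype: np.ndarray
    ) -> "ContingencyTable":
        states = np.asarray(states)
        phenotype = np.asarray(phenotype)
        s_codes, s_inv = np.unique(states, return_inverse=True)
        p_codes, p_inv = np.unique(phenotype, return_inverse=True)
        counts = np.zeros((s_codes.size, p_codes.size))
        np.add.at(counts, (s_inv, p_inv), 1.0)
        return cls(counts)

    @property
    def joint_freq(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @property
    def state_freq(self) -> np.ndarray:
        return self.joint_freq.sum(axis=1)

    @property
    def phenotype_freq(self) -> np.ndarray:
        return self.joint_freq.sum(axis=0)

    @property
    def phenotype_entropy(self) -> float:
        """H(P) in bits."""
        p = self.phenotype_freq
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum())


def mutual_information(table: ContingencyTable) -> float:
    """Plug-in mutual information of the table, in units of H(P).

    Computes sum_{g,p} f(g,p) * log2( f(g,p) / (f(g) f(p)) ) in bits and
    divides by the phenotype entropy, so a perfectly phenotype-determining
    discretization scores 1.  Raises for a single-class phenotype.
    """
    h_p = table.phenotype_entropy
    if h_p <= 0.0:
        raise DegeneratePhenotypeError("degenerate phenotype: H(P) = 0")
    f = table.joint_freq
    fg = table.state_freq[:, None]
    fp = table.phenotype_freq[None, :]
    mask = f > 0
    mi = float((f[mask] * np.log2(f[mask] / (fg * fp)[mask])).sum())
    return mi / h_p


def _mi_batch(states: np.ndarray, y: np.ndarray, n_states: int) -> np.ndarray:
    """Normalized MI for a batch of state vectors against binary labels.

    ``states``: (P, n) ints in [0, n_states); ``y``: (n,) ints in {0,1}.
    Vectorised equivalent of :func:`mutual_information` per row.
    """
    states = np.atleast_2d(states)
    P, n = states.shape
    flat = (np.arange(P)[:, None] * (2 * n_states) + states * 2 + y).ravel()
    counts = np.bincount(flat, minlength=P * n_states * 2).reshape(P, n_states, 2)
    f = counts / n
    fg = f.sum(axis=2, keepdims=True)
    fp = f.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = f * np.log2(f / (fg * fp))
    mi = np.where(f > 0, terms, 0.0).sum(axis=(1, 2))
    pp = f.sum(axis=1)  # (P, 2) phenotype freqs (identical across rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        hterms = np.where(pp > 0, -pp * np.log2(pp), 0.0)
    h_p = hterms.sum(axis=1)
    if np.any(h_p <= 0):
        raise DegeneratePhenotypeError("degenerate phenotype: H(P) = 0")
    return mi / h_p


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SynergyEstimator:
    """Configuration of the MI estimator.

    Parameters
    ----------
    method:
        ``"cluster"`` - joint states by k-means on the standardized pair
        into ``n_states**2`` clusters (10 restarts, seeded);
        ``"grid"`` - joint states as the product of the two marginal
        partitions.  Marginal states always use the exact 1-D partition.
    n_states:
        Number of marginal expression states per gene.
    seed:
        Seed for the k-means restarts (irrelevant for ``grid``).
    """

    method: str = "cluster"
    n_states: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("cluster", "grid"):
            raise ValueError(f"unknown estimator method {self.method!r}")
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")

    @property
    def n_joint_states(self) -> int:
        return self.n_states**2

    # -- marginal ------------------------------------------------------------
    def marginal_states(self, values: np.ndarray) -> np.ndarray:
        """1-D states for one gene (n,) or a gene matrix (G, n)."""
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            return optimal_1d_labels(values, self.n_states)
        return np.vstack([optimal_1d_labels(v, self.n_states) for v in values])

    # -- joint ---------------------------------------------------------------
    def joint_states_batch(
        self, g1: np.ndarray, g2: np.ndarray
    ) -> np.ndarray:
        """Joint states for batches of pairs; g1, g2 are (P, n) matrices."""
        g1 = np.atleast_2d(np.asarray(g1, dtype=float))
        g2 = np.atleast_2d(np.asarray(g2, dtype=float))
        P, n = g1.shape
        if n < self.n_states:
            raise ValueError(f"fewer samples ({n}) than states ({self.n_states})")

        if self.method == "grid":
            out = np.empty((P, n), dtype=np.int64)
            for i in range(P):
                b1 = optimal_1d_labels(g1[i], self.n_states)
                b2 = optimal_1d_labels(g2[i], self.n_states)
                out[i] = b1 * self.n_states + b2
            return out

        sd1 = g1.std(axis=1)
        sd2 = g2.std(axis=1)
        z1 = np.where(sd1[:, None] > 0, (g1 - g1.mean(1, keepdims=True)) / np.where(sd1 == 0, 1, sd1)[:, None], 0.0)
        z2 = np.where(sd2[:, None] > 0, (g2 - g2.mean(1, keepdims=True)) / np.where(sd2 == 0, 1, sd2)[:, None], 0.0)

        # a pair whose joint support is one-dimensional (duplicated or
        # perfectly linearly related genes) carries no second coordinate:
        # use the marginal-resolution 1-D partition of its principal axis,
        # so that I12 equals the marginal MI exactly.
        r = (z1 * z2).mean(axis=1)
        degenerate = (sd1 == 0) | (sd2 == 0) | (1.0 - np.abs(r) < _COLLINEAR_TOL)

        out = np.empty((P, n), dtype=np.int64)
        todo = ~degenerate
        if todo.any():
            X = np.stack([z1[todo], z2[todo]], axis=-1)
            out[todo] = batched_kmeans(
                X, self.n_joint_states, restarts=10, seed=self.seed
            )
        for i in np.where(degenerate)[0]:
            axis = z1[i] if sd1[i] > 0 else z2[i]
            out[i] = optimal_1d_labels(axis, self.n_states)
        return out

    def joint_states(self, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
        return self.joint_states_batch(g1[None, :], g2[None, :])[0]


def discretize(
    values,
    method: str = "cluster",
    n_states: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Assign discrete expression states to samples.

    ``values`` may be a single expression vector (1-D partition into at
    most ``n_states`` bins) or a pair of vectors (joint 2-D states, at most
    ``n_states**2``).  Deterministic for a fixed seed.
    """
    est = SynergyEstimator(method=method, n_states=n_states, seed=seed)
    if isinstance(values, (tuple, list)) and len(values) == 2:
        g1 = np.asarray(values[0], dtype=float)
        g2 = np.asarray(values[1], dtype=float)
        if g1.shape != g2.shape or g1.ndim != 1:
            raise ValueError("expected two equal-length 1-D vectors")
        if g1.size < n_states:
            raise ValueError(f"fewer samples ({g1.size}) than states ({n_states})")
        return est.joint_states(g1, g2)
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("expected one vector or a pair of vectors")
    if values.size < n_states:
        raise ValueError(f"fewer samples ({values.size}) than states ({n_states})")
    return est.marginal_states(values)


# ---------------------------------------------------------------------------
# synergy scores
# ---------------------------------------------------------------------------

def _phenotype_to_binary(phenotype) -> np.ndarray:
    y = np.asarray(phenotype)
    classes = np.unique(y)
    if classes.size < 2:
        raise DegeneratePhenotypeError("degenerate phenotype: single class")
    if classes.size > 2:
        raise ValueError(f"expected binary phenotype, got classes {classes}")
    return (y == classes[1]).astype(np.int64)


def synergy_score(
    g1: np.ndarray,
    g2: np.ndarray,
    phenotype,
    estimator: SynergyEstimator | None = None,
) -> tuple[float, float, float, float]:
    """Return (I1, I2, I12, syn) for one gene pair.

    I1, I2 come from the marginal partitions, I12 from the joint
    discretization; all normalized by H(P).  syn = I12 - I1 - I2.
    """
    est = estimator or SynergyEstimator()
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("expression vectors differ in length")
    y = _phenotype_to_binary(phenotype)
    s1 = est.marginal_states(g1)
    s2 = est.marginal_states(g2)
    s12 = est.joint_states(g1, g2)
    i1 = float(_mi_batch(s1, y, est.n_states)[0])
    i2 = float(_mi_batch(s2, y, est.n_states)[0])
    i12 = float(_mi_batch(s12, y, est.n_joint_states)[0])
    return i1, i2, i12, i12 - i1 - i2


def all_pairs(genes: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered gene pairs, in deterministic order."""
    return list(combinations(genes, 2))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _null_scores(
    s1_marg: np.ndarray,
    s12: np.ndarray,
    pair_idx: np.ndarray,
    y: np.ndarray,
    n_states: int,
    n_joint: int,
    B: int,
    rng: np.random.Generator,
    syn_obs: np.ndarray,
):
    """Permutation null synergy scores; returns per-pair and pooled counts.

    For each of B label permutations (shared across pairs) the synergy of
    every pair is recomputed from the fixed discretizations.  Returns
    ``count_ge`` (per pair: permuted scores >= observed) and
    ``pooled_ge`` (per pair: pooled scores over all pairs >= observed).
    """
    P = s12.shape[0]
    order = np.argsort(syn_obs, kind="mergesort")
    sorted_obs = syn_obs[order]
    count_ge = np.zeros(P, dtype=np.int64)
    pooled_hist = np.zeros(P + 1, dtype=np.int64)
    for _ in range(B):
        perm = rng.permutation(y.size)
        yb = y[perm]
        i1b = _mi_batch(s1_marg, yb, n_states)
        i12b = _mi_batch(s12, yb, n_joint)
        syn_b = i12b - i1b[pair_idx[:, 0]] - i1b[pair_idx[:, 1]]
        count_ge += syn_b >= syn_obs
        # each null score v contributes to every observed score <= v
        idx = np.searchsorted(sorted_obs, syn_b, side="right")
        pooled_hist += np.bincount(idx, minlength=P + 1)
    # suffix-sum: pooled count of nulls >= sorted_obs[r]
    pooled_sorted = pooled_hist[::-1].cumsum()[::-1][1:]  # length P

    # pooled_hist[j] counted nulls v with sorted_obs[j-1] <= v; nulls >=
    # sorted_obs[r] are those landing at index > r
    pooled_ge = np.empty(P, dtype=np.int64)
    pooled_ge[order] = pooled_sorted
    return count_ge, pooled_ge


def synergy_scan(
    dataset: ExpressionDataset,
    genes: Sequence[str] | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
    estimator: SynergyEstimator | None = None,
    B: int = 1000,
    seed: int = 0,
    null_model: str = "pooled",
) -> pd.DataFrame:
    """Score all gene pairs: synergy, permutation p, BH-adjusted p.

    Parameters
    ----------
    dataset:
        Phenotype-labelled expression data (two phenotype classes).
    genes / pairs:
        Restrict the scan; default is every unordered pair of all genes.
    B:
        Number of phenotype permutations (shared across pairs).
    null_model:
        ``"pooled"`` - each pair's p-value uses the null scores pooled over
        all pairs, resolution 1/(P*B+1); ``"per_pair"`` - classic per-pair
        empirical p = (1 + #{syn_b >= syn_obs}) / (B + 1).

    Returns
    -------
    DataFrame with columns gene1, gene2, I1, I2, I12, syn, p_raw, p_adj.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if null_model not in ("pooled", "per_pair"):
        raise ValueError(f"unknown null model {null_model!r}")
    est = estimator or SynergyEstimator()
    gene_list = list(genes) if genes is not None else dataset.gene_ids
    if pairs is None:
        pair_list = all_pairs(gene_list)
    else:
        pair_list = [tuple(p) for p in pairs]
    seen = set()
    for p in pair_list:
        key = frozenset(p)
        if key in seen:
            raise ValueError(f"duplicate pair {p}")
        seen.add(key)

    y = _phenotype_to_binary(dataset.phenotype.to_numpy())
    used_genes = sorted({g for p in pair_list for g in p})
    gidx = {g: i for i, g in enumerate(used_genes)}
    M = dataset.values.loc[used_genes].to_numpy()

    s1 = est.marginal_states(M)  # (G, n)
    pair_idx = np.array([(gidx[a], gidx[b]) for a, b in pair_list])
    s12 = est.joint_states_batch(M[pair_idx[:, 0]], M[pair_idx[:, 1]])

    i1 = _mi_batch(s1, y, est.n_states)
    i12 = _mi_batch(s12, y, est.n_joint_states)
    syn = i12 - i1[pair_idx[:, 0]] - i1[pair_idx[:, 1]]

    rng = np.random.default_rng(seed)
    count_ge, pooled_ge = _null_scores(
        s1, s12, pair_idx, y, est.n_states, est.n_joint_states, B, rng, syn
    )
    if null_model == "per_pair":
        p_raw = (1.0 + count_ge) / (B + 1.0)
    else:
        p_raw = (1.0 + pooled_ge) / (len(pair_list) * B + 1.0)

    return pd.DataFrame(
        {
            "gene1": [a for a, _ in pair_list],
            "gene2": [b for _, b in pair_list],
            "I1": i1[pair_idx[:, 0]],
            "I2": i1[pair_idx[:, 1]],
            "I12": i12,
            "syn": syn,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
        }
    )


def permutation_test(
    pairs: Sequence[tuple[str, str]],
    dataset: ExpressionDataset,
    B: int = 1000,
    seed: int = 0,
    estimator: SynergyEstimator | None = None,
    null_model: str = "per_pair",
) -> np.ndarray:
    """One-sided permutation p-values for the given pairs' synergy scores.

    With ``null_model="per_pair"`` (this function's default) the p-value is
    the classic smoothed empirical tail (1 + #{b: syn_b >= syn_obs})/(B+1)
    from the B shared permutations; ``"pooled"`` pools the null scores of
    all supplied pairs for finer resolution.
    """
    res = synergy_scan(
        dataset,
        pairs=pairs,
        estimator=estimator,
        B=B,
        seed=seed,
        null_model=null_model,
    )
    return res["p_raw"].to_numpy()
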