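"""Metabolite-trend-guided gene selection.

Genes enter the synergy analysis only if (i) their per-condition mean
expression follows one of four strict orderings across the BSA control,
palmitate and oleate treatments - the trends observed in the measured
metabolite profiles - and (ii) they are differentially expressed between
at least one pair of conditions (Welch two-sample t-test, p < alpha).

Trend codes over condition means (mBSA, mPA, mOA), all inequalities strict:

    I   : mBSA < mPA and mPA > mOA      (palmitate peak)
    II  : mBSA > mPA and mPA < mOA      (palmitate trough)
    III : mBSA < mPA < mOA              (monotone increase)
    IV  : mBSA > mPA > mOA              (monotone decrease)
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CONDITIONS, ExpressionDataset

__all__ = ["match_trend", "preprocess", "select_genes", "TREND_CODES"]

TREND_CODES = ("I", "II", "III", "IV")

_CONDITION_PAIRS = (("BSA", "PA"), ("PA", "OA"), ("BSA", "OA"))


def match_trend(means: Sequence[float]) -> str | None:
    """Match condition means (mBSA, mPA, mOA) to a trend code, or ``None``.

    The four predicates are mutually exclusive; any tie (non-strict
    inequality) fails every predicate and returns ``None``.
    """
    m_bsa, m_pa, m_oa = (float(m) for m in means)
    if not all(np.isfinite([m_bsa, m_pa, m_oa])):
        raise ValueError("condition means must be finite")
    if m_bsa < m_pa and m_pa > m_oa:
        return "I"
    if m_bsa > m_pa and m_pa < m_oa:
        return "II"
    if m_bsa < m_pa < m_oa:
        return "III"
    if m_bsa > m_pa > m_oa:
        return "IV"
    return None


def preprocess(
    raw: ExpressionDataset,
    probe_map: Mapping[str, Sequence[str]] | None = None,
    log2_transform: bool = False,
    drop_genes: Iterable[str] | None = None,
) -> ExpressionDataset:
    """Log2-transform, average probes per gene, drop unannotated genes.

    ``probe_map`` maps gene id -> probe row ids to be averaged (after the
    log transform); with ``None`` the rows are taken to be genes already.
    ``drop_genes`` is an optional blacklist (e.g. ESTs / hypothetical
    proteins) removed at the end.
    """
    values = raw.values
    if log2_transform:
        arr = values.to_numpy()
        if (arr <= 0).any():
            g, s = np.argwhere(arr <= 0)[0]
            raise ValueError(
                f"non-positive value at gene {values.index[g]!r}, "
                f"sample {values.columns[s]!r}: cannot log2-transform"
            )
        values = np.log2(values)

    if probe_map is not None:
        rows = {}
        for gene, probes in probe_map.items():
            missing = [p for p in probes if p not in values.index]
            if missing:
                raise ValueError(f"gene {gene!r}: unknown probe {missing[0]!r}")
            rows[gene] = values.loc[list(probes)].mean(axis=0)
        values = pd.DataFrame(rows).T
        values.columns = raw.values.columns

    if drop_genes is not None:
        drop = set(drop_genes)
        values = values.loc[[g for g in values.index if g not in drop]]

    return ExpressionDataset(values, raw.condition, raw.phenotype)


def select_genes(
    ds: ExpressionDataset, alpha: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Keep genes that match a trend and are differentially expressed.

    A gene is kept iff its condition means follow one of the four strict
    trends and at least one of the three pairwise Welch t-tests between
    conditions has p < alpha.  Returns the kept gene list and a per-gene
    report (means, matched trend, the three p-values, kept flag).
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    cond = ds.condition.to_numpy()
    groups = {}
    for c in CONDITIONS:
        idx = np.flatnonzero(cond == c)
        if idx.size < 2:
            raise ValueError(f"condition {c!r} has {idx.size} samples; need >= 2")
        groups[c] = idx

    mat = ds.matrix()
    means = {c: mat[:, groups[c]].mean(axis=1) for c in CONDITIONS}

    pvals = {}
    for a, b in _CONDITION_PAIRS:
        res = stats.ttest_ind(
            mat[:, groups[a]], mat[:, groups[b]], axis=1, equal_var=False
        )
        p = np.asarray(res.pvalue, dtype=float)
        # a gene constant in both groups has an undefined statistic: treat
        # as no evidence of differential expression
        pvals[(a, b)] = np.where(np.isfinite(p), p, 1.0)

    records = []
    kept = []
    for i, gene in enumerate(ds.gene_ids):
        trend = match_trend((means["BSA"][i], means["PA"][i], means["OA"][i]))
        ps = [pvals[pair][i] for pair in _CONDITION_PAIRS]
        keep = trend is not None and min(ps) < alpha
        if keep:
            kept.append(gene)
        records.append(
            {
                "gene": gene,
                "mBSA": means["BSA"][i],
                "mPA": means["PA"][i],
                "mOA": means["OA"][i],
                "trend": trend or "",
                "p_BSA_PA": ps[0],
                "p_PA_OA": ps[1],
                "p_BSA_OA": ps[2],
                "kept": keep,
            }
        )
    return kept, pd.DataFrame.from_records(records)
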