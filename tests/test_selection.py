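"""Trend matching, preprocessing, and differential-expression filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from synergynet import (
    ExpressionDataset,
    SimulationConfig,
    match_trend,
    preprocess,
    select_genes,
    simulate_dataset,
)
from synergynet.selection import TREND_CODES


def _make_dataset(values: np.ndarray, cond: list[str]) -> ExpressionDataset:
    samples = [f"S{i}" for i in range(values.shape[1])]
    phen = ["toxic" if c == "PA" else "nontoxic" for c in cond]
    return ExpressionDataset(
        pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                     columns=samples),
        pd.Series(cond, index=samples),
        pd.Series(phen, index=samples),
    )


class TestMatchTrend:
    @pytest.mark.parametrize(
        "means,expected",
        [
            ((1.0, 2.0, 3.0), "III"),  # monotone increase
            ((1.0, 3.0, 2.0), "I"),    # palmitate peak
            ((3.0, 1.0, 2.0), "II"),   # palmitate trough
            ((3.0, 2.0, 1.0), "IV"),   # monotone decrease
            ((2.0, 2.0, 3.0), None),   # tie fails every strict ordering
            ((2.0, 2.0, 2.0), None),
        ],
    )
    def test_examples(self, means, expected):
        assert match_trend(means) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            match_trend((np.nan, 1.0, 2.0))

    @given(
        st.tuples(
            st.floats(-10, 10, allow_nan=False),
            st.floats(-10, 10, allow_nan=False),
            st.floats(-10, 10, allow_nan=False),
        )
    )
    @settings(deadline=None, max_examples=200, derandomize=True)
    def test_predicates_mutually_exclusive(self, means):
        """At most one trend predicate can hold; the match obeys it."""
        m_bsa, m_pa, m_oa = means
        predicates = {
            "I": m_bsa < m_pa and m_pa > m_oa,
            "II": m_bsa > m_pa and m_pa < m_oa,
            "III": m_bsa < m_pa < m_oa,
            "IV": m_bsa > m_pa > m_oa,
        }
        holders = [c for c, ok in predicates.items() if ok]
        assert len(holders) <= 1
        got = match_trend(means)
        assert got == (holders[0] if holders else None)
        assert got in (*TREND_CODES, None)


class TestPreprocess:
    def test_probe_averaging(self):
        ds = _make_dataset(
            np.array([[2.0, 2.0, 2.0, 2.0], [4.0, 4.0, 4.0, 4.0]]),
            ["BSA", "PA", "PA", "OA"],
        )
        out = preprocess(ds, probe_map={"gene": ["g0", "g1"]})
        assert out.gene_ids == ["gene"]
        assert (out.gene("gene") == 3.0).all()

    def test_log2_transform(self):
        ds = _make_dataset(
            np.full((1, 4), 8.0), ["BSA", "PA", "PA", "OA"]
        )
        out = preprocess(ds, log2_transform=True)
        assert (out.gene("g0") == 3.0).all()

    def test_identity_probe_map_preserves_matrix(self):
        ds = _make_dataset(
            np.arange(8.0).reshape(2, 4), ["BSA", "PA", "PA", "OA"]
        )
        out = preprocess(ds, probe_map={"g0": ["g0"], "g1": ["g1"]})
        assert np.array_equal(out.matrix(), ds.matrix())

    def test_non_positive_value_named(self):
        ds = _make_dataset(
            np.array([[1.0, 2.0, -3.0, 4.0]]), ["BSA", "PA", "PA", "OA"]
        )
        with pytest.raises(ValueError, match=r"g0.*S2"):
            preprocess(ds, log2_transform=True)

    def test_blacklist_dropped(self):
        ds = _make_dataset(
            np.ones((3, 4)), ["BSA", "PA", "PA", "OA"]
        )
        out = preprocess(ds, drop_genes=["g1"])
        assert out.gene_ids == ["g0", "g2"]


class TestSelectGenes:
    def _trendful_dataset(self, n_per_cond=10, sd=0.1, seed=0):
        rng = np.random.default_rng(seed)
        cond = ["BSA"] * n_per_cond + ["PA"] * n_per_cond + ["OA"] * n_per_cond
        means = np.array([0.0] * n_per_cond + [3.0] * n_per_cond + [0.0] * n_per_cond)
        strong = means + rng.normal(0, sd, 3 * n_per_cond)
        flat = rng.normal(5.0, sd, 3 * n_per_cond)
        constant = np.full(3 * n_per_cond, 2.0)
        return _make_dataset(np.vstack([strong, flat, constant]), cond)

    def test_strong_palmitate_peak_kept_under_trend_one(self):
        ds = self._trendful_dataset()
        kept, report = select_genes(ds, alpha=0.05)
        assert "g0" in kept
        row = report.set_index("gene").loc["g0"]
        assert row["trend"] == "I"
        # oracle: Welch t between BSA and PA from the closed form
        v = ds.gene("g0")
        cond = ds.condition.to_numpy()
        a, b = v[cond == "BSA"], v[cond == "PA"]
        t = (a.mean() - b.mean()) / np.sqrt(a.var(ddof=1) / 10 + b.var(ddof=1) / 10)
        assert abs(t) > 10  # overwhelming evidence; p must be < alpha
        assert row["p_BSA_PA"] < 0.05
        assert row["kept"]

    def test_constant_gene_dropped(self):
        ds = self._trendful_dataset()
        kept, report = select_genes(ds, alpha=0.05)
        assert "g2" not in kept
        assert report.set_index("gene").loc["g2", "trend"] == ""

    def test_alpha_zero_empties_selection(self):
        ds = self._trendful_dataset()
        kept, _ = select_genes(ds, alpha=0.0)
        assert kept == []

    def test_alpha_monotonicity(self):
        ds = simulate_dataset(
            SimulationConfig(
                n_genes=30,
                n_samples_per_phenotype=20,
                trend_assignment={f"G{i:04d}": "I" for i in range(1, 16)},
                trend_effect=0.35,
                seed=5,
            )
        )
        kept = {a: set(select_genes(ds, alpha=a)[0]) for a in (0.01, 0.05, 0.5)}
        assert kept[0.01] <= kept[0.05] <= kept[0.5]

    def test_invariant_to_gene_and_sample_order(self):
        ds = self._trendful_dataset()
        rng = np.random.default_rng(1)
        genes = list(rng.permutation(ds.gene_ids))
        samples = list(rng.permutation(ds.sample_ids))
        shuffled = ExpressionDataset(
            ds.values.loc[genes, samples], ds.condition[samples],
            ds.phenotype[samples],
        )
        assert set(select_genes(ds)[0]) == set(select_genes(shuffled)[0])

    def test_recall_of_trend_assigned_genes(self):
        """Strong condition effects: >= 90% of trend genes selected."""
        assignment = {f"G{i:04d}": TREND_CODES[i % 4] for i in range(1, 41)}
        ds = simulate_dataset(
            SimulationConfig(
                n_genes=40,
                n_samples_per_phenotype=30,
                trend_assignment=assignment,
                trend_effect=1.0,
                noise_sd=0.3,
                seed=9,
            )
        )
        kept, _ = select_genes(ds, alpha=0.05)
        recall = len(set(kept) & set(assignment)) / len(assignment)
        assert recall >= 0.9

    def test_small_condition_rejected(self):
        ds = _make_dataset(np.ones((2, 4)), ["BSA", "PA", "PA", "OA"])
        with pytest.raises(ValueError, match="BSA"):
            select_genes(ds)
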