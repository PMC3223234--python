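"""Mutual information, discretization, synergy scores, permutation, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from synergynet import (
    ContingencyTable,
    ExpressionDataset,
    SynergyEstimator,
    all_pairs,
    bh_adjust,
    discretize,
    mutual_information,
    null_config,
    simulate_dataset,
    synergy_scan,
    synergy_score,
)
from synergynet.synergy import DegeneratePhenotypeError, _mi_batch


def mi_double_sum(counts: np.ndarray) -> float:
    """Independent oracle: normalized MI by the explicit double sum."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    mi = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            p = counts[i, j] / total
            if p > 0:
                pg = counts[i, :].sum() / total
                pp = counts[:, j].sum() / total
                mi += p * np.log2(p / (pg * pp))
    h = 0.0
    for j in range(counts.shape[1]):
        pp = counts[:, j].sum() / total
        if pp > 0:
            h -= pp * np.log2(pp)
    return mi / h


class TestMutualInformation:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([[25, 25], [25, 25]], 0.0),               # independence
            ([[50, 0], [0, 50]], 1.0),                 # perfect association
            ([[30, 10], [10, 30]], 0.18872187554086717),
        ],
    )
    def test_known_tables(self, counts, expected):
        assert mutual_information(ContingencyTable(counts)) == pytest.approx(
            expected, abs=1e-12
        )
        # the middle example's value comes from the double-sum oracle
        assert mi_double_sum(np.array(counts)) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_phenotype_rejected(self):
        with pytest.raises(DegeneratePhenotypeError, match="degenerate"):
            mutual_information(ContingencyTable([[10, 0], [20, 0]]))

    def test_invalid_tables(self):
        with pytest.raises(ValueError):
            ContingencyTable([[1, -1], [0, 2]])
        with pytest.raises(ValueError):
            ContingencyTable([[0, 0], [0, 0]])

    def test_matches_double_sum_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            k = rng.integers(2, 10)
            counts = rng.integers(0, 30, size=(k, 2)).astype(float)
            counts[0] += 1  # keep both classes populated
            if counts[:, 0].sum() == 0 or counts[:, 1].sum() == 0:
                continue
            got = mutual_information(ContingencyTable(counts))
            want = mi_double_sum(counts)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_batch_matches_scalar_path(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 40)
        y[:5], y[5:10] = 0, 1
        states = rng.integers(0, 4, size=(6, 40))
        batch = _mi_batch(states, y, 4)
        for row, got in zip(states, batch):
            table = ContingencyTable.from_labels(row, y)
            assert got == pytest.approx(mutual_information(table), abs=1e-12)


class TestDiscretize:
    def test_constant_vector_single_state(self):
        assert set(discretize(np.full(10, 3.14), n_states=3)) == {0}

    def test_two_cluster_split_at_gap(self):
        x = np.array([1.0, 1.0, 1.0, 9.0, 9.0, 9.0])
        labels = discretize(x, n_states=2)
        # oracle: exhaustive search over contiguous splits of the sorted values
        best_cost, best_split = np.inf, None
        xs = np.sort(x)
        for cut in range(1, 6):
            lo, hi = xs[:cut], xs[cut:]
            cost = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
            if cost < best_cost:
                best_cost, best_split = cost, cut
        assert best_split == 3
        assert (labels == np.array([0, 0, 0, 1, 1, 1])).all()

    def test_dp_matches_exhaustive_three_bins(self):
        rng = np.random.default_rng(3)
        from itertools import combinations

        from synergynet._cluster import optimal_1d_labels

        for _ in range(10):
            x = np.sort(rng.normal(size=9))
            labels = optimal_1d_labels(x, 3)
            got = sum(
                ((x[labels == b] - x[labels == b].mean()) ** 2).sum()
                for b in np.unique(labels)
            )
            best = np.inf
            for c1, c2 in combinations(range(1, 9), 2):
                parts = [x[:c1], x[c1:c2], x[c2:]]
                best = min(
                    best, sum(((p - p.mean()) ** 2).sum() for p in parts)
                )
            assert got == pytest.approx(best, abs=1e-12)

    def test_seeded_determinism_2d(self):
        rng = np.random.default_rng(4)
        g1, g2 = rng.normal(size=30), rng.normal(size=30)
        a = discretize((g1, g2), n_states=3, seed=9)
        b = discretize((g1, g2), n_states=3, seed=9)
        assert (a == b).all()
        assert a.max() < 9

    def test_fewer_samples_than_states_rejected(self):
        with pytest.raises(ValueError, match="fewer samples"):
            discretize(np.array([1.0, 2.0]), n_states=3)

    def test_batched_kmeans_matches_sklearn_inertia(self):
        """Independent oracle: sklearn KMeans reaches the same optimum."""
        sklearn_cluster = pytest.importorskip("sklearn.cluster")
        rng = np.random.default_rng(5)
        from synergynet._cluster import batched_kmeans

        X = rng.normal(size=(3, 40, 2))
        labels = batched_kmeans(X, 4, restarts=10, seed=0)
        for i in range(3):
            km = sklearn_cluster.KMeans(n_clusters=4, n_init=10, random_state=0)
            km.fit(X[i])
            ours = sum(
                ((X[i][labels[i] == c] - X[i][labels[i] == c].mean(0)) ** 2).sum()
                for c in np.unique(labels[i])
            )
            assert ours == pytest.approx(km.inertia_, rel=0.05)


class TestSynergyScore:
    def test_duplicated_gene_is_fully_redundant(self, planted_dataset):
        phen = planted_dataset.phenotype.to_numpy()
        for gene in planted_dataset.gene_ids[:5]:
            g = planted_dataset.gene(gene)
            i1, i2, i12, syn = synergy_score(g, g.copy(), phen)
            assert i1 == i2
            assert i12 == pytest.approx(i1, abs=1e-12)
            assert syn == pytest.approx(-i1, abs=1e-12)
            assert syn <= 1e-12

    def test_planted_gap_pair_is_positive(self):
        """syn > 0 for the planted pair even at sigma_c2=1 (20 seeds)."""
        syns = []
        for seed in range(20):
            from synergynet import PlantedPair, SimulationConfig

            cfg = SimulationConfig(
                n_genes=2,
                n_samples_per_phenotype=30,
                planted_pairs=(PlantedPair("gap", delta=2.0, sigma_c2=1.0),),
                noise_sd=0.3,
                seed=seed,
            )
            ds = simulate_dataset(cfg)
            *_, syn = synergy_score(
                ds.gene("G0001"), ds.gene("G0002"), ds.phenotype.to_numpy()
            )
            syns.append(syn)
        syns = np.array(syns)
        # the mean is decisively positive (≈5 standard errors above zero)
        assert syns.mean() > 3 * syns.std(ddof=1) / np.sqrt(syns.size)

    def test_null_pairs_center_on_their_permutation_null(self):
        """Phenotype-null pairs score like label-permuted data: the mean
        synergy difference over 200 null pairs is within 3 SE of zero.
        (The raw plug-in scores carry a small positive finite-sample bias
        that the permutation null shares and therefore cancels.)"""
        ds = simulate_dataset(
            null_config(n_genes=400, n_samples_per_phenotype=30, seed=21)
        )
        genes = ds.gene_ids
        pairs = [(genes[2 * i], genes[2 * i + 1]) for i in range(200)]
        obs = synergy_scan(ds, pairs=pairs, B=1, seed=0)["syn"].to_numpy()

        rng = np.random.default_rng(5)
        perm = rng.permutation(ds.n_samples)
        permuted = ExpressionDataset(
            ds.values,
            ds.condition,
            pd.Series(ds.phenotype.to_numpy()[perm], index=ds.sample_ids),
        )
        null = synergy_scan(permuted, pairs=pairs, B=1, seed=0)["syn"].to_numpy()
        diff = obs - null
        se = diff.std(ddof=1) / np.sqrt(diff.size)
        assert abs(diff.mean()) < 3 * se
        # and the raw bias itself stays small
        assert abs(obs.mean()) < 0.1

    def test_bounds(self, planted_dataset):
        res = synergy_scan(planted_dataset, B=20, seed=2)
        assert ((res[["I1", "I2", "I12"]] >= 0).all().all())
        assert ((res[["I1", "I2", "I12"]] <= 1 + 1e-12).all().all())
        assert res["syn"].between(-1 - 1e-12, 1 + 1e-12).all()
        assert np.allclose(res["syn"], res["I12"] - res["I1"] - res["I2"])

    def test_degenerate_phenotype(self):
        with pytest.raises(DegeneratePhenotypeError):
            synergy_score(np.arange(6.0), np.arange(6.0), ["toxic"] * 6)


class TestPermutation:
    def _two_gene_dataset(self, g1, g2, phen):
        samples = [f"S{i}" for i in range(len(phen))]
        values = pd.DataFrame([g1, g2], index=["a", "b"], columns=samples)
        cond = pd.Series(
            np.where(np.array(phen) == "toxic", "PA", "BSA"), index=samples
        )
        return ExpressionDataset(values, cond, pd.Series(phen, index=samples))

    def test_extreme_pair_attains_minimal_p(self):
        from synergynet import PlantedPair, SimulationConfig, permutation_test

        cfg = SimulationConfig(
            n_genes=2,
            n_samples_per_phenotype=30,
            planted_pairs=(PlantedPair("gap", delta=4.0, sigma_c2=16.0),),
            seed=2,
        )
        ds = simulate_dataset(cfg)
        B = 99
        p = permutation_test(
            [("G0001", "G0002")], ds, B=B, seed=5, null_model="per_pair"
        )
        assert p[0] == pytest.approx(1.0 / (B + 1))

    def test_fully_redundant_pair_has_p_one(self):
        """A gene that determines the phenotype, duplicated: syn = -1 is
        the worst possible score, so every permutation ties or beats it."""
        rng = np.random.default_rng(8)
        phen = ["toxic"] * 10 + ["nontoxic"] * 10
        g1 = np.where(np.array(phen) == "toxic", 5.0, 1.0) + rng.normal(0, 1e-6, 20)
        ds = self._two_gene_dataset(g1, g1.copy(), phen)
        from synergynet import permutation_test

        p = permutation_test([("a", "b")], ds, B=50, seed=1, null_model="per_pair")
        assert p[0] == 1.0

    def test_null_scores_equal_scores_of_label_permuted_data(self):
        """Exchangeability: the permutation null reproduces the observed
        score of the dataset with pre-permuted labels.  Uses the grid
        estimator, whose discretization is RNG-free, so the same states
        underlie both routes."""
        ds = simulate_dataset(null_config(n_genes=6, n_samples_per_phenotype=10, seed=3))
        est = SynergyEstimator(method="grid", seed=0)
        y = ds.phenotype_indicator()
        M = ds.values.to_numpy()
        s1 = est.marginal_states(M)
        pair_idx = np.array([[0, 1], [2, 3]])
        s12 = est.joint_states_batch(M[pair_idx[:, 0]], M[pair_idx[:, 1]])
        rng = np.random.default_rng(77)
        perm = rng.permutation(y.size)
        yb = y[perm]
        i1b = _mi_batch(s1, yb, est.n_states)
        i12b = _mi_batch(s12, yb, est.n_joint_states)
        null_scores = i12b - i1b[pair_idx[:, 0]] - i1b[pair_idx[:, 1]]
        # observed scores of the dataset whose labels were permuted upfront
        phen = ds.phenotype.to_numpy()[perm]
        for row, (i, j) in enumerate(pair_idx):
            *_, syn = synergy_score(M[i], M[j], phen, est)
            assert syn == pytest.approx(null_scores[row], abs=1e-12)

    def test_duplicate_pair_rejected(self, null_dataset):
        with pytest.raises(ValueError, match="duplicate"):
            synergy_scan(
                null_dataset,
                pairs=[("G0001", "G0002"), ("G0002", "G0001")],
                B=1,
            )

    def test_b_must_be_positive(self, null_dataset):
        with pytest.raises(ValueError, match="B"):
            synergy_scan(null_dataset, pairs=[("G0001", "G0002")], B=0)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
        ],
    )
    def test_examples(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_adjust([1.5])

    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=30,
        )
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_step_up_oracle(self, pvals):
        """Oracle: adjusted_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
        p = np.array(pvals)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        sorted_adj = np.minimum.accumulate(
            (p[order] * m / np.arange(1, m + 1))[::-1]
        )[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(sorted_adj, 1.0)
        got = bh_adjust(p)
        assert got == pytest.approx(oracle, abs=1e-12)
        assert (got >= p - 1e-12).all()


def test_all_pairs_count():
    genes = [f"g{i}" for i in range(25)]
    assert len(all_pairs(genes)) == 25 * 24 // 2
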