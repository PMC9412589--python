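"""Co-expression network: adjacency, TOM, module detection, eigengenes,
module-trait correlation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from csfpanel.errors import AnalysisError
from csfpanel import network as net
from csfpanel.synthetic import ModuleSpec, SyntheticConfig, default_config, generate_dataset


def brute_force_tom(a):
    """Triple-loop reference implementation of the topological overlap."""
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            ki = sum(a[i, u] for u in range(n) if u != i)
            kj = sum(a[j, u] for u in range(n) if u != j)
            tom[i, j] = (l + a[i, j]) / (min(ki, kj) + 1 - a[i, j])
    return tom


def random_adjacency(rng, n):
    a = rng.random((n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestAdjacency:
    def test_perfect_correlation_gives_unit_adjacency(self, matrix_factory):
        values = np.array([[1.0, 2, 3, 4], [2.0, 4, 6, 8]])
        a = net.adjacency(matrix_factory(values), beta=1)
        assert a.iloc[0, 1] == pytest.approx(1.0)

    def test_power_arithmetic(self):
        corr = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]])
        a = net.adjacency_from_correlation(corr, beta=6)
        assert a.iloc[0, 1] == pytest.approx(0.015625)

    def test_matches_brute_force_pearson_power(self, matrix_factory, rng):
        values = rng.normal(size=(10, 6))
        a = net.adjacency(matrix_factory(values), beta=3)
        for i in range(10):
            for j in range(10):
                r = np.corrcoef(values[i], values[j])[0, 1]
                assert a.iloc[i, j] == pytest.approx(abs(r) ** 3 if i != j else 1.0, abs=1e-10)


class TestTopologicalOverlap:
    def test_two_node_network_by_hand(self):
        a12 = 0.6
        a = pd.DataFrame([[1.0, a12], [a12, 1.0]])
        tom = net.topological_overlap(a)
        # l = 0, k_1 = k_2 = a12 -> TOM = a12 / (a12 + 1 - a12) = a12
        assert tom.iloc[0, 1] == pytest.approx(a12)

    def test_identity_adjacency_has_zero_overlap(self):
        tom = net.topological_overlap(pd.DataFrame(np.eye(5)))
        off = tom.to_numpy()[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 0.0)

    def test_matches_triple_loop_brute_force(self, rng):
        for n in (3, 6, 9, 12):
            a = random_adjacency(rng, n)
            tom = net.topological_overlap(pd.DataFrame(a)).to_numpy()
            np.testing.assert_allclose(tom, brute_force_tom(a), atol=1e-12)

    def test_bounds_and_symmetry(self, rng):
        for _ in range(10):
            a = random_adjacency(rng, 8)
            tom = net.topological_overlap(pd.DataFrame(a)).to_numpy()
            assert np.all(tom >= 0) and np.all(tom <= 1 + 1e-12)
            np.testing.assert_allclose(tom, tom.T, atol=1e-12)


class TestScaleFreeFit:
    def test_exact_power_law_degrees_fit_perfectly(self):
        ks = np.concatenate([np.full(round(2000 * k ** -2.0), float(k)) for k in range(1, 11)])
        r2, slope = net.scale_free_fit(ks, n_bins=10)
        assert r2 > 0.99
        assert slope < 0

    def test_single_candidate_power_is_forced(self):
        matrix, _ = generate_dataset(default_config(n_proteins=200, seed=8))
        beta, fits = net.pick_soft_threshold(matrix, candidate_powers=(1,))
        assert beta == 1
        assert list(fits.index) == [1]

    def test_selection_is_deterministic(self):
        matrix, _ = generate_dataset(default_config(n_proteins=200, seed=8))
        b1, _ = net.pick_soft_threshold(matrix)
        b2, _ = net.pick_soft_threshold(matrix)
        assert b1 == b2


class TestDetectModules:
    @staticmethod
    def block_tom(sizes, within, between, rng):
        n = sum(sizes)
        tom = np.full((n, n), between) + rng.normal(0, 0.01, (n, n))
        start = 0
        for s in sizes:
            tom[start:start + s, start:start + s] = within + rng.normal(0, 0.01, (s, s))
            start += s
        tom = np.clip((tom + tom.T) / 2, 0, 1)
        np.fill_diagonal(tom, 1.0)
        return pd.DataFrame(tom)

    def test_two_planted_blocks_recovered(self, rng):
        tom = self.block_tom([30, 30], within=0.7, between=0.05, rng=rng)
        labels = net.detect_modules(tom, min_size=20)
        truth = [0] * 30 + [1] * 30
        assert adjusted_rand_score(truth, labels.tolist()) == 1.0

    def test_all_equal_tom_yields_single_module(self):
        n = 25
        tom = np.full((n, n), 0.5)
        np.fill_diagonal(tom, 1.0)
        labels = net.detect_modules(pd.DataFrame(tom), min_size=20)
        assert labels.nunique() == 1
        assert labels.iloc[0] != net.BACKGROUND_LABEL

    def test_undersized_module_goes_to_background(self, rng):
        tom = self.block_tom([10, 40], within=0.8, between=0.03, rng=rng)
        labels = net.detect_modules(tom, min_size=20, cut_height=0.5)
        assert (labels.iloc[:10] == net.BACKGROUND_LABEL).all()
        assert (labels.iloc[10:] != net.BACKGROUND_LABEL).all()

    def test_min_size_larger_than_matrix_raises(self):
        with pytest.raises(AnalysisError):
            net.detect_modules(pd.DataFrame(np.eye(5)), min_size=20)


class TestModuleEigengenes:
    def test_identical_proteins_give_their_profile(self, matrix_factory):
        profile = np.array([1.0, 3.0, 2.0, 5.0])
        m = matrix_factory(np.tile(profile, (4, 1)))
        labels = pd.Series(["blue"] * 4, index=m.protein_ids)
        eig, explained = net.module_eigengenes(m, labels)
        assert explained["blue"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eig["blue"], z / np.linalg.norm(z), atol=1e-10)

    def test_anticorrelated_pair_fully_explained(self, matrix_factory):
        x = np.array([1.0, 2.0, 4.0, 3.0])
        m = matrix_factory(np.vstack([x, -x]))
        labels = pd.Series(["red", "red"], index=m.protein_ids)
        eig, explained = net.module_eigengenes(m, labels)
        assert explained["red"] == pytest.approx(1.0)
        me = eig["red"].to_numpy()
        assert abs(np.corrcoef(me, x)[0, 1]) == pytest.approx(1.0)

    def test_matches_svd_oracle(self, matrix_factory, rng):
        values = rng.normal(size=(8, 10))
        m = matrix_factory(values, fractions=["total"] * 10)
        labels = pd.Series(["green"] * 8, index=m.protein_ids)
        eig, explained = net.module_eigengenes(m, labels)
        z = (values - values.mean(1, keepdims=True)) / values.std(1, keepdims=True)
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        ref = vt[0] / np.linalg.norm(vt[0])
        me = eig["green"].to_numpy()
        assert min(np.abs(me - ref).max(), np.abs(me + ref).max()) < 1e-10
        assert explained["green"] == pytest.approx(s[0] ** 2 / np.sum(s ** 2))


class TestModuleTraitCorrelation:
    def test_eigengene_equal_to_indicator_has_rho_one(self):
        traits = pd.DataFrame({"MB": [0, 0, 0, 1, 1, 1], "total": [1, 1, 1, 1, 1, 1]},
                              index=list("abcdef"))
        eig = pd.DataFrame({"red": [0.0, 0, 0, 1, 1, 1]}, index=list("abcdef"))
        with pytest.raises(AnalysisError, match="total"):
            net.module_trait_correlation(eig, traits)
        table = net.module_trait_correlation(eig, traits[["MB"]])
        assert table.loc[0, "rho"] == pytest.approx(1.0)

    def test_planted_trait_module_is_the_only_hit(self):
        cfg = default_config(seed=5, de_specs=(), exclusive_specs={})
        matrix, truth = generate_dataset(cfg)
        _, partition = net.build_network(matrix)
        hits = partition.trait_correlations.query("significant")
        assert set(hits["module"]) == {"turquoise"}
        members = partition.labels.index[partition.labels == "turquoise"]
        planted = pd.Series(truth.module_assignment)[members]
        assert (planted == "planted1").mean() > 0.9
        assert set(hits["trait"]) <= {"MB", "control"}
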