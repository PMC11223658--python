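import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nestnet.errors import FormatError, InvalidConfigError
from nestnet.network import (
    AdjacencyMatrix,
    CoexpressionModules,
    CorrelationMatrix,
    ModulePartition,
    UNASSIGNED,
    correlation_matrix,
    detect_modules,
    module_eigengene,
    module_membership,
    module_membership_all,
    signed_hybrid_adjacency,
    tom_similarity,
)

from conftest import factor_module, loading_for, make_matrix


def bicor_oracle(x, y):
    """Elementwise biweight midcorrelation, straight from the formula."""
    def weights(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        u = (v - med) / (9 * mad)
        w = (1 - u**2) ** 2 * (np.abs(u) < 1)
        return w * (v - med)

    ax, ay = weights(x), weights(y)
    return float(np.sum(ax * ay) / np.sqrt(np.sum(ax**2) * np.sum(ay**2)))


class TestCorrelation:
    def test_duplicated_gene_has_correlation_one(self, rng):
        x = rng.standard_normal(20)
        m = make_matrix(np.vstack([x, x, -x]))
        for method in ("bicor", "pearson"):
            c = correlation_matrix(m, method)
            assert c.values[0, 1] == pytest.approx(1.0)
            assert c.values[0, 2] == pytest.approx(-1.0)

    def test_bicor_matches_formula_oracle(self, rng):
        X = rng.standard_normal((10, 20))
        c = correlation_matrix(make_matrix(X), "bicor")
        for i in range(10):
            for j in range(i + 1, 10):
                assert c.values[i, j] == pytest.approx(bicor_oracle(X[i], X[j]), abs=1e-12)

    def test_constant_gene_flagged_and_zeroed(self, rng):
        X = rng.standard_normal((3, 10))
        X[1] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            c = correlation_matrix(make_matrix(X), "bicor")
        assert c.constant_genes == ["g1"]
        assert c.values[0, 1] == 0.0 and c.values[1, 1] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(FormatError):
            correlation_matrix(make_matrix(np.ones((4, 2))))


class TestAdjacency:
    def test_signed_hybrid_zeroes_negative_correlations(self):
        C = np.array([[1.0, -0.5], [-0.5, 1.0]])
        adj = signed_hybrid_adjacency(CorrelationMatrix(["a", "b"], C, "pearson"))
        assert adj.values[0, 1] == 0.0

    @pytest.mark.parametrize("cor,expected", [(0.5, 0.5**6), (1.0, 1.0)])
    def test_soft_power_six(self, cor, expected):
        C = np.array([[1.0, cor], [cor, 1.0]])
        adj = signed_hybrid_adjacency(CorrelationMatrix(["a", "b"], C, "pearson"))
        assert adj.values[0, 1] == pytest.approx(expected)
        assert adj.values[0, 0] == 0.0  # zero diagonal

    def test_invalid_beta_rejected(self):
        C = np.eye(2)
        with pytest.raises(InvalidConfigError):
            signed_hybrid_adjacency(CorrelationMatrix(["a", "b"], C, "pearson"), beta=0)

    def test_monotone_in_positive_correlation(self):
        cors = np.linspace(0, 1, 11)
        vals = [signed_hybrid_adjacency(
            CorrelationMatrix(["a", "b"], np.array([[1, c], [c, 1]]), "pearson")
        ).values[0, 1] for c in cors]
        assert (np.diff(vals) >= 0).all()


def tom_oracle(A):
    """Direct evaluation of the topological-overlap formula."""
    n = A.shape[0]
    k = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n))
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


class TestTom:
    def test_exclusive_pair_with_unit_adjacency_has_tom_one(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        tom = tom_similarity(AdjacencyMatrix(["a", "b"], A, 6))
        assert tom[0, 1] == pytest.approx(1.0)

    def test_disconnected_pair_has_tom_zero(self):
        A = np.zeros((3, 3))
        A[1, 2] = A[2, 1] = 0.5  # g0 shares nothing with anyone
        tom = tom_similarity(AdjacencyMatrix(["a", "b", "c"], A, 6))
        assert tom[0, 1] == 0.0 and tom[0, 2] == 0.0

    def test_matches_formula_oracle_on_random_networks(self, rng):
        for _ in range(20):
            A = rng.uniform(0, 1, (6, 6))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0.0)
            tom = tom_similarity(AdjacencyMatrix(list("abcdef"), A, 6))
            np.testing.assert_allclose(tom, tom_oracle(A), atol=1e-12)
            assert (tom >= 0).all() and (tom <= 1).all()
            np.testing.assert_allclose(tom, tom.T)


class TestDetectModules:
    def test_two_separable_blocks_recovered(self):
        n = 80
        tom = np.full((n, n), 0.002)
        tom[:40, :40] = 0.8
        tom[40:, 40:] = 0.8
        np.fill_diagonal(tom, 1.0)
        part = detect_modules(tom, [f"g{i}" for i in range(n)], min_module_size=30)
        labels = part.labels
        assert len(part.modules) == 2
        assert labels.iloc[:40].nunique() == 1 and labels.iloc[40:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[79]

    def test_all_zero_adjacency_leaves_everything_unassigned(self):
        n = 50
        tom = np.eye(n)
        part = detect_modules(tom, [f"g{i}" for i in range(n)], min_module_size=30)
        assert (part.labels == UNASSIGNED).all()

    def test_invariant_to_gene_order(self, rng):
        n = 60
        tom = np.full((n, n), 0.02)
        tom[:30, :30] = 0.7
        tom[30:, 30:] = 0.7
        np.fill_diagonal(tom, 1.0)
        genes = [f"g{i:02d}" for i in range(n)]
        part1 = detect_modules(tom, genes, min_module_size=10)
        perm = rng.permutation(n)
        part2 = detect_modules(tom[np.ix_(perm, perm)], [genes[i] for i in perm],
                               min_module_size=10)
        pd.testing.assert_series_equal(part1.labels.sort_index(), part2.labels.sort_index())

    def test_bad_cut_height_rejected(self):
        with pytest.raises(InvalidConfigError):
            detect_modules(np.eye(3), ["a", "b", "c"], cut_height=1.5)


class TestEigengene:
    def make_partition(self, m, label="mod"):
        return ModulePartition(pd.Series([label] * m.n_genes, index=m.gene_ids))

    def test_identical_genes_give_full_variance_and_unit_mm(self, rng):
        x = rng.standard_normal(12)
        m = make_matrix(np.tile(x, (5, 1)))
        part = self.make_partition(m)
        me = module_eigengene(m, part, "mod")
        assert me.variance_explained == pytest.approx(1.0)
        assert np.linalg.norm(me.scores) == pytest.approx(1.0)
        for g in m.gene_ids:
            assert module_membership(m, me, g) == pytest.approx(1.0)

    def test_sign_convention_mean_mm_nonnegative(self, rng):
        x = rng.standard_normal(15)
        # two anti-correlated halves, majority positive
        m = make_matrix(np.vstack([x, x, x + 0.01 * rng.standard_normal(15), -x]))
        part = self.make_partition(m)
        me = module_eigengene(m, part, "mod")
        mms = module_membership_all(m, me)
        assert mms.mean() >= 0

    def test_matches_direct_eigendecomposition(self, rng):
        X = rng.standard_normal((8, 20))
        m = make_matrix(X)
        me = module_eigengene(m, self.make_partition(m), "mod")
        Z = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
        evals, evecs = np.linalg.eigh(Z.T @ Z)
        top = evecs[:, -1]
        assert abs(float(np.dot(top, me.scores))) == pytest.approx(1.0, abs=1e-8)
        assert me.variance_explained == pytest.approx(evals[-1] / evals.sum())

    def test_single_gene_module_degenerates(self, rng):
        m = make_matrix(rng.standard_normal((1, 10)))
        part = self.make_partition(m)
        me = module_eigengene(m, part, "mod")
        assert me.degenerate
        z = m.values[0] - m.values[0].mean()
        np.testing.assert_allclose(me.scores, z / np.linalg.norm(z), atol=1e-12)


class TestModuleMembership:
    def test_gene_equal_to_eigengene_scores(self, rng):
        X = rng.standard_normal((6, 10))
        m = make_matrix(X)
        part = ModulePartition(pd.Series(["mod"] * 6, index=m.gene_ids))
        me = module_eigengene(m, part, "mod")
        aligned = make_matrix(np.vstack([me.scores.to_numpy(), -me.scores.to_numpy()]))
        assert module_membership(aligned, me, "g0") == pytest.approx(1.0)
        assert module_membership(aligned, me, "g1") == pytest.approx(-1.0)

    def test_null_mm_rarely_large(self, rng):
        # |r| between independent vectors at n=30 stays under 0.5 >= 95% of the time
        n, reps = 30, 1000
        me_scores = rng.standard_normal(n)
        X = rng.standard_normal((reps, n))
        r = np.array([stats.pearsonr(x, me_scores)[0] for x in X])
        assert np.mean(np.abs(r) < 0.5) >= 0.95


class TestEstimator:
    def test_recovers_planted_modules_and_exposes_sklearn_api(self, rng):
        blocks = [factor_module(rng, 40, 30, loading_for(0.7)) for _ in range(2)]
        X = np.vstack(blocks + [rng.standard_normal((20, 30))])
        df = pd.DataFrame(X.T, index=[f"s{i}" for i in range(30)],
                          columns=[f"g{i}" for i in range(100)])
        model = CoexpressionModules(min_module_size=20)
        labels = model.fit_predict(df)
        assert set(model.get_params()) >= {"beta", "cut_height", "min_module_size"}
        assert len(model.partition_.modules) == 2
        assert model.eigengenes_.shape == (30, 2)
        # planted blocks map to single detected labels
        assert len(set(labels[:40])) == 1 and len(set(labels[40:80])) == 1
        assert labels[0] != labels[40]
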