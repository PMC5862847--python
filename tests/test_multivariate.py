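"""Statistical battery vs independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rpas import (
    ator_pairs,
    bartlett_sphericity,
    centroid_distance,
    hierarchical_clusters,
    iterative_efa,
    kmo,
    pearson_matrix,
    stepwise_lda,
    varimax,
)


def _three_var_data(n=40, seed=5):
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    x1 = z[:, 0]
    x2 = 0.6 * z[:, 0] + 0.8 * z[:, 1]
    x3 = 0.3 * z[:, 0] - 0.5 * z[:, 1] + rng.standard_normal(n)
    return pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})


class TestPearson:
    def test_self_correlation_and_symmetry(self):
        df = _three_var_data()
        r, p, n = pearson_matrix(df)
        assert n == len(df)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r.to_numpy(), r.to_numpy().T)

    def test_perfect_linearity(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "y": [2.0, 4, 6]})
        r, p, _ = pearson_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert p.loc["x", "y"] == pytest.approx(0.0)

    def test_matches_scipy_pairwise(self):
        df = _three_var_data()
        r, p, n = pearson_matrix(df)
        for a, b in itertools.combinations(df.columns, 2):
            r_ref, p_ref = stats.pearsonr(df[a], df[b])
            assert r.loc[a, b] == pytest.approx(r_ref, abs=1e-12)
            assert p.loc[a, b] == pytest.approx(p_ref, rel=1e-9)

    def test_affine_rescaling_invariance(self):
        df = _three_var_data()
        r1, _, _ = pearson_matrix(df)
        scaled = df.assign(x2=3.5 * df["x2"] - 11.0)
        r2, _, _ = pearson_matrix(scaled)
        assert np.allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-12)

    def test_zero_variance_flagged(self):
        df = _three_var_data().assign(flat=1.0)
        with pytest.warns(UserWarning, match="flat"):
            r, p, _ = pearson_matrix(df)
        assert math.isnan(r.loc["flat", "x1"])


def _ward_oracle(x, k):
    """Brute-force Ward agglomeration: merge the pair with the smallest
    increase in total within-cluster sum of squares."""
    clusters = [[i] for i in range(len(x))]
    while len(clusters) > k:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            a, b = x[clusters[i]], x[clusters[j]]
            na, nb = len(a), len(b)
            delta = (na * nb / (na + nb)) * np.sum(
                (a.mean(axis=0) - b.mean(axis=0)) ** 2)
            if best is None or delta < best[0]:
                best = (delta, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = np.empty(len(x), dtype=int)
    for ci, members in enumerate(clusters):
        labels[members] = ci
    return labels


def _partition_sets(labels):
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(i)
    return {frozenset(v) for v in groups.values()}


class TestHierarchicalClusters:
    def test_singleton_cut(self):
        x = _three_var_data(n=6)
        labels = hierarchical_clusters(x, k=6)
        assert sorted(labels) == [1, 2, 3, 4, 5, 6]

    def test_two_clouds_recovered(self):
        rng = np.random.default_rng(0)
        # clouds separated in both location and direction so that the
        # squared-euclidean and cosine dissimilarities both resolve them
        x = np.vstack([rng.normal([5, 0], 0.3, (10, 2)),
                       rng.normal([0, 5], 0.3, (10, 2))])
        for method, metric in [("ward", "squared_euclidean"),
                               ("nearest_neighbor", "squared_euclidean"),
                               ("nearest_neighbor", "cosine")]:
            labels = hierarchical_clusters(pd.DataFrame(x), method, metric, k=2)
            assert _partition_sets(labels) == {
                frozenset(range(10)), frozenset(range(10, 20))}

    def test_ward_matches_bruteforce_on_8_points(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((8, 3))
        for k in (2, 3, 4):
            ours = hierarchical_clusters(pd.DataFrame(x), "ward",
                                         "squared_euclidean", k)
            oracle = _ward_oracle(x, k)
            assert _partition_sets(ours) == _partition_sets(oracle)

    def test_row_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((12, 4))
        base = hierarchical_clusters(pd.DataFrame(x), k=3)
        perm = rng.permutation(12)
        permuted = hierarchical_clusters(pd.DataFrame(x[perm]), k=3)
        base_sets = _partition_sets(base)
        permuted_sets = {
            frozenset(int(perm[i]) for i in members)
            for members in _partition_sets(permuted)
        }
        assert base_sets == permuted_sets

    def test_ward_cosine_unsupported(self):
        with pytest.raises(ValueError, match="squared_euclidean"):
            hierarchical_clusters(_three_var_data(), "ward", "cosine", 2)


class TestFactorabilityGates:
    def test_kmo_matches_hand_partials_on_3_vars(self):
        """For 3 variables the anti-image partials have the closed form
        r_ij.k = (r_ij - r_ik r_jk) / sqrt((1-r_ik^2)(1-r_jk^2))."""
        df = _three_var_data()
        r = np.corrcoef(df.to_numpy(), rowvar=False)

        def partial(i, j, k):
            return (r[i, j] - r[i, k] * r[j, k]) / math.sqrt(
                (1 - r[i, k] ** 2) * (1 - r[j, k] ** 2))

        pairs = [(0, 1, 2), (0, 2, 1), (1, 2, 0)]
        r2 = sum(2 * r[i, j] ** 2 for i, j, _ in pairs)
        q2 = sum(2 * partial(i, j, k) ** 2 for i, j, k in pairs)
        assert kmo(df) == pytest.approx(r2 / (r2 + q2), abs=1e-10)

    def test_bartlett_matches_hand_determinant(self):
        df = _three_var_data()
        x = df.to_numpy()
        n, p = x.shape
        r = np.corrcoef(x, rowvar=False)
        # 3x3 determinant by cofactor expansion
        det = (r[0, 0] * (r[1, 1] * r[2, 2] - r[1, 2] * r[2, 1])
               - r[0, 1] * (r[1, 0] * r[2, 2] - r[1, 2] * r[2, 0])
               + r[0, 2] * (r[1, 0] * r[2, 1] - r[1, 1] * r[2, 0]))
        chi2_hand = -(n - 1 - (2 * p + 5) / 6) * math.log(det)
        p_hand = stats.chi2.sf(chi2_hand, p * (p - 1) / 2)
        chi2, pval = bartlett_sphericity(df)
        assert chi2 == pytest.approx(chi2_hand, abs=1e-10)
        assert pval == pytest.approx(p_hand, abs=1e-10)

    def test_bartlett_null_on_independent_columns(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal((500, 4))
        _, pval = bartlett_sphericity(x)
        assert pval > 0.01  # no evidence against sphericity

    def test_bartlett_significant_on_collinear_columns(self):
        rng = np.random.default_rng(9)
        z = rng.standard_normal(200)
        x = np.column_stack([z, z + 0.1 * rng.standard_normal(200),
                             rng.standard_normal(200)])
        _, pval = bartlett_sphericity(x)
        assert pval < 1e-6

    def test_singular_matrix_names_columns(self):
        df = _three_var_data()
        df["dup"] = df["x1"]
        with pytest.raises(ValueError, match="x1"):
            kmo(df)


def _two_factor_data(n=300, seed=4, noise=0.2):
    """Six observed variables driven by two orthogonal latents
    (loadings 0.8), generating structure {x1,x2,x3} vs {x4,x5,x6}."""
    rng = np.random.default_rng(seed)
    f = rng.standard_normal((n, 2))
    load = np.array([[0.8, 0], [0.8, 0], [0.8, 0],
                     [0, 0.8], [0, 0.8], [0, 0.8]])
    x = f @ load.T + noise * rng.standard_normal((n, 6))
    return pd.DataFrame(x, columns=[f"x{i + 1}" for i in range(6)])


class TestIterativeEFA:
    def test_two_factor_structure_recovered(self):
        result = iterative_efa(_two_factor_data())
        assert result.retained_factors == 2
        assert result.removed_variables == ()
        # each variable loads dominantly on its generating factor
        loads = result.loadings.abs()
        block1 = loads.loc[["x1", "x2", "x3"]].idxmax(axis=1)
        block2 = loads.loc[["x4", "x5", "x6"]].idxmax(axis=1)
        assert block1.nunique() == 1 and block2.nunique() == 1
        assert set(block1) != set(block2)
        assert result.total_variance > 80.0

    def test_pure_noise_flagged(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal((2000, 4))
        # exactly-uncorrelated columns: center, then orthogonalize (the span
        # of mean-zero vectors stays mean-zero), so the correlation matrix
        # is the identity to rounding and no eigenvalue exceeds 1
        q, _ = np.linalg.qr(x - x.mean(axis=0))
        with pytest.warns(UserWarning, match="Kaiser"):
            result = iterative_efa(q[:, :4])
        assert result.retained_factors == 0
        assert result.total_variance == 0.0

    def test_weak_variable_removed(self):
        df = _two_factor_data()
        rng = np.random.default_rng(13)
        df["junk"] = rng.standard_normal(len(df))
        result = iterative_efa(df, loading_threshold=0.30)
        assert "junk" in result.removed_variables
        assert "junk" not in result.loadings.index

    def test_variance_equals_eigenvalue_sum_ratio(self):
        df = _two_factor_data()
        result = iterative_efa(df)
        eig = np.array(result.eigenvalues)
        expected = 100.0 * eig[: result.retained_factors].sum() / len(df.columns)
        # rotation redistributes but preserves the total
        assert result.total_variance == pytest.approx(expected, abs=1e-8)

    def test_varimax_preserves_communalities(self):
        rng = np.random.default_rng(14)
        load = rng.standard_normal((6, 2))
        rotated = varimax(load)
        assert np.allclose((load**2).sum(axis=1), (rotated**2).sum(axis=1))


def _separable_groups(n_per=30, seed=21, delta=4.0):
    rng = np.random.default_rng(seed)
    cols = [f"v{i}" for i in range(5)]
    a = rng.standard_normal((n_per, 5))
    b = rng.standard_normal((n_per, 5))
    b[:, 2] += delta  # only v2 separates the groups
    x = pd.DataFrame(np.vstack([a, b]), columns=cols)
    labels = np.array(["g1"] * n_per + ["g2"] * n_per)
    return x, labels


class TestStepwiseLDA:
    def test_informative_variable_selected_first(self):
        x, labels = _separable_groups()
        result = stepwise_lda(x, labels)
        assert result.selected_variables[0] == "v2"
        assert (result.classification.to_numpy() == labels).all()

    def test_shuffled_labels_find_nothing(self):
        x, labels = _separable_groups()
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(labels)
        result = stepwise_lda(x, shuffled)
        accuracy = float((result.classification.to_numpy() == shuffled).mean())
        # at chance within 3 binomial standard errors
        assert abs(accuracy - 0.5) <= 3 * math.sqrt(0.25 / len(shuffled))

    def test_classification_matches_sklearn(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        x, labels = _separable_groups(delta=2.0)
        result = stepwise_lda(x, labels)
        sel = list(result.selected_variables)
        ref = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
        ref.fit(x[sel], labels)
        assert (result.classification.to_numpy() == ref.predict(x[sel])).all()

    def test_three_groups_two_functions(self):
        rng = np.random.default_rng(30)
        a = rng.standard_normal((20, 4))
        b = rng.standard_normal((20, 4)) + [4, 0, 0, 0]
        c = rng.standard_normal((20, 4)) + [0, 4, 0, 0]
        x = pd.DataFrame(np.vstack([a, b, c]), columns=list("wxyz"))
        labels = np.repeat(["A", "B", "C"], 20)
        result = stepwise_lda(x, labels)
        assert result.functions.shape[1] == 2
        assert len(result.wilks) == 2
        assert all(p < 0.001 for _, p in result.wilks)
        assert set(result.centroids) == {"A", "B", "C"}

    def test_wilks_lambda_in_unit_interval(self):
        x, labels = _separable_groups()
        result = stepwise_lda(x, labels)
        for lam, p in result.wilks:
            assert 0.0 < lam <= 1.0
            assert 0.0 <= p <= 1.0

    def test_degenerate_groups_rejected(self):
        x, _ = _separable_groups(n_per=3)
        with pytest.raises(ValueError):
            stepwise_lda(x, np.array(["g1"] * 6))


class TestCentroidDistance:
    def test_identical_groups(self):
        x = pd.DataFrame(np.ones((6, 3)))
        labels = ["a", "a", "a", "b", "b", "b"]
        assert centroid_distance(x, "a", "b", labels=labels) == 0.0

    def test_pythagoras(self):
        coords = pd.DataFrame(
            [[0, 0, 0], [0, 0, 0], [3, 4, 0], [3, 4, 0]], dtype=float)
        labels = ["a", "a", "b", "b"]
        assert centroid_distance(coords, "a", "b", labels=labels) == pytest.approx(5.0)

    def test_lda_canonical_space(self):
        x, labels = _separable_groups()
        result = stepwise_lda(x, labels)
        dist = centroid_distance(result, "g1", "g2")
        assert dist > 0
        with pytest.raises(ValueError, match="g3"):
            centroid_distance(result, "g1", "g3")

    def test_empty_group_rejected(self):
        x = pd.DataFrame(np.ones((2, 2)))
        with pytest.raises(ValueError, match="'c'"):
            centroid_distance(x, "a", "c", labels=["a", "a"])


class TestAtoR:
    def test_homogeneous_corpus_unflagged(self):
        # richness and RA power varying together: no chunk is simultaneously
        # in the high-R and low-A tails
        n = 57
        table = pd.DataFrame({
            "chunk_id": range(1, n + 1),
            "R": np.linspace(15.0, 17.0, n),
            "A": np.linspace(29.0, 31.0, n),
        })
        out = ator_pairs(table)
        assert not out["outlier"].any()

    def test_injected_anomaly_flagged(self):
        # one chunk with doubled rare-vocabulary rate and halved
        # function-word rate: doubled R, halved A
        n = 56
        table = pd.DataFrame({
            "chunk_id": list(range(1, n + 1)) + [99],
            "R": list(np.linspace(15.0, 17.0, n)) + [2 * 16.0],
            "A": list(np.linspace(29.0, 31.0, n)) + [0.5 * 29.0],
        })
        out = ator_pairs(table)
        assert out.loc[out["chunk_id"] == 99, "outlier"].all()
        assert out["outlier"].sum() == 1

    def test_aggregate_a_from_components(self):
        table = pd.DataFrame({
            "R": [1.0, 2.0, 3.0],
            "A_article": [0.1, 0.2, 0.3],
            "A_pronoun": [0.4, 0.5, 0.6],
        })
        out = ator_pairs(table)
        assert list(out["A"]) == pytest.approx([0.5, 0.7, 0.9])

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="R"):
            ator_pairs(pd.DataFrame({"A": [1.0, 2.0]}))
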