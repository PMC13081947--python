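import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from modulescope import (
    classifier_validation,
    deg_coherence,
    detection_fraction,
    jaccard_matrix,
    rank_genes_one_vs_rest,
    tau_scores,
    top_deg_sets,
)
from modulescope.dea import tau_from_means, wilcoxon_z
from modulescope.errors import ParameterError
from tests.conftest import make_expression, processed


def exact_ranksum_pvalue(x, y):
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    obs = ranks[:n1].sum()
    stats = [sum(ranks[list(idx)]) for idx in itertools.combinations(range(len(pooled)), n1)]
    stats = np.array(stats)
    mean = stats.mean()
    p = np.mean(np.abs(stats - mean) >= np.abs(obs - mean) - 1e-12)
    return p


class TestWilcoxon:
    def test_identical_groups_null(self):
        values = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        z, p = wilcoxon_z(values, np.array([True, True, True, False, False, False]))
        assert z[0] == 0.0
        assert p[0] == 1.0

    def test_normal_approximation_close_to_exact_enumeration(self):
        x, y = np.array([5.0, 6.0, 7.0]), np.array([1.0, 2.0, 3.0])
        exact = exact_ranksum_pvalue(x, y)
        assert np.isclose(exact, 0.1)
        values = np.concatenate([x, y])[:, None]
        _, p = wilcoxon_z(values, np.array([True] * 3 + [False] * 3))
        assert abs(p[0] - exact) < 0.05

    def test_matches_mannwhitneyu_asymptotic(self):
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, (40, 6))
        values[:15] += rng.normal(0, 1, 6)
        mask = np.zeros(40, dtype=bool)
        mask[:15] = True
        _, p = wilcoxon_z(values, mask)
        ref = mannwhitneyu(values[mask], values[~mask], axis=0,
                           method="asymptotic", use_continuity=True).pvalue
        assert np.allclose(p, ref, atol=1e-10)


class TestRankGenes:
    @pytest.fixture()
    def two_cluster_table(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(3, (60, 5)) + 1
        counts[:30, 0] *= 8  # strong marker of cluster 0
        X = processed(counts)
        clusters = [0] * 30 + [1] * 30
        return rank_genes_one_vs_rest(X, clusters)

    def test_marker_detected_with_positive_lfc(self, two_cluster_table):
        row = two_cluster_table.query("gene == 'g0' and cluster == 0").iloc[0]
        assert row.qvalue < 1e-6
        assert row.lfc > 1.5  # ~8-fold raw boost on normalised expression

    def test_bh_qvalues_monotone_and_bounded(self, two_cluster_table):
        for _, sub in two_cluster_table.groupby("cluster"):
            sub = sub.sort_values("pvalue")
            assert (sub.qvalue.to_numpy() >= sub.pvalue.to_numpy() - 1e-12).all()
            assert (np.diff(sub.qvalue.to_numpy()) >= -1e-12).all()

    def test_doubled_mean_gives_lfc_of_one(self):
        X = make_expression(np.ones((8, 1), dtype=int))
        X.layers["norm"] = np.array([[2.0]] * 4 + [[1.0]] * 4)
        X.layers["log"] = np.log1p(X.layers["norm"])
        table = rank_genes_one_vs_rest(X, [0] * 4 + [1] * 4)
        row = table.query("cluster == 0").iloc[0]
        assert np.isclose(row.lfc, 1.0, atol=1e-5)


class TestDetectionFraction:
    def test_half_expressed(self):
        X = make_expression([[1], [0], [1], [0]])
        X.layers["log"] = np.array([[1.0], [0.0], [1.0], [0.0]])
        f = detection_fraction(X, [0, 0, 0, 0])
        assert f.iloc[0, 0] == 0.5

    def test_threshold_at_max_gives_zero(self):
        X = make_expression([[1], [2]])
        X.layers["log"] = np.array([[1.0], [2.0]])
        f = detection_fraction(X, [0, 0], threshold=2.0)
        assert f.iloc[0, 0] == 0.0


class TestTopDegSets:
    def make_table(self):
        return pd.DataFrame({
            "gene": ["a", "b", "c", "d"],
            "cluster": [0, 0, 0, 0],
            "qvalue": [0.01, 0.01, 0.5, 0.2],
            "lfc": [1.0, 2.0, -1.0, 0.5],
        })

    def test_tie_broken_by_abs_lfc(self):
        sets = top_deg_sets(self.make_table(), n=2, require_positive_lfc=False)
        assert sets[0] == ["b", "a"]

    def test_no_padding_beyond_available(self):
        sets = top_deg_sets(self.make_table(), n=10, require_positive_lfc=True)
        assert sets[0] == ["b", "a", "d"]  # c excluded: negative lfc

    def test_all_depleted_cluster_empty(self):
        table = self.make_table().assign(lfc=[-1, -2, -3, -0.5])
        assert top_deg_sets(table, n=5)[0] == []

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ParameterError):
            top_deg_sets(self.make_table(), n=0)


class TestJaccard:
    def test_identical_disjoint_partial(self):
        J = jaccard_matrix(
            {"i": ["g1", "g2", "g3"], "d": ["x", "y"], "p": ["a", "b", "c"]},
            {"i": ["g1", "g2", "g3"], "d2": ["z", "w"], "p2": ["b", "c", "d"]},
        )
        assert J.loc["i", "i"] == 1.0
        assert J.loc["d", "d2"] == 0.0
        assert J.loc["p", "p2"] == 0.5

    def test_self_comparison_symmetric_unit_diagonal(self):
        sets = {"a": ["x", "y"], "b": ["y", "z"], "c": ["q"]}
        J = jaccard_matrix(sets, sets)
        assert np.allclose(J, J.T)
        assert np.allclose(np.diag(J), 1.0)


class TestTau:
    def test_perfectly_specific(self):
        assert tau_from_means([5, 0, 0, 0]) == 1.0

    def test_uniform(self):
        assert tau_from_means([3, 3, 3, 3]) == 0.0

    def test_partial_specificity(self):
        assert tau_from_means([2, 1, 1, 1]) == 0.5

    def test_all_zero_undefined(self):
        assert np.isnan(tau_from_means([0, 0, 0]))

    def test_single_cluster_rejected(self):
        with pytest.raises(ParameterError):
            tau_from_means([1.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=2, max_size=20))
    def test_bounds_on_nonnegative_means(self, means):
        tau = tau_from_means(means)
        if not np.isnan(tau):
            assert -1e-12 <= tau <= 1.0 + 1e-12

    def test_tau_scores_over_cells(self):
        values = pd.DataFrame({"spec": [4.0, 4.0, 0.0, 0.0], "unif": [1.0] * 4})
        out = tau_scores(values, ["a", "a", "b", "b"])
        assert out.loc["spec", "tau"] == 1.0
        assert out.loc["unif", "tau"] == 0.0


class TestDegCoherence:
    def test_self_and_negation(self):
        X = make_expression(np.ones((5, 2), dtype=int))
        base = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        X.layers["log"] = np.column_stack([base, -base])
        r = deg_coherence(X, ["g0", "g1"])
        assert r.loc["g0", "g0"] == 1.0
        assert np.isclose(r.loc["g0", "g1"], -1.0)

    def test_independent_genes_uncorrelated(self):
        rng = np.random.default_rng(3)
        X = make_expression(np.ones((1000, 2), dtype=int))
        X.layers["log"] = rng.normal(0, 1, (1000, 2))
        r = deg_coherence(X, ["g0", "g1"])
        assert abs(r.loc["g0", "g1"]) < 0.1


def _blob_dataset(seed, n_per=40, shift=4.0):
    rng = np.random.default_rng(seed)
    log = np.vstack([
        rng.normal(0, 1, (n_per, 6)),
        rng.normal(shift, 1, (n_per, 6)),
    ])
    X = make_expression(np.ones_like(log, dtype=int))
    X.layers["log"] = log
    labels = [0] * n_per + [1] * n_per
    return X, labels


class TestClassifierValidation:
    def test_resubstitution_on_separable_blobs_is_perfect(self):
        X, labels = _blob_dataset(0)
        res = classifier_validation(X, labels, X, labels,
                                    {0: ["g0", "g1"], 1: ["g2"]}, seed=0, n_trees=50)
        assert (res.per_class_accuracy == 1.0).all()

    def test_permuted_labels_near_chance(self):
        X, labels = _blob_dataset(1, n_per=100)
        rng = np.random.default_rng(0)
        permuted = rng.permutation(labels)
        res = classifier_validation(X, permuted, X, rng.permutation(labels),
                                    {0: ["g0", "g1", "g2"]}, seed=0, n_trees=100)
        assert abs(res.per_class_accuracy.mean() - 0.5) < 0.1

    def test_same_seed_identical_confusion(self):
        X, labels = _blob_dataset(2)
        args = (X, labels, X, labels, {0: ["g0"], 1: ["g1"]})
        a = classifier_validation(*args, seed=5, n_trees=50)
        b = classifier_validation(*args, seed=5, n_trees=50)
        assert a.confusion.equals(b.confusion)


def test_global_null_type_one_error_calibrated():
    """Under one shared distribution and random labels, ~5% of genes reach p<0.05."""
    rng = np.random.default_rng(42)
    n_cells, n_genes = 400, 2_000
    X = make_expression(np.ones((n_cells, n_genes), dtype=int))
    X.layers["log"] = rng.normal(0, 1, (n_cells, n_genes))
    labels = rng.integers(0, 2, n_cells)
    table = rank_genes_one_vs_rest(X, labels)
    frac = (table.query("cluster == 0").pvalue < 0.05).mean()
    assert 0.03 <= frac <= 0.07
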