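import igraph as ig
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.metrics import adjusted_rand_score

from modulescope import (
    adjacency,
    cut_modules,
    gene_correlation,
    scan_soft_power,
    topological_overlap,
)
from modulescope.coexpression import GREY, WGCNA_COLORS
from modulescope.errors import DataError, ParameterError


def tom_loop_oracle(A):
    """Independent O(p^3) transcription of the unsigned TOM formula."""
    A = np.asarray(A, dtype=float)
    p = A.shape[0]
    tom = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                tom[i, j] = 1.0
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(p) if u != i and u != j)
            k_i = sum(A[i, u] for u in range(p) if u != i)
            k_j = sum(A[j, u] for u in range(p) if u != j)
            tom[i, j] = (l_ij + A[i, j]) / (min(k_i, k_j) + 1 - A[i, j])
    return tom


def random_adjacency(rng, p):
    r = rng.uniform(0, 1, (p, p))
    a = (r + r.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestGeneCorrelation:
    def test_duplicate_and_negated_genes(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 1, 30)
        df = pd.DataFrame({"a": base, "b": base, "c": -base, "d": rng.normal(0, 1, 30)})
        r = gene_correlation(df)
        assert np.isclose(r.loc["a", "b"], 1.0)
        assert np.isclose(r.loc["a", "c"], -1.0)

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 50)
        df = pd.DataFrame({"a": x, "b": np.exp(x)})
        r = gene_correlation(df, method="spearman")
        assert np.isclose(r.loc["a", "b"], 1.0)

    def test_bicor_close_to_pearson_on_clean_data(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 200)
        df = pd.DataFrame({"a": x + rng.normal(0, 0.3, 200), "b": x})
        rp = gene_correlation(df, method="pearson").loc["a", "b"]
        rb = gene_correlation(df, method="bicor").loc["a", "b"]
        assert abs(rp - rb) < 0.1

    def test_too_few_metacells_rejected(self):
        with pytest.raises(DataError):
            gene_correlation(pd.DataFrame({"a": [1, 2], "b": [2, 1]}))

    def test_zero_variance_gene_dropped(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.normal(0, 1, 20), "flat": np.ones(20)})
        r = gene_correlation(df)
        assert list(r.columns) == ["a"]


class TestSoftPower:
    def corr_block(self, seed=0, p=40):
        rng = np.random.default_rng(seed)
        f = rng.normal(0, 1, (100, 1))
        X = 0.7 * f + 0.5 * rng.normal(0, 1, (100, p))
        return np.corrcoef(X, rowvar=False)

    def test_beta_one_is_absolute_correlation(self):
        corr = self.corr_block()
        assert np.allclose(adjacency(corr, 1.0)[~np.eye(len(corr), dtype=bool)],
                           np.abs(corr)[~np.eye(len(corr), dtype=bool)])

    def test_mean_connectivity_strictly_decreasing(self):
        scan = scan_soft_power(self.corr_block(), betas=list(range(1, 11)))
        k = scan.table["mean_connectivity"].to_numpy()
        assert (np.diff(k) < 0).all()

    def test_scale_free_network_reaches_fit_target(self):
        # Barabasi-Albert topology converted to a correlation-like matrix
        g = ig.Graph.Barabasi(400, m=2, directed=False)
        A = np.array(g.get_adjacency().data, dtype=float)
        rng = np.random.default_rng(0)
        corr = A * 0.8 + (1 - A) * rng.uniform(0, 0.05, A.shape)
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        scan = scan_soft_power(corr)
        best = scan.table["signed_r2"].max()
        assert best >= 0.8
        assert scan.chosen_beta == scan.table.query("signed_r2 >= 0.8").beta.iloc[0]

    def test_degenerate_correlations_rejected(self):
        with pytest.raises(DataError):
            scan_soft_power(np.ones((10, 10)))


class TestAdjacency:
    @pytest.mark.parametrize("r,beta,expected", [(0.5, 2, 0.25), (-0.5, 2, 0.25), (0.3, 1, 0.3)])
    def test_elementwise_power_of_absolute(self, r, beta, expected):
        corr = np.array([[1.0, r], [r, 1.0]])
        assert np.isclose(adjacency(corr, beta)[0, 1], expected)

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ParameterError):
            adjacency(np.eye(2), 0)


class TestTom:
    def test_clique_saturates_at_one(self):
        assert np.allclose(topological_overlap(np.ones((3, 3))), 1.0)

    def test_isolated_pair_is_zero(self):
        A = np.eye(4)
        assert topological_overlap(A)[0, 1] == 0.0

    def test_matches_loop_oracle_on_small_matrices(self):
        rng = np.random.default_rng(0)
        for p in (4, 9, 17, 30):
            A = random_adjacency(rng, p)
            assert np.allclose(topological_overlap(A), tom_loop_oracle(A), atol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_bounds_on_random_adjacencies(self, seed):
        A = random_adjacency(np.random.default_rng(seed), 8)
        tom = topological_overlap(A)
        assert (tom >= 0).all() and (tom <= 1 + 1e-12).all()

    def test_asymmetric_input_rejected(self):
        A = np.eye(3)
        A[0, 1] = 0.5
        with pytest.raises(ParameterError):
            topological_overlap(A)


def block_dissim(seed=0, sizes=(50, 50), noise=100, within=0.8):
    """TOM dissimilarity from a planted block-correlation structure."""
    rng = np.random.default_rng(seed)
    n = 200
    cols = []
    labels = []
    for b, size in enumerate(sizes):
        f = rng.normal(0, 1, n)
        for _ in range(size):
            w = np.sqrt(within)
            cols.append(w * f + np.sqrt(1 - within) * rng.normal(0, 1, n))
            labels.append(b)
    for _ in range(noise):
        cols.append(rng.normal(0, 1, n))
        labels.append(-1)
    X = np.column_stack(cols)
    corr = np.corrcoef(X, rowvar=False)
    tom = topological_overlap(adjacency(corr, 6.0))
    genes = [f"g{i}" for i in range(len(labels))]
    return pd.DataFrame(1 - tom, index=genes, columns=genes), np.array(labels)


class TestCutModules:
    def test_two_planted_blocks_recovered_exactly(self):
        dissim, labels = block_dissim()
        assign = cut_modules(dissim, min_module_size=10)
        non_grey = assign.labels != GREY
        planted = labels >= 0
        assert adjusted_rand_score(labels[planted], assign.labels[planted]) == 1.0
        assert len(assign.modules) == 2
        # colour order by size
        assert set(assign.modules) <= set(WGCNA_COLORS)

    def test_min_module_size_above_total_gives_all_grey(self):
        dissim, _ = block_dissim(sizes=(20,), noise=0)
        assign = cut_modules(dissim, min_module_size=50)
        assert (assign.labels == GREY).all()

    def test_pure_noise_is_mostly_grey(self):
        dissim, _ = block_dissim(seed=5, sizes=(), noise=150)
        assign = cut_modules(dissim, min_module_size=10)
        assert (assign.labels == GREY).mean() >= 0.9

    def test_permutation_destroys_structure(self):
        rng = np.random.default_rng(7)
        n = 200
        f = rng.normal(0, 1, n)
        X = 0.9 * f[:, None] + 0.4 * rng.normal(0, 1, (n, 80))
        # shuffle each gene's values independently
        for j in range(X.shape[1]):
            rng.shuffle(X[:, j])
        corr = np.corrcoef(X, rowvar=False)
        tom = topological_overlap(adjacency(corr, 6.0))
        genes = [f"g{i}" for i in range(80)]
        assign = cut_modules(pd.DataFrame(1 - tom, index=genes, columns=genes),
                             min_module_size=10)
        assert (assign.labels == GREY).mean() >= 0.9


def test_planted_module_recovery_across_seeds():
    """Five planted modules of 40-100 genes recovered at ARI >= 0.9, 5 seeds."""
    from modulescope import ModuleSpec, SyntheticSpec, generate, run_cna
    from modulescope.preprocess import PreprocessConfig, run_preprocess

    sizes = [40, 55, 70, 85, 100]
    for seed in range(5):
        mods = [ModuleSpec(f"m{i}", s, peripheral_range=(0.6, 0.9))
                for i, s in enumerate(sizes)]
        X, ann, truth = generate(SyntheticSpec(
            n_cells=1_000, n_genes=500, cluster_proportions=[1.0],
            markers_per_cluster=0, modules=mods, seed=seed))
        X, pca, clusters = run_preprocess(X, PreprocessConfig(n_pcs=10, seed=seed))
        ann.table["cluster"] = 0
        res = run_cna(X, pca, ann, clusters, beta=4.0, min_module_size=20, seed=seed)
        labels = res.modules.labels
        truth_labels = truth.genes["module"].reindex(labels.index).fillna("")
        planted = truth_labels != ""
        ari = adjusted_rand_score(truth_labels[planted], labels[planted])
        assert ari >= 0.9, f"seed {seed}: ARI {ari:.3f}"
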