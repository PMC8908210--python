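"""Pareto scaling, PCA, clustering, and OPLS-DA VIP."""

import numpy as np
import pandas as pd
import pytest

from equiomics import synthetic
from equiomics.multivariate import hcluster, oplsda_vip, pareto_scale, pca


def _df(array, features=None, samples=None):
    a = np.asarray(array, dtype=float)
    features = features or [f"f{i}" for i in range(a.shape[0])]
    samples = samples or [f"s{i}" for i in range(a.shape[1])]
    return pd.DataFrame(a, index=features, columns=samples)


class TestPareto:
    def test_hand_example(self):
        scaled = pareto_scale(_df([[1, 2, 3]]))
        # mean 2, sample sd 1, sqrt(sd) 1
        assert np.allclose(scaled.values.to_numpy(), [[-1, 0, 1]])

    def test_constant_feature_flagged_zeros(self):
        scaled = pareto_scale(_df([[5, 5, 5], [1, 2, 3]]))
        assert scaled.zero_variance == ("f0",)
        assert np.allclose(scaled.values.loc["f0"], 0.0)

    def test_recomposition_reproduces_input(self, rng):
        data = _df(rng.lognormal(3, 1, size=(30, 9)))
        scaled = pareto_scale(data)
        assert np.allclose(scaled.recompose().to_numpy(), data.to_numpy(), atol=1e-9)

    def test_missing_policies(self):
        data = _df([[1.0, np.nan, 3.0]])
        with pytest.raises(ValueError):
            pareto_scale(data)
        assert not pareto_scale(data, missing="mean").values.isna().any().any()
        assert not pareto_scale(data, missing="halfmin").values.isna().any().any()


class TestPCA:
    def test_collinear_samples_single_component(self, rng):
        t = rng.normal(size=8)
        direction = rng.normal(size=5)
        data = _df(np.outer(direction, t))  # 5 features x 8 samples on a line
        model = pca(data, n_components=1)
        assert model.explained_variance[0] == pytest.approx(1.0)

    def test_two_equal_variance_directions(self):
        # four samples at (+-1, 0) and (0, +-1): symmetric 50/50 split
        data = _df([[1, -1, 0, 0], [0, 0, 1, -1]])
        model = pca(data, n_components=2)
        assert np.allclose(model.explained_variance, [0.5, 0.5])

    def test_explained_variance_sums_to_one(self, rng):
        data = _df(rng.normal(size=(12, 7)))
        model = pca(data, n_components=6)  # rank of 7 centered samples
        assert model.explained_variance.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(model.explained_variance) <= 1e-12)

    def test_sign_is_deterministic(self, rng):
        data = _df(rng.normal(size=(10, 6)))
        m1, m2 = pca(data), pca(data)
        pd.testing.assert_frame_equal(m1.scores, m2.scores)
        for comp in m1.loadings:
            col = m1.loadings[comp]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0

    def test_rank_truncation_warns(self):
        data = _df([[1, 2, 3], [2, 4, 6]])  # rank 1 after centering
        with pytest.warns(UserWarning):
            model = pca(data, n_components=3)
        assert model.scores.shape[1] <= 2

    def test_background_split_separates_breeding_groups(self, design):
        matrix, _ = synthetic.gen_expression_study(design, 300, seed=21)
        model = pca(np.log2(matrix.data + 1), n_components=2)
        pc1 = model.scores["PC1"]
        conv = [s for s in pc1.index if design.role(design.line_of(s)) == "conventional"]
        rest = [s for s in pc1.index if s not in conv]
        # conventional lines separate from GE lines + parent on PC1
        assert (pc1[conv].min() > pc1[rest].max()) or (pc1[conv].max() < pc1[rest].min())


class TestHCluster:
    def test_identical_profiles_merge_at_zero(self):
        data = _df([[1, 1, 9], [2, 2, 5], [3, 3, 1]], samples=["a", "b", "c"])
        dendro = hcluster(data)
        assert dendro.heights[0] == pytest.approx(0.0)

    def test_outlier_merges_last(self):
        import scipy.cluster.hierarchy as h

        data = _df([[0.0, 0.1, 50.0], [0.0, 0.1, 50.0]], samples=["a", "b", "out"])
        dendro = hcluster(data)
        assert dendro.heights[-1] > dendro.heights[0]
        clusters = h.fcluster(dendro.linkage, t=2, criterion="maxclust")
        partition = {frozenset(np.array(dendro.labels)[clusters == c])
                     for c in set(clusters)}
        assert partition == {frozenset({"a", "b"}), frozenset({"out"})}

    def test_column_order_invariance(self, rng):
        data = _df(rng.normal(size=(20, 6)), samples=list("fbdace"))
        shuffled = data[list("abcdef")]
        assert hcluster(data).to_newick() == hcluster(shuffled).to_newick()

    def test_ge_and_parent_form_one_subtree(self, design):
        matrix, _ = synthetic.gen_expression_study(design, 300, seed=22)
        means = np.log2(matrix.data + 1).T.groupby(design.line_of).mean().T
        dendro = hcluster(means, distance="correlation")
        # cutting at two clusters isolates the conventional lines, leaving
        # the GE lines plus parent in one subtree
        import scipy.cluster.hierarchy as h

        clusters = h.fcluster(dendro.linkage, t=2, criterion="maxclust")
        groups = {}
        for lab, cl in zip(dendro.labels, clusters):
            groups.setdefault(cl, set()).add(lab)
        assert {"AR02", "AR03"} in groups.values()

    def test_nan_distance_rejected(self):
        data = _df([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            hcluster(data)


class TestOPLSDA:
    def test_single_feature_vip_is_one(self):
        data = _df([[1.0, 2.0, 3.0, 4.0]], samples=["a1", "a2", "b1", "b2"])
        model = oplsda_vip(data, {"a1": "a", "a2": "a", "b1": "b", "b2": "b"},
                           n_orthogonal=0)
        assert model.vip.iloc[0] == pytest.approx(1.0)

    def test_vip_mean_square_is_one(self, rng, design):
        matrix, _ = synthetic.gen_metabolome_study(design, 80, seed=23)
        scaled = pareto_scale(matrix.data)
        classes = {
            s: design.role(design.line_of(s)) == "conventional"
            for s in matrix.data.columns
        }
        model = oplsda_vip(scaled.values, classes)
        assert (model.vip**2).mean() == pytest.approx(1.0, abs=1e-9)

    def test_discriminating_feature_outranks_noise(self, rng):
        n = 12
        y = np.array([0] * 6 + [1] * 6)
        signal = y * 4.0 + rng.normal(0, 0.1, n)
        noise = rng.normal(0, 1.0, n)
        data = _df(np.vstack([signal, noise]),
                   features=["signal", "noise"],
                   samples=[f"s{i}" for i in range(n)])
        model = oplsda_vip(data, ["a"] * 6 + ["b"] * 6, n_orthogonal=1)
        assert model.vip["signal"] > 1.0 > model.vip["noise"]

    def test_predictive_weights_match_pls_reference(self, rng):
        """With zero orthogonal components the predictive weights equal a
        plain PLS-DA first component (independent implementation)."""
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(10, 6))
        y = np.array([0.0] * 5 + [1.0] * 5)
        data = _df(X.T, samples=[f"s{i}" for i in range(10)])
        model = oplsda_vip(data, ["a"] * 5 + ["b"] * 5, n_orthogonal=0)
        ref = PLSRegression(n_components=1, scale=False).fit(
            X - X.mean(axis=0), y - y.mean()
        )
        w_ref = ref.x_weights_[:, 0]
        w_ours = model.vip.to_numpy() / np.sqrt(len(model.vip))
        # |w| agreement (VIP = sqrt(p)*|w| for one component)
        assert np.allclose(w_ours, np.abs(w_ref), atol=1e-8)

    def test_single_class_rejected(self):
        data = _df(np.ones((3, 4)))
        with pytest.raises(ValueError):
            oplsda_vip(data, ["a", "a", "a", "a"])

    def test_shuffled_labels_null_vip_normalized(self, rng, design):
        """Permutation null: VIPs stay normalized (mean square 1) and no
        feature dominates; the median of sqrt(p)*|w| for an isotropic unit
        weight vector is ~0.67."""
        matrix, _ = synthetic.gen_metabolome_study(
            design, 60, background_fraction=0.0, seed=24
        )
        scaled = pareto_scale(matrix.data)
        labels = ["a", "b"] * 9
        rng.shuffle(labels)
        model = oplsda_vip(scaled.values, labels)
        assert (model.vip**2).mean() == pytest.approx(1.0, abs=1e-9)
        assert 0.3 < np.median(model.vip) < 1.2
        assert model.vip.max() < np.sqrt(len(model.vip))  # normalization bound
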