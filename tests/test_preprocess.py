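import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iqgrn.preprocess import (ExpressionBinarizer, KnnDiffusionImputer,
                              binarize, expression_density, impute)

from conftest import make_binarized, make_dataset


class TestImpute:
    def test_t_zero_is_identity(self):
        ds = make_dataset(np.random.default_rng(0).random((6, 3)))
        out = impute(ds, k_neighbors=2, diffusion_t=0)
        np.testing.assert_array_equal(out.values, ds.values)

    def test_constant_gene_unchanged(self):
        rng = np.random.default_rng(1)
        vals = rng.random((10, 2))
        vals[:, 1] = 0.7
        out = impute(make_dataset(vals), k_neighbors=3, diffusion_t=2,
                     zeros_only=False)
        np.testing.assert_allclose(out.values[:, 1], 0.7)

    def test_duplicate_cells_zero_pulled_toward_neighbor(self):
        # two near-duplicate cells; one has a zeroed (dropout) entry
        vals = np.array([[1.0, 2.0], [1.0, 0.0], [5.0, 6.0], [5.0, 6.0]])
        out = impute(make_dataset(vals), k_neighbors=1, diffusion_t=1)
        assert out.values[1, 1] > 0.0
        assert out.values[1, 1] <= 2.0

    def test_k_too_large_fatal(self):
        ds = make_dataset(np.ones((3, 2)))
        with pytest.raises(ValueError, match="smaller than n_cells"):
            impute(ds, k_neighbors=3, diffusion_t=1)

    def test_full_smoothing_preserves_range_and_sign(self):
        rng = np.random.default_rng(2)
        ds = make_dataset(rng.random((20, 4)))
        out = impute(ds, k_neighbors=5, diffusion_t=3, zeros_only=False)
        assert (out.values >= 0).all()
        for j in range(4):
            assert out.values[:, j].min() >= ds.values[:, j].min() - 1e-12
            assert out.values[:, j].max() <= ds.values[:, j].max() + 1e-12

    def test_zeros_only_leaves_observed_values_untouched(self):
        rng = np.random.default_rng(3)
        vals = rng.random((15, 3)) + 0.5
        vals[rng.random((15, 3)) < 0.3] = 0.0
        ds = make_dataset(vals)
        out = impute(ds, k_neighbors=4, diffusion_t=2)
        nz = vals > 0
        np.testing.assert_array_equal(out.values[nz], vals[nz])

    def test_sklearn_transformer_matches_function(self):
        rng = np.random.default_rng(4)
        X = rng.random((12, 3))
        est = KnnDiffusionImputer(k_neighbors=4, diffusion_t=2).fit(X)
        out = est.transform(X)
        ref = impute(make_dataset(X), 4, 2, zeros_only=False)
        np.testing.assert_allclose(out, ref.values)


class TestBinarize:
    def test_two_point_gene(self):
        b = binarize(make_dataset(np.array([[0.], [0.], [10.], [10.]])))
        assert b.mu_off[0] == 0 and b.mu_on[0] == 10 and b.thresholds[0] == 5
        np.testing.assert_array_equal(b.calls.ravel(), [0, 0, 1, 1])

    def test_exhaustive_split_example(self):
        b = binarize(make_dataset(np.array([[1.], [2.], [8.], [9.], [10.]])))
        assert b.mu_off[0] == pytest.approx(1.5)
        assert b.mu_on[0] == pytest.approx(9.0)
        assert b.thresholds[0] == pytest.approx(5.25)
        np.testing.assert_array_equal(b.calls.ravel(), [0, 0, 1, 1, 1])

    def test_constant_gene_rules(self):
        b = binarize(make_dataset(np.array([[3.0, 0.0]] * 4)))
        np.testing.assert_array_equal(b.calls[:, 0], 1)
        np.testing.assert_array_equal(b.calls[:, 1], 0)
        assert b.thresholds[0] == 3.0

    def test_mean_method(self):
        b = binarize(make_dataset(np.array([[0.], [0.], [10.], [10.]])),
                     method="mean")
        assert b.thresholds[0] == 5.0
        np.testing.assert_array_equal(b.calls.ravel(), [0, 0, 1, 1])

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(0.2, 0.02, 20),
                               rng.normal(3.0, 0.3, 30)])
        perm = rng.permutation(50)
        b1 = binarize(make_dataset(vals[:, None]))
        b2 = binarize(make_dataset(vals[perm][:, None]))
        np.testing.assert_array_equal(b1.calls.ravel()[perm],
                                      b2.calls.ravel())

    def test_threshold_between_centroids(self):
        rng = np.random.default_rng(6)
        vals = rng.random((30, 5)) * 4
        b = binarize(make_dataset(vals))
        assert (b.mu_off <= b.thresholds).all()
        assert (b.thresholds <= b.mu_on).all()

    def test_unimodal_always_on_gene_called_on(self):
        # one constitutive gene amid bimodal genes: its sampling noise must
        # not be split in half
        rng = np.random.default_rng(7)
        on = np.exp(rng.normal(np.log(3.0), 0.25, 200))
        bi = np.where(rng.random(200) < 0.5,
                      np.exp(rng.normal(np.log(3.0), 0.25, 200)),
                      np.exp(rng.normal(np.log(0.2), 0.25, 200)))
        ds = make_dataset(np.log1p(np.column_stack([on, bi])))
        b = binarize(ds)
        assert b.calls[:, 0].mean() > 0.95

    def test_sklearn_binarizer_transform(self):
        X = np.array([[0.], [0.], [10.], [10.]])
        est = ExpressionBinarizer().fit(X)
        np.testing.assert_array_equal(est.transform([[4.0], [6.0]]).ravel(),
                                      [0, 1])


class TestExpressionDensity:
    def test_all_on_gives_unit_density(self):
        d = expression_density(make_binarized(np.ones((6, 1))), window=3)
        np.testing.assert_allclose(d.values, 1.0)

    def test_step_with_truncated_ends(self):
        calls = np.array([[0], [0], [0], [1], [1], [1]])
        d = expression_density(make_binarized(calls), window=3)
        np.testing.assert_allclose(
            d.values.ravel(), [0, 0, 1 / 3, 2 / 3, 1, 1])

    def test_auto_window_is_cells_over_genes(self):
        calls = np.zeros((1500, 15), dtype=np.int8)
        d = expression_density(make_binarized(calls), window="auto")
        assert d.window == 100

    def test_window_one_is_identity(self):
        rng = np.random.default_rng(8)
        calls = (rng.random((20, 3)) < 0.5).astype(np.int8)
        d = expression_density(make_binarized(calls), window=1)
        np.testing.assert_array_equal(d.values, calls)

    def test_oversized_window_clamped(self, caplog):
        with caplog.at_level("WARNING"):
            d = expression_density(make_binarized(np.ones((4, 1))), window=10)
        assert d.window == 4

    @given(st.integers(1, 7), st.integers(0, 2 ** 10 - 1))
    @settings(max_examples=30, deadline=None)
    def test_density_bounded_and_mass_preserving_inside(self, window, bits):
        calls = np.array([(bits >> i) & 1 for i in range(10)])[:, None]
        d = expression_density(make_binarized(calls), window=window)
        assert (d.values >= 0).all() and (d.values <= 1).all()
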