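"""Shape PCA, variance decomposition, size tests and allometry."""

import itertools

import numpy as np
import pandas as pd
import pytest

from molargm import (ValidationError, allometry_regression, gpa, pca_shapes,
                     reconstruct_shape, size_tests, variance_decomposition)
from molargm.simulate import GroupSpec, SimulationDesign, simulate_dataset


@pytest.fixture()
def aligned_sample(small_template, rng):
    pts = small_template.points
    stack = pts[None] + rng.normal(0, 0.03, size=(12, *pts.shape))
    return gpa(stack)


class TestPCA:
    def test_rank_one_data_pc1_explains_everything(self, rng):
        mean = rng.normal(size=10)
        v = rng.normal(size=10)
        t = rng.normal(size=(8, 1))
        data = mean + t * v
        space = pca_shapes(data)
        assert space.variance_proportions[0] == pytest.approx(1.0, abs=1e-9)

    def test_variance_proportions_sum_to_one(self, aligned_sample):
        space = pca_shapes(aligned_sample)
        assert space.variance_proportions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.abs(space.scores.mean(0)).max() < 1e-9

    def test_eigenvalues_match_covariance_eigendecomposition(self, rng):
        data = rng.normal(size=(10, 6))
        space = pca_shapes(data)
        cov = np.cov(data, rowvar=False)
        expected = np.sort(np.linalg.eigvalsh(cov))[::-1][: space.n_components]
        np.testing.assert_allclose(space.eigenvalues, expected, atol=1e-8)

    def test_reconstruction_of_centred_data(self, aligned_sample):
        space = pca_shapes(aligned_sample)
        flat = aligned_sample.tangent_coordinates()
        recon = flat.mean(0) + space.scores @ space.eigenvectors
        np.testing.assert_allclose(recon, flat, atol=1e-8)

    def test_order_invariance(self, aligned_sample, rng):
        space1 = pca_shapes(aligned_sample)
        perm = rng.permutation(aligned_sample.n)
        shuffled = pca_shapes(aligned_sample.tangent_coordinates()[perm])
        np.testing.assert_allclose(space1.eigenvalues, shuffled.eigenvalues, atol=1e-9)
        np.testing.assert_allclose(space1.eigenvectors, shuffled.eigenvectors, atol=1e-8)

    def test_too_few_specimens(self, rng):
        with pytest.raises(ValidationError):
            pca_shapes(rng.normal(size=(2, 8)))


class TestReconstructShape:
    def test_score_zero_is_mean(self, aligned_sample):
        space = pca_shapes(aligned_sample)
        np.testing.assert_array_equal(reconstruct_shape(space, 0, 0.0), space.mean_shape)

    def test_specimen_full_score_vector_recovers_specimen(self, aligned_sample):
        space = pca_shapes(aligned_sample)
        i = 3
        flat = space.scores[i] @ space.eigenvectors
        k = space.k
        recon = space.mean_shape + np.column_stack([flat[:k], flat[k:]])
        target = aligned_sample.tangent_coordinates()[i]
        np.testing.assert_allclose(
            np.concatenate([recon[:, 0], recon[:, 1]]), target, atol=1e-8)

    def test_plus_minus_scores_symmetric_about_mean(self, aligned_sample):
        space = pca_shapes(aligned_sample)
        plus = reconstruct_shape(space, 1, 0.3)
        minus = reconstruct_shape(space, 1, -0.3)
        np.testing.assert_allclose(
            (plus + minus) / 2, space.mean_shape, atol=1e-10)

    def test_unknown_component(self, aligned_sample):
        space = pca_shapes(aligned_sample)
        with pytest.raises(ValidationError):
            reconstruct_shape(space, space.n_components + 5, 1.0)


class TestVarianceDecomposition:
    def test_perfect_separation_explains_everything(self):
        y = np.repeat(np.array([[0.0, 0.0], [1.0, 2.0]]), 5, axis=0)
        groups = pd.DataFrame({"g": ["a"] * 5 + ["b"] * 5})
        dec = variance_decomposition(y, groups, n_perm=99, seed=0)
        assert dec.terms.loc["g", "percent_variation"] == pytest.approx(100, abs=1e-9)
        # only partition-preserving permutations can tie the observed F
        assert 1 / 100 <= dec.terms.loc["g", "p"] <= 5 / 100

    def test_percent_rows_total_100(self, aligned_sample, rng):
        factors = pd.DataFrame({
            "a": rng.choice(["x", "y"], size=aligned_sample.n),
            "b": list("pq") * (aligned_sample.n // 2),
        })
        dec = variance_decomposition(aligned_sample, factors, n_perm=99, seed=1)
        assert dec.terms["percent_variation"].sum() == pytest.approx(100, abs=1e-6)
        assert (dec.terms["p"].dropna() >= 1 / 100).all()

    def test_exhaustive_enumeration_matches_independent_oracle(self, rng):
        """n=6, one two-level factor: the 720-permutation p equals an
        independent enumeration of the F statistic over label permutations."""
        y = rng.normal(size=(6, 3))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        dec = variance_decomposition(y, pd.DataFrame({"g": labels}), n_perm=719, seed=0)
        assert dec.exhaustive

        yc = y - y.mean(0)

        def f_stat(lab):
            ss_b = 0.0
            fit = np.zeros_like(yc)
            for g in ("a", "b"):
                m = lab == g
                fit[m] = yc[m].mean(0)
            ss_b = (fit ** 2).sum()
            ss_w = ((yc - fit) ** 2).sum()
            return (ss_b / 1) / (ss_w / 4)

        f_obs = f_stat(labels)
        count = sum(
            f_stat(labels[list(perm)]) >= f_obs - 1e-12
            for perm in itertools.permutations(range(6))
        )
        assert dec.terms.loc["g", "p"] == pytest.approx(count / 720, abs=1e-12)

    def test_single_level_factor_rejected(self, rng):
        y = rng.normal(size=(6, 3))
        with pytest.raises(ValidationError):
            variance_decomposition(y, pd.DataFrame({"g": ["a"] * 6}), n_perm=99)

    def test_order_invariance_of_percent(self, rng):
        y = rng.normal(size=(20, 4))
        labels = pd.DataFrame({"g": list("ab") * 10})
        d1 = variance_decomposition(y, labels, n_perm=99, seed=3)
        perm = rng.permutation(20)
        d2 = variance_decomposition(y[perm], labels.iloc[perm].reset_index(drop=True),
                                    n_perm=99, seed=3)
        assert d1.terms.loc["g", "percent_variation"] == pytest.approx(
            d2.terms.loc["g", "percent_variation"], abs=1e-9)


class TestSizeTests:
    def test_exact_wilcoxon_worked_example(self):
        sizes = np.exp([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        report = size_tests(sizes, ["a", "a", "a", "b", "b", "b"])
        assert report.pairwise_p.loc["a", "b"] == pytest.approx(0.10, abs=1e-12)

    def test_identical_groups_with_ties(self):
        sizes = np.exp([5.0, 6.0, 7.0, 5.0, 6.0, 7.0])
        report = size_tests(sizes, ["a", "a", "a", "b", "b", "b"])
        assert report.pairwise_p.loc["a", "b"] == pytest.approx(1.0)
        assert report.adjusted_p.loc["a", "b"] == pytest.approx(1.0)

    def test_bh_adjustment_invariants(self, rng):
        sizes = np.exp(rng.normal(1, 0.3, size=24))
        groups = np.repeat(["a", "b", "c", "d"], 6)
        report = size_tests(sizes, groups)
        raw, adj = report.pairwise_p, report.adjusted_p
        assert (adj.values >= raw.values - 1e-12).all()
        assert (adj.values <= 1 + 1e-12).all()
        np.testing.assert_allclose(adj.values, adj.values.T)
        # BH preserves the ordering of the raw p-values
        pairs = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("b", "d"), ("c", "d")]
        rawv = np.array([raw.loc[a, b] for a, b in pairs])
        adjv = np.array([adj.loc[a, b] for a, b in pairs])
        order = np.argsort(rawv)
        assert (np.diff(adjv[order]) >= -1e-12).all()

    def test_small_group_excluded_with_warning(self):
        sizes = np.exp([1.0, 2, 3, 4, 5])
        with pytest.warns(UserWarning, match="excluded"):
            report = size_tests(sizes, ["a", "a", "b", "b", "c"])
        assert report.groups == ["a", "b"]


class TestAllometry:
    def _allometric_sample(self, small_template, slope):
        design = SimulationDesign(
            template=small_template,
            groups={"g": GroupSpec("tarandus", "wild_mountain", base_size=10.0)},
            wear_classes=(2,), wear_magnitude_per_class=0.0, sexes=("F",),
            allometry_magnitude=slope, noise_sd=0.0 if slope else 0.004,
            size_cv=0.2, n_per_cell=30, seed=7,
        )
        ds, _ = simulate_dataset(design)
        return gpa(ds)

    def test_exact_linear_relation(self, small_template):
        aligned = self._allometric_sample(small_template, slope=0.1)
        res = allometry_regression(aligned, n_perm=199, seed=0)
        assert res.r_squared > 0.99
        assert res.p_value == pytest.approx(1 / 200)

    def test_coefficients_match_normal_equations(self, small_template):
        aligned = self._allometric_sample(small_template, slope=0.0)
        res = allometry_regression(aligned, n_perm=9, seed=0)
        y = aligned.tangent_coordinates()
        y = y - y.mean(0)
        x = np.log(aligned.centroid_sizes)
        xc = x - x.mean()
        beta = np.linalg.lstsq(xc[:, None], y, rcond=None)[0][0]
        np.testing.assert_allclose(res.coefficients, beta, atol=1e-8)

    def test_constant_sizes_rejected(self, small_template, rng):
        aligned = self._allometric_sample(small_template, slope=0.0)
        aligned.centroid_sizes[:] = 2.0
        with pytest.raises(ValidationError):
            allometry_regression(aligned)
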