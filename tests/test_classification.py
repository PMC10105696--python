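"""CVA, leave-one-out classification and archaeological assignment."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg as sla
from scipy.stats import multivariate_normal

from molargm import (CVA, ValidationError, classify_unknowns, cva_fit, gpa,
                     loo_cross_validate, pca_shapes, project_unknowns,
                     retain_components, summarize_assignments)
from molargm.shape_stats import ShapeSpace


def _space_from_props(props):
    props = np.asarray(props, dtype=float)
    n_comp = len(props)
    return ShapeSpace(
        mean_shape=np.zeros((4, 2)),
        eigenvectors=np.eye(n_comp, 8),
        eigenvalues=props,
        variance_proportions=props,
        scores=np.random.default_rng(0).normal(size=(10, n_comp)),
    )


class TestRetainComponents:
    def test_worked_example(self):
        space = _space_from_props([0.60, 0.30, 0.08, 0.02])
        _, n = retain_components(space, 0.95)
        assert n == 3

    def test_threshold_one_keeps_all(self):
        space = _space_from_props([0.60, 0.30, 0.08, 0.02])
        _, n = retain_components(space, 1.0)
        assert n == 4

    def test_default_threshold_is_95_percent(self):
        import inspect

        sig = inspect.signature(retain_components)
        assert sig.parameters["threshold"].default == 0.95

    def test_monotone_in_threshold(self):
        space = _space_from_props([0.4, 0.3, 0.2, 0.07, 0.03])
        counts = [retain_components(space, t)[1] for t in (0.3, 0.5, 0.7, 0.9, 0.99, 1.0)]
        assert counts == sorted(counts)
        assert counts[0] >= 1


class TestCVA:
    def test_two_groups_one_axis(self, rng):
        scores = rng.normal(size=(20, 5))
        res = cva_fit(scores, ["a"] * 10 + ["b"] * 10)
        assert res.n_axes == 1

    def test_identity_covariance_gives_euclidean_mahalanobis(self, rng):
        # construct data whose pooled within-group covariance is exactly I
        base = rng.normal(size=(40, 3))
        labels = np.array(["a", "b"] * 20)
        for g in ("a", "b"):
            block = base[labels == g]
            block -= block.mean(0)
            cov = block.T @ block
            base[labels == g] = block @ np.linalg.inv(sla.sqrtm(cov).real) * np.sqrt(38 / 2)
        offset = np.array([1.3, -0.4, 2.0])
        base[labels == "b"] += offset
        res = cva_fit(base, labels)
        assert res.mahalanobis.loc["a", "b"] == pytest.approx(
            np.linalg.norm(offset), abs=1e-9)

    def test_axes_match_generalized_eigen_oracle(self, rng):
        scores = rng.normal(size=(60, 4))
        labels = np.repeat(["a", "b", "c"], 20)
        scores[labels == "b"] += [1.0, 0, 0.5, 0]
        scores[labels == "c"] += [0, 1.5, 0, -0.5]
        res = cva_fit(scores, labels)

        groups, means, pooled = (
            res.groups, res.means, res.pooled_covariance)
        grand = scores.mean(0)
        between = sum(
            (labels == g).sum() * np.outer(means[g] - grand, means[g] - grand)
            for g in groups
        ) / 2
        evals, evecs = sla.eig(np.linalg.inv(pooled) @ between)
        order = np.argsort(evals.real)[::-1][:2]
        for j, col in enumerate(order):
            v = evecs[:, col].real
            v = v / np.sqrt(v @ pooled @ v)
            agreement = abs(v @ pooled @ res.axes[:, j])
            assert agreement == pytest.approx(1.0, abs=1e-7)

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValidationError):
            CVA(rng.normal(size=(10, 2)), ["a"] * 10)

    def test_summary_mentions_groups_and_accuracy(self, rng):
        scores = rng.normal(size=(24, 3))
        scores[12:] += 8.0
        text = cva_fit(scores, ["a"] * 12 + ["b"] * 12).summary()
        assert "Mahalanobis" in text and "accuracy" in text


class TestLOOCrossValidation:
    def test_huge_separation_is_perfect(self, rng):
        scores = rng.normal(size=(30, 3))
        scores[15:] += 20.0
        report = loo_cross_validate(scores, ["a"] * 15 + ["b"] * 15)
        assert report.overall_accuracy == 100.0
        assert report.confusion.loc["a"].sum() == 15

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(2024)
        scores = rng.normal(size=(100, 4))
        labels = np.array(["a", "b"] * 50)
        report = loo_cross_validate(scores, labels)
        # central 99% binomial band around 50% for n=100
        assert 37.0 <= report.overall_accuracy <= 63.0

    def test_matches_brute_force_refit_oracle(self, rng):
        """Confusion identical to a literal refit-per-held-out-specimen script
        using scipy Gaussian densities."""
        scores = rng.normal(size=(12, 2))
        labels = np.array(["a"] * 4 + ["b"] * 4 + ["c"] * 4)
        scores[labels == "b"] += [2.0, 0]
        scores[labels == "c"] += [0, 2.0]
        report = loo_cross_validate(scores, labels)

        names = ["a", "b", "c"]
        confusion = pd.DataFrame(0, index=names, columns=names)
        for i in range(12):
            mask = np.ones(12, dtype=bool)
            mask[i] = False
            x, lab = scores[mask], labels[mask]
            pooled = np.zeros((2, 2))
            means = {}
            for g in names:
                block = x[lab == g]
                means[g] = block.mean(0)
                pooled += (block - means[g]).T @ (block - means[g])
            pooled /= len(x) - 3
            dens = [multivariate_normal.pdf(scores[i], means[g], pooled) for g in names]
            confusion.loc[labels[i], names[int(np.argmax(dens))]] += 1
        pd.testing.assert_frame_equal(report.confusion, confusion)

    def test_row_sums_equal_group_sizes(self, rng):
        scores = rng.normal(size=(18, 3))
        labels = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        report = loo_cross_validate(scores, labels)
        assert report.confusion.sum(axis=1).tolist() == [6, 6, 6]


class TestClassifyUnknowns:
    def test_unknown_at_group_mean(self, rng):
        scores = rng.normal(size=(20, 2))
        labels = ["a"] * 10 + ["b"] * 10
        scores = np.asarray(scores)
        scores[10:] += 6.0
        mean_a = scores[:10].mean(0)
        report = classify_unknowns(scores, labels, mean_a)
        row = report.assignments.iloc[0]
        assert row["assigned"] == "a"
        assert row["p_a"] > 0.99

    def test_midpoint_posteriors_half_half(self, rng):
        scores = rng.normal(size=(40, 2))
        labels = np.array(["a", "b"] * 20)
        scores[labels == "b"] += [3.0, 1.0]
        midpoint = (scores[labels == "a"].mean(0) + scores[labels == "b"].mean(0)) / 2
        report = classify_unknowns(scores, labels, midpoint)
        row = report.assignments.iloc[0]
        assert row["p_a"] == pytest.approx(0.5, abs=1e-9)
        assert row["tie"]

    def test_posteriors_match_density_oracle(self, rng):
        scores = rng.normal(size=(10, 2))
        labels = ["a"] * 5 + ["b"] * 5
        scores = np.asarray(scores)
        scores[5:] += [1.0, -0.5]
        unknowns = rng.normal(size=(5, 2))
        report = classify_unknowns(scores, labels, unknowns)

        pooled = np.zeros((2, 2))
        means = {}
        for g, sl in (("a", slice(0, 5)), ("b", slice(5, 10))):
            block = scores[sl]
            means[g] = block.mean(0)
            pooled += (block - means[g]).T @ (block - means[g])
        pooled /= 8
        for i in range(5):
            dens = np.array([
                multivariate_normal.pdf(unknowns[i], means[g], pooled) for g in ("a", "b")
            ])
            post = dens / dens.sum()
            assert report.assignments.iloc[i]["p_a"] == pytest.approx(post[0], abs=1e-9)

    def test_mahalanobis_affine_invariance(self, rng):
        scores = rng.normal(size=(30, 3))
        labels = ["a"] * 15 + ["b"] * 15
        scores = np.asarray(scores)
        scores[15:] += [1.0, 0.5, -0.2]
        unknowns = rng.normal(size=(6, 3))
        a = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        shift = rng.normal(size=3)
        r1 = classify_unknowns(scores, labels, unknowns)
        r2 = classify_unknowns(scores @ a + shift, labels, unknowns @ a + shift)
        np.testing.assert_allclose(
            r1.assignments[["p_a", "p_b"]].to_numpy(),
            r2.assignments[["p_a", "p_b"]].to_numpy(), atol=1e-7)

    def test_agrees_with_sklearn_lda(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        scores = rng.normal(size=(60, 4))
        labels = np.repeat(["a", "b", "c"], 20)
        scores[labels == "b"] += [1.5, 0, 0, 0]
        scores[labels == "c"] += [0, 1.5, 0, 0.5]
        unknowns = rng.normal(size=(25, 4)) + [0.7, 0.7, 0, 0.2]
        mine = classify_unknowns(scores, labels, unknowns).assignments["assigned"]
        lda = LinearDiscriminantAnalysis(priors=[1 / 3] * 3).fit(scores, labels)
        assert mine.tolist() == lda.predict(unknowns).tolist()

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValidationError):
            classify_unknowns(rng.normal(size=(10, 3)), ["a"] * 5 + ["b"] * 5,
                              rng.normal(size=(2, 2)))


class TestProjectUnknowns:
    @pytest.fixture()
    def trained(self, small_template, rng):
        pts = small_template.points
        stack = pts[None] + rng.normal(0, 0.03, size=(15, *pts.shape))
        aligned = gpa(stack)
        space = pca_shapes(aligned)
        return stack, aligned, space

    def test_consensus_projects_to_zero(self, trained):
        _, aligned, space = trained
        scores = project_unknowns(aligned, space, aligned.consensus[None])
        mean_offset = np.linalg.norm(
            np.concatenate([space.mean_shape[:, 0], space.mean_shape[:, 1]])
            - np.concatenate([aligned.consensus[:, 0], aligned.consensus[:, 1]]))
        assert np.abs(scores).max() <= 1e-9 + mean_offset

    def test_training_specimen_recovers_its_scores(self, trained, rng):
        stack, aligned, space = trained
        i = 4
        # original raw configuration, re-rotated and scaled arbitrarily
        th = rng.uniform(0, 2 * np.pi)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        raw = stack[i] @ rot.T * 2.3 + [5.0, -1.0]
        scores = project_unknowns(aligned, space, raw[None])
        np.testing.assert_allclose(scores[0], space.scores[i], atol=1e-6)

    def test_rotation_invariance(self, trained, rng):
        stack, aligned, space = trained
        unknown = stack[7] + rng.normal(0, 0.01, stack[7].shape)
        rot90 = np.array([[0.0, -1.0], [1.0, 0.0]])
        s1 = project_unknowns(aligned, space, unknown[None])
        s2 = project_unknowns(aligned, space, (unknown @ rot90.T)[None])
        np.testing.assert_allclose(s1, s2, atol=1e-9)


class TestSummarizeAssignments:
    def test_single_assignment(self):
        df = pd.DataFrame({"assigned": ["mountain"]})
        out = summarize_assignments(df)
        assert out.loc[0, "percent"] == 100.0

    def test_per_site_percentages(self):
        # Markkina, both molars pooled: 40 mountain vs 4 forest reindeer
        df = pd.DataFrame({
            "assigned": ["mountain"] * 40 + ["forest"] * 4,
            "site": ["Markkina"] * 44,
        })
        out = summarize_assignments(df, by=["site"]).set_index("assigned")
        assert out.loc["mountain", "percent"] == pytest.approx(100 * 40 / 44)
        assert out.loc["mountain", "percent_rounded"] == 91
        assert out.loc["forest", "percent_rounded"] == 9

    def test_stratified_totals(self):
        df = pd.DataFrame({
            "assigned": ["mountain", "forest", "mountain", "mountain"],
            "site": ["A", "A", "B", "B"],
            "tooth": ["m1", "m1", "m1", "m2"],
        })
        out = summarize_assignments(df, by=["site", "tooth"])
        assert out["n"].sum() == 4
        block = out[(out["site"] == "B") & (out["tooth"] == "m1")]
        assert block["percent"].tolist() == [100.0]
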