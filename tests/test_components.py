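"""Gaussian components, evidence and posterior computation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from robustbayes import (BayesModel, GaussianComponent, evidence, gaussian_pdf,
                         posteriors)
from robustbayes.fitting import fit_from_labeled

from conftest import random_model

# independently computed with 25-digit symbolic evaluation of the normal
# density formula (frozen oracle values)
PDF_GIRLS_AT_151 = 0.08525176717923902
EVIDENCE_HEIGHTS_AT_155 = 2.960670081722779e-14
POST_GIRLS_AT_151_5 = 0.019792247193379430


class TestGaussianPdf:
    def test_standard_normal_at_mean(self):
        comp = GaussianComponent("z", 0.0, 1.0, 1.0)
        assert gaussian_pdf(comp, 0.0) == pytest.approx(1 / np.sqrt(2 * np.pi),
                                                        rel=1e-12)

    def test_symmetry_about_mean(self):
        comp = GaussianComponent("g", 149.8081, 0.5843, 1.0)
        for a in (0.1, 0.5, 1.7, 4.0):
            assert gaussian_pdf(comp, 149.8081 + a) == pytest.approx(
                gaussian_pdf(comp, 149.8081 - a), rel=1e-12
            )

    def test_against_high_precision_oracle(self):
        comp = GaussianComponent("girls", 149.8081, 0.5843, 1.0)
        assert gaussian_pdf(comp, 151.0) == pytest.approx(PDF_GIRLS_AT_151,
                                                          rel=1e-12)

    def test_strictly_positive_far_out(self):
        comp = GaussianComponent("z", 0.0, 1.0, 1.0)
        assert gaussian_pdf(comp, 8.0) > 0.0

    def test_dimension_mismatch_rejected(self):
        comp = GaussianComponent("a", [0.0, 0.0], np.eye(2), 1.0)
        with pytest.raises(ValueError):
            comp.log_density(np.zeros((3, 3)))

    def test_multivariate_matches_scipy(self):
        from scipy.stats import multivariate_normal

        rng = np.random.default_rng(7)
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        comp = GaussianComponent("m", [1.0, -2.0], cov, 1.0)
        X = rng.normal(0, 3, size=(50, 2))
        expected = multivariate_normal([1.0, -2.0], cov).pdf(X)
        np.testing.assert_allclose(comp.density(X), expected, rtol=1e-10)


class TestModelValidation:
    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            GaussianComponent("a", 0.0, 0.0, 1.0)

    def test_non_pd_covariance_rejected_at_construction(self):
        with pytest.raises(ValueError):
            GaussianComponent("a", [0.0, 0.0], np.array([[1.0, 2.0], [2.0, 1.0]]),
                              1.0)

    def test_weight_bounds(self):
        with pytest.raises(ValueError):
            GaussianComponent("a", 0.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            GaussianComponent("a", 0.0, 1.0, 1.5)

    def test_weights_must_sum_to_one(self):
        comps = [GaussianComponent("a", 0.0, 1.0, 0.5),
                 GaussianComponent("b", 1.0, 1.0, 0.6)]
        with pytest.raises(ValueError):
            BayesModel(comps)

    def test_duplicate_labels_rejected(self):
        comps = [GaussianComponent("a", 0.0, 1.0, 0.5),
                 GaussianComponent("a", 1.0, 1.0, 0.5)]
        with pytest.raises(ValueError):
            BayesModel(comps)


class TestEvidence:
    def test_single_class_equals_pdf(self):
        comp = GaussianComponent("only", 3.0, 2.0, 1.0)
        model = BayesModel([comp])
        for x in (-1.0, 3.0, 9.5):
            assert evidence(model, x) == pytest.approx(gaussian_pdf(comp, x),
                                                       rel=1e-12)

    def test_identical_components_any_weights(self):
        a = GaussianComponent("a", 1.0, 1.5, 0.3)
        b = GaussianComponent("b", 1.0, 1.5, 0.7)
        model = BayesModel([a, b])
        for x in (0.0, 1.0, 4.0):
            assert evidence(model, x) == pytest.approx(gaussian_pdf(a, x),
                                                       rel=1e-12)

    def test_height_model_at_155_hand_sum(self, height_model):
        assert evidence(height_model, 155.0) == pytest.approx(
            EVIDENCE_HEIGHTS_AT_155, rel=1e-10
        )

    def test_linearity_in_components(self):
        """Evidence is the weight-weighted sum of single-class evidences."""
        rng = np.random.default_rng(11)
        model = random_model(rng, d=2, c=4)
        X = rng.normal(0, 4, size=(40, 2))
        total = np.zeros(40)
        for comp in model.components:
            single = BayesModel([GaussianComponent(comp.label, comp.mean,
                                                   comp.cov, 1.0)])
            total += comp.weight * single.evidence(X)
        np.testing.assert_allclose(model.evidence(X), total, rtol=1e-12)


class TestPosteriors:
    def test_identical_components_give_half(self):
        model = BayesModel([GaussianComponent("a", 0.0, 1.0, 0.5),
                            GaussianComponent("b", 0.0, 1.0, 0.5)])
        for x in (-3.0, 0.0, 5.0):
            np.testing.assert_allclose(posteriors(model, x), [0.5, 0.5],
                                       atol=1e-12)

    def test_giants_are_female_under_plain_bayes(self, height_model):
        """Above 160 cm the larger girls' variance dominates the posterior."""
        post = posteriors(height_model, 165.0)
        assert post[0] > 0.5  # girls

    def test_direct_formula_oracle_at_151_5(self, height_model):
        post = posteriors(height_model, 151.5)
        assert post[0] == pytest.approx(POST_GIRLS_AT_151_5, rel=1e-10)
        assert post[1] == pytest.approx(1 - POST_GIRLS_AT_151_5, rel=1e-10)

    def test_normalization_over_many_random_models(self):
        """Posterior rows sum to one (1e-9) across 10^4 random points."""
        rng = np.random.default_rng(42)
        total = 0
        for _ in range(25):
            d = int(rng.integers(1, 4))
            model = random_model(rng, d=d, c=int(rng.integers(2, 5)))
            X = rng.normal(0, 6, size=(400, d))
            post = model.posteriors(X)
            np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)
            total += X.shape[0]
        assert total == 10_000

    def test_log_space_survives_deep_tails(self):
        """Posteriors stay defined far beyond where densities underflow."""
        model = BayesModel([GaussianComponent("a", 0.0, 1e-3, 0.5),
                            GaussianComponent("b", 1.0, 1e-3, 0.5)])
        table = model.posterior_table(np.array([[10.0]]))
        assert table.evidence[0] == 0.0  # underflow in linear space
        assert table.defined[0]          # but the log-space ratio is exact
        np.testing.assert_allclose(table.posteriors[0].sum(), 1.0)

    def test_underflow_flagged_not_raised(self):
        """A case where every log-density is -inf gets NaN posteriors and
        an explicit flag instead of an exception."""
        model = BayesModel([GaussianComponent("a", 0.0, 1e-3, 1.0)])
        table = model.posterior_table(np.array([[1e200]]))
        assert table.evidence[0] == 0.0
        assert not table.defined[0]
        assert np.isnan(table.posteriors[0]).all()


@settings(deadline=None, max_examples=40, derandomize=True)
@given(x=st.floats(-50, 50), m=st.floats(-10, 10),
       s=st.floats(0.1, 5.0), w=st.floats(0.05, 0.95))
def test_posterior_proportional_to_weighted_likelihood(x, m, s, w):
    """p(class|x) ∝ weight · pdf for any two-component model."""
    from scipy.stats import norm

    a = GaussianComponent("a", m, s, w)
    b = GaussianComponent("b", m + 3.0, 1.0, 1.0 - w)
    model = BayesModel([a, b])
    post = posteriors(model, x)
    # independent log-domain oracle (scipy logpdf + logaddexp)
    la = np.log(w) + norm.logpdf(x, m, s)
    lb = np.log(1 - w) + norm.logpdf(x, m + 3.0, 1.0)
    expected = np.exp(la - np.logaddexp(la, lb))
    assert post[0] == pytest.approx(expected, rel=1e-9, abs=1e-300)


class TestFitFromLabeled:
    def test_group_means_recovered_exactly(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, size=60)
        labels = np.array(["u"] * 30 + ["v"] * 30, dtype=object)
        model = fit_from_labeled(x, labels)
        np.testing.assert_allclose(model.components[0].mean[0], x[:30].mean())
        np.testing.assert_allclose(model.components[1].mean[0], x[30:].mean())
        np.testing.assert_allclose(model.components[0].sd, x[:30].std(ddof=1))

    def test_equal_priors_ignore_group_sizes(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 1, 102), rng.normal(5, 1, 301)])
        labels = np.array(["p"] * 102 + ["c"] * 301, dtype=object)
        model = fit_from_labeled(x, labels, prior_mode="equal")
        np.testing.assert_allclose(model.weights, [0.5, 0.5])
        prop = fit_from_labeled(x, labels, prior_mode="proportional")
        np.testing.assert_allclose(prop.weights, [102 / 403, 301 / 403])

    def test_parameter_recovery_within_3_standard_errors(self):
        rng = np.random.default_rng(77)
        n = 5000
        x = np.concatenate([rng.normal(2.0, 1.5, n), rng.normal(-1.0, 0.5, n)])
        labels = np.array(["a"] * n + ["b"] * n, dtype=object)
        model = fit_from_labeled(x, labels)
        # SE(mean) = s/sqrt(n); SE(s) ≈ s/sqrt(2n)
        for comp, (m, s) in zip(model.components, [(2.0, 1.5), (-1.0, 0.5)]):
            assert abs(comp.mean[0] - m) < 3 * s / np.sqrt(n)
            assert abs(comp.sd - s) < 3 * s / np.sqrt(2 * n)

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_from_labeled([1.0, 2.0, 3.0], ["a", "a", "b"])  # class of size 1
        with pytest.raises(ValueError):
            fit_from_labeled([1.0, 1.0, 2.0, 3.0], ["a", "a", "b", "b"])  # zero var
        with pytest.raises(ValueError):
            fit_from_labeled([1.0, 2.0], ["a", None])  # missing label
        with pytest.raises(ValueError):
            fit_from_labeled([1.0, 2.0], ["a", "a"], prior_mode="bogus")

    def test_idempotent_on_large_resimulation(self):
        """Simulating from a fit and refitting recovers it within 2%."""
        rng = np.random.default_rng(123)
        x = np.concatenate([rng.normal(10, 2, 200), rng.normal(20, 3, 200)])
        labels = np.array(["a"] * 200 + ["b"] * 200, dtype=object)
        first = fit_from_labeled(x, labels)
        n = 100_000
        sim = np.concatenate([
            rng.normal(first.components[0].mean[0], first.components[0].sd, n),
            rng.normal(first.components[1].mean[0], first.components[1].sd, n),
        ])
        sim_labels = np.array(["a"] * n + ["b"] * n, dtype=object)
        second = fit_from_labeled(sim, sim_labels)
        for c1, c2 in zip(first.components, second.components):
            assert c2.mean[0] == pytest.approx(c1.mean[0], rel=0.02)
            assert c2.sd == pytest.approx(c1.sd, rel=0.02)
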