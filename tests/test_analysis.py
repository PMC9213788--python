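"""Latent-space applications: empirical prior, virtual populations,
traversal, feature encoding, and disease classification."""

import numpy as np
import pytest

from cardiovae.analysis import (
    ClassificationReport, LatentPrior, classify_disease, encode_features,
    fit_latent_prior, generate_virtual_population, latent_traversal,
)
from cardiovae.vae import MultiDomainVAE, VAEConfig


@pytest.fixture(scope="module")
def model():
    return MultiDomainVAE(VAEConfig.small_preset(ecg_length=100, seed=4))


@pytest.fixture(scope="module")
def prior(model, tiny_population):
    return fit_latent_prior(model, tiny_population)


class TestLatentPrior:
    def test_dimension_matches_latent_size(self, prior):
        assert prior.dim == 12
        assert (prior.sd > 0).all()

    def test_mean_is_arithmetic_mean_of_encoder_outputs(self, model,
                                                        tiny_population):
        code = model.encode_joint(tiny_population)
        prior = fit_latent_prior(model, tiny_population)
        np.testing.assert_allclose(prior.mean, code.mu.mean(axis=0))
        np.testing.assert_allclose(prior.sd, code.mu.std(axis=0))

    def test_identical_records_give_zero_spread_error(self, model,
                                                      tiny_population):
        with pytest.raises(ValueError, match="zero spread"):
            fit_latent_prior(model, [tiny_population[0]] * 4)

    def test_empty_population_rejected(self, model):
        with pytest.raises(ValueError, match="empty"):
            fit_latent_prior(model, [])

    def test_two_point_arithmetic(self):
        prior = LatentPrior(mean=np.ones(3), sd=np.ones(3))
        assert prior.dim == 3
        with pytest.raises(ValueError, match="strictly positive"):
            LatentPrior(mean=np.zeros(2), sd=np.array([1.0, 0.0]))


class TestVirtualPopulation:
    def test_counts_and_structure(self, model, prior):
        out = generate_virtual_population(model, prior, 5, seed=3)
        assert len(out) == 5
        assert set(out[0]) >= {"ed", "es", "ecg"}
        assert len(out[0]["ecg"]) == 100

    def test_deterministic_given_seed(self, model, prior):
        a = generate_virtual_population(model, prior, 3, seed=7)
        b = generate_virtual_population(model, prior, 3, seed=7)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra["ecg"].samples, rb["ecg"].samples)

    def test_different_seeds_differ(self, model, prior):
        a = generate_virtual_population(model, prior, 3, seed=1)
        b = generate_virtual_population(model, prior, 3, seed=2)
        assert any(not np.array_equal(ra["ecg"].samples, rb["ecg"].samples)
                   for ra, rb in zip(a, b))

    def test_degenerate_prior_reproduces_mean_decode(self, model, prior):
        tight = LatentPrior(mean=prior.mean, sd=np.full(prior.dim, 1e-12))
        out = generate_virtual_population(model, tight, 2, seed=0)
        np.testing.assert_allclose(out[0]["ecg"].samples,
                                   out[1]["ecg"].samples, atol=1e-6)

    def test_sample_mean_converges_to_prior_mean(self, prior):
        rng = np.random.default_rng(0)
        n = 10_000
        z = prior.mean + prior.sd * rng.standard_normal((n, prior.dim))
        bound = 4 * prior.sd / np.sqrt(n)
        assert np.all(np.abs(z.mean(axis=0) - prior.mean) < bound)


class TestTraversal:
    def test_offset_zero_reproduces_prior_mean_decode(self, model, prior):
        res = latent_traversal(model, prior, component=0, offsets=(-3, 0, 3))
        base = model.generate(prior.mean[None, :])[0]
        idx = res.offsets.index(0.0)
        np.testing.assert_array_equal(res.outputs[idx]["ecg"].samples,
                                      base["ecg"].samples)

    def test_positive_and_negative_offsets_differ(self, model, prior):
        res = latent_traversal(model, prior, component=2, offsets=(-3, 0, 3))
        a = res.outputs[0]["ecg"].samples
        b = res.outputs[-1]["ecg"].samples
        assert np.abs(a - b).max() > 1e-8

    def test_component_out_of_range_rejected(self, model, prior):
        with pytest.raises(ValueError, match="component"):
            latent_traversal(model, prior, component=12)

    def test_offsets_must_include_zero(self, model, prior):
        with pytest.raises(ValueError, match="include 0"):
            latent_traversal(model, prior, component=0, offsets=(-3, 3))


class TestEncodeFeatures:
    def test_feature_width_equals_latent_size(self, model, tiny_population):
        feats = encode_features({"multi_domain": model}, tiny_population[:4],
                                "multi_domain")
        assert feats.shape == (4, 12)

    def test_identical_records_identical_rows(self, model, tiny_population):
        r = tiny_population[0]
        feats = encode_features({"multi_domain": model}, [r, r], "multi_domain")
        np.testing.assert_array_equal(feats[0], feats[1])

    def test_single_domain_models_must_match_mode(self, model, tiny_population):
        with pytest.raises(ValueError, match="domains"):
            encode_features({"anatomy_only": model}, tiny_population[:2],
                            "anatomy_only")

    def test_anatomy_only_features_differ_from_multi(self, tiny_population):
        multi = MultiDomainVAE(VAEConfig.small_preset(ecg_length=100, seed=4))
        anat = MultiDomainVAE(VAEConfig.small_preset(
            ecg_length=100, domains=("ed", "es"), seed=4))
        models = {"multi_domain": multi, "anatomy_only": anat}
        f_multi = encode_features(models, tiny_population[:3], "multi_domain")
        f_anat = encode_features(models, tiny_population[:3], "anatomy_only")
        assert not np.array_equal(f_multi, f_anat)


class TestClassification:
    def test_perfectly_separable_feature(self):
        rng = np.random.default_rng(0)
        labels = np.array([0] * 50 + [1] * 50)
        features = (labels * 10.0 + rng.normal(0, 0.1, 100))[:, None]
        rep = classify_disease(features, labels, folds=10, seed=0)
        assert rep.mean_auroc == 1.0
        assert len(rep.fold_aurocs) == 10

    def test_permuted_labels_auroc_near_half(self):
        hits = 0
        for rep_i in range(100):
            rng = np.random.default_rng(2000 + rep_i)
            features = rng.normal(size=(300, 5))
            labels = np.array([0] * 150 + [1] * 150)
            rng.shuffle(labels)
            rep = classify_disease(features, labels, folds=10, seed=rep_i)
            if 0.4 <= rep.mean_auroc <= 0.6:
                hits += 1
        assert hits >= 95

    def test_fold_count_matches_config(self):
        rng = np.random.default_rng(1)
        features = rng.normal(size=(300, 3))
        labels = np.array([0, 1] * 150)
        rep = classify_disease(features, labels, folds=10, seed=0)
        assert len(rep.fold_aurocs) == 10

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            classify_disease(np.zeros((20, 2)), np.zeros(20), folds=5)

    def test_report_validates_auroc_range(self):
        with pytest.raises(ValueError, match="AUROC"):
            ClassificationReport(fold_aurocs=[1.2], feature_set="multi_domain")
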