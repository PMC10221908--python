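"""KPMSE, the VAE loss, latent merging and class-conditional sampling."""

import numpy as np
import pytest

from tssci import generative
from tssci.errors import CannotFitError
from tssci.skeleton import TourOrder


@pytest.fixture
def toy_tour():
    # 5 columns: joint 0 at positions 0 and 2, joint 2 at 3 and 4
    return TourOrder((0, 1, 0, 2, 2))


class TestKPMSE:
    def test_zero_on_duplicate_consistent_image(self, tour):
        rng = np.random.default_rng(0)
        joints = rng.random((49, 25, 3))
        pixels = joints[:, list(tour.sequence), :]
        assert generative.kpmse(pixels, tour) == pytest.approx(0.0)

    def test_single_pair_hand_value(self, toy_tour):
        pixels = np.zeros((1, 5, 3))
        pixels[0, 0, 0] = 0.1  # one duplicated joint differs by 0.1 in x
        pixels[0, 3:, :] = 0.4  # other group consistent
        assert generative.kpmse(pixels, toy_tour) == pytest.approx(0.01)

    def test_row_permutation_invariant(self, tour):
        rng = np.random.default_rng(1)
        pixels = rng.random((49, 49, 3))
        permuted = pixels[rng.permutation(49)]
        assert generative.kpmse(pixels, tour) == pytest.approx(
            generative.kpmse(permuted, tour)
        )

    def test_matches_explicit_pair_sum(self, toy_tour):
        # oracle: direct loop over unordered pairs
        rng = np.random.default_rng(2)
        pixels = rng.random((3, 5, 3))
        expected = 0.0
        for row in pixels:
            for group in ((0, 2), (3, 4)):
                for a in range(len(group)):
                    for b in range(a + 1, len(group)):
                        expected += np.sum((row[group[a]] - row[group[b]]) ** 2)
        assert generative.kpmse(pixels, toy_tour) == pytest.approx(expected)

    def test_gradient_matches_finite_differences(self, toy_tour):
        rng = np.random.default_rng(3)
        batch = rng.random((2, 3, 5, 3))
        groups = generative._duplicate_groups(toy_tour)
        value, grad = generative._kpmse_batch(batch, groups)
        eps = 1e-6
        for idx in [(0, 1, 0, 0), (1, 2, 3, 1), (0, 0, 4, 2)]:
            bumped = batch.copy()
            bumped[idx] += eps
            numeric = (generative._kpmse_batch(bumped, groups)[0] - value) / eps
            assert grad[idx] == pytest.approx(numeric, abs=1e-4)


class TestVAELoss:
    def test_perfect_reconstruction_at_prior_is_zero(self, tour):
        rng = np.random.default_rng(0)
        joints = rng.random((49, 25, 3))
        img = joints[:, list(tour.sequence), :]
        mu = np.zeros(16)
        logvar = np.zeros(16)
        total, mse, dkl, kp = generative.vae_loss(
            img, img, mu, logvar, generative.VAEConfig()
        )
        assert total == pytest.approx(0.0)
        assert (mse, dkl, kp) == (pytest.approx(0.0),) * 3

    def test_alpha_zero_reduces_to_plain_vae(self):
        rng = np.random.default_rng(1)
        recon, target = rng.random((49, 49, 3)), rng.random((49, 49, 3))
        mu, logvar = rng.normal(size=16), rng.normal(size=16)
        cfg0 = generative.VAEConfig(alpha=0.0, beta=0.7)
        total, mse, dkl, kp = generative.vae_loss(recon, target, mu, logvar, cfg0)
        assert total == pytest.approx(mse + 0.7 * dkl)

    def test_total_nondecreasing_in_alpha(self):
        rng = np.random.default_rng(2)
        recon, target = rng.random((49, 49, 3)), rng.random((49, 49, 3))
        mu, logvar = rng.normal(size=16), rng.normal(size=16)
        totals = [
            generative.vae_loss(
                recon, target, mu, logvar, generative.VAEConfig(alpha=a)
            )[0]
            for a in (0.0, 0.3, 0.6, 1.0)
        ]
        assert all(b >= a for a, b in zip(totals, totals[1:]))

    def test_config_bounds(self):
        with pytest.raises(ValueError):
            generative.VAEConfig(alpha=1.5)
        with pytest.raises(ValueError):
            generative.VAEConfig(beta=-0.1)


class TestVAETraining:
    def test_small_training_run_reduces_loss(self, small_dataset):
        cfg = generative.VAEConfig(epochs=6, seed=5)
        vae = generative.train_vae(small_dataset[:64], cfg)
        assert vae.history[-1]["total"] < vae.history[0]["total"]

    def test_decoder_output_shape_and_range(self, small_dataset):
        cfg = generative.VAEConfig(epochs=2, seed=5)
        vae = generative.train_vae(small_dataset[:32], cfg)
        out = vae.decode(np.zeros(16))
        assert out.shape == (49, 49, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0
        batch = vae.sample(4, seed=1)
        assert batch.shape == (4, 49, 49, 3)

    def test_training_is_deterministic(self, small_dataset):
        cfg = generative.VAEConfig(epochs=3, seed=11)
        a = generative.train_vae(small_dataset[:32], cfg)
        b = generative.train_vae(small_dataset[:32], cfg)
        assert a.history[-1]["total"] == b.history[-1]["total"]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            generative.train_vae([], generative.VAEConfig())

    def test_save_load_round_trip(self, small_dataset, tmp_path):
        cfg = generative.VAEConfig(epochs=2, seed=3)
        vae = generative.train_vae(small_dataset[:32], cfg)
        vae.save(tmp_path / "vae.npz")
        loaded = generative.VAE.load(tmp_path / "vae.npz")
        z = np.random.default_rng(0).standard_normal(16)
        np.testing.assert_allclose(loaded.decode(z), vae.decode(z))


class TestLatentOps:
    def test_merge_examples(self):
        z = np.arange(16.0)
        np.testing.assert_array_equal(generative.merge_latents(z, z), z)
        np.testing.assert_array_equal(
            generative.merge_latents(np.zeros(16), z), z / 2
        )
        z2 = np.ones(16)
        np.testing.assert_array_equal(
            generative.merge_latents(z, z2), generative.merge_latents(z2, z)
        )

    def test_merge_dim_mismatch(self):
        with pytest.raises(ValueError):
            generative.merge_latents(np.zeros(16), np.zeros(8))

    def test_conditional_sampling_zero_variance(self):
        cloud = [np.full(16, 2.0)] * 3
        samples = generative.sample_class_conditional(cloud, 5, seed=0)
        np.testing.assert_allclose(samples, 2.0)

    def test_conditional_sampling_law_of_large_numbers(self):
        rng = np.random.default_rng(4)
        cloud = rng.normal(3.0, 0.5, size=(50, 16))
        samples = generative.sample_class_conditional(cloud, 10000, seed=1)
        np.testing.assert_allclose(samples.mean(axis=0), cloud.mean(axis=0), atol=0.05)

    def test_conditional_sampling_deterministic(self):
        cloud = np.random.default_rng(5).normal(size=(10, 16))
        a = generative.sample_class_conditional(cloud, 8, seed=2)
        b = generative.sample_class_conditional(cloud, 8, seed=2)
        np.testing.assert_array_equal(a, b)

    def test_too_few_latents(self):
        with pytest.raises(CannotFitError):
            generative.sample_class_conditional([np.zeros(16)], 3)


class TestMovementGeneration:
    def test_class_conditional_samples_classify_as_requested(
        self, vae_dataset, generator_vae, trained_classifier
    ):
        """Decoding draws from a class's latent sub-distribution yields
        images an independently trained classifier assigns to that class."""
        correct = total = 0
        for label in sorted({im.label for im in vae_dataset}):
            class_images = [im for im in vae_dataset if im.label == label]
            mu, _ = generator_vae.encode(class_images)
            draws = generative.sample_class_conditional(mu, 20, seed=21)
            predicted = trained_classifier.predict_label(list(generator_vae.decode(draws)))
            correct += sum(p == label for p in predicted)
            total += len(predicted)
        assert correct / total >= 0.90

    def test_merged_latent_decodes_to_valid_image(self, vae_dataset, generator_vae):
        """Averaging one SLL and one TRO latent yields a well-formed image."""
        sll = next(im for im in vae_dataset if im.label == "SLL")
        tro = next(im for im in vae_dataset if im.label == "TRO")
        mu_a, _ = generator_vae.encode(sll)
        mu_b, _ = generator_vae.encode(tro)
        merged = generator_vae.decode(generative.merge_latents(mu_a, mu_b))
        assert merged.shape == (49, 49, 3)
        assert merged.min() >= 0.0 and merged.max() <= 1.0

    def test_generated_duplicates_stay_consistent(self, generator_vae):
        """KPMSE-trained generation keeps duplicate columns nearly equal:
        per-pair mean squared disagreement well below pixel scale."""
        samples = generator_vae.sample(8, seed=2)
        n_pairs = generative._n_pairs(generator_vae.tour)
        for pixels in samples:
            per_pair = generative.kpmse(pixels) / (49 * n_pairs * 3)
            assert per_pair < 1e-3
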