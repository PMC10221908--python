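import numpy as np
import pytest
from hypothesis import settings

from tssci import generative, scoring, simulate
from tssci.skeleton import body25_tour

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tour():
    return body25_tour()


@pytest.fixture(scope="session")
def small_dataset():
    """120 encoded images (20 per class), shared by light-weight tests."""
    return simulate.generate_dataset(20, seed=101)


@pytest.fixture(scope="session")
def classifier_dataset():
    """200 images per class, the held-out-accuracy study condition."""
    return simulate.generate_dataset(200, seed=202)


@pytest.fixture(scope="session")
def trained_classifier(classifier_dataset):
    train, _ = scoring.split_dataset(classifier_dataset, seed=0)
    return scoring.train_classifier(train, seed=0)


@pytest.fixture(scope="session")
def vae_dataset():
    """600 encoded images (100 per class) for generative training."""
    return simulate.generate_dataset(100, seed=303)


@pytest.fixture(scope="session")
def vae_twins(vae_dataset):
    """Two VAEs, identical but for the KPMSE weight (alpha 0.5 vs 0)."""
    with_kp = generative.train_vae(
        vae_dataset, generative.VAEConfig(epochs=30, alpha=0.5, seed=7)
    )
    without_kp = generative.train_vae(
        vae_dataset, generative.VAEConfig(epochs=30, alpha=0.0, seed=7)
    )
    return with_kp, without_kp


@pytest.fixture(scope="session")
def generator_vae(vae_dataset):
    """Longer-trained VAE used for movement generation checks."""
    return generative.train_vae(
        vae_dataset, generative.VAEConfig(epochs=60, alpha=0.5, seed=13)
    )


def label_accuracy(classifier, images):
    predicted = classifier.predict_label(list(images))
    truth = [im.label for im in images]
    return float(np.mean([p == t for p, t in zip(predicted, truth)]))
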