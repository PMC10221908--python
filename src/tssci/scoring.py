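"""Exercise classification and reference-vs-subject scoring.

Classification maps an encoded motion image to one of six exercise
classes.  Scoring compares a subject's exercise to an expert reference:
both images are embedded (a Siamese arrangement — the same backbone maps
both), the Euclidean distance D between the embeddings is taken, and an
empirical 0-100 score is

    f = alpha * 100 / D,      s = min(f, 100)

with scaling factor alpha chosen empirically as 30: the inverse distance
is scaled and capped, so identical performances score 100 and unrelated
ones approach 0.  A normalized similarity S = 1 - ||T1 - T2|| / ||T2||
(reference norm in the denominator) and the classic contrastive loss
(Y = 0 for similar pairs, Y = 1 for dissimilar) round out the toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codec import TSSCIImage
from .errors import DegenerateTrainingError, MissingClassError

CLASS_LABELS = ("AFR", "ARO", "LBE", "LFC", "SLL", "TRO")


@dataclass
class ScoreConfig:
    """Empirical-score parameters: scale alpha, cap, contrastive margin."""

    alpha_scale: float = 30.0
    cap: float = 100.0
    margin: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_scale <= 0 or self.cap <= 0:
            raise ValueError("alpha_scale and cap must be positive")


def _pixels(image) -> np.ndarray:
    return image.pixels if isinstance(image, TSSCIImage) else np.asarray(image, dtype=float)


def _labels_of(images, labels=None) -> list:
    if labels is not None:
        return list(labels)
    return [im.label for im in images]


# ---------------------------------------------------------------------------
# Pure scoring formulas


def contrastive_loss(dw: float, y: int, margin: float = 1.0) -> float:
    """Contrastive pair loss: (1-Y) * Dw^2/2 + Y * max(0, m - Dw)^2 / 2.

    Y = 0 marks a similar pair (penalized by distance), Y = 1 a
    dissimilar pair (penalized for being inside the margin).
    """
    if dw < 0:
        raise ValueError("distance must be non-negative")
    return (1 - y) * 0.5 * dw**2 + y * 0.5 * max(0.0, margin - dw) ** 2


def similarity_s(t1: np.ndarray, t2: np.ndarray) -> float:
    """S = 1 - ||T1 - T2|| / ||T2||; equals 1 iff the embeddings match.

    T2 is the reference (expert) embedding; its norm sets the scale.
    """
    t1 = np.asarray(t1, dtype=float).ravel()
    t2 = np.asarray(t2, dtype=float).ravel()
    ref_norm = float(np.linalg.norm(t2))
    if ref_norm == 0.0:
        raise ValueError("reference embedding has zero norm")
    return 1.0 - float(np.linalg.norm(t1 - t2)) / ref_norm


def empirical_score(distance: float, config: ScoreConfig | None = None) -> float:
    """Map an embedding distance to a 0-100 score (inverse, capped).

    Monotone non-increasing in the distance; D = 0 scores the cap by
    convention (perfect match), negative distances are rejected.
    """
    config = config or ScoreConfig()
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if distance == 0:
        return config.cap
    return min(config.alpha_scale * config.cap / distance, config.cap)


# ---------------------------------------------------------------------------
# Dataset splitting


def split_dataset(
    items: Sequence, train_fraction: float = 0.8, seed: int = 0, labels=None
) -> tuple[list, list]:
    """Deterministic, label-stratified train/eval partition.

    The train side gets floor(n * train_fraction) items in total,
    apportioned per class by largest fractional remainder, so e.g. 2004
    images at 0.8 split 1603 / 401.  Items without labels are split by a
    plain shuffle.
    """
    if len(items) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    n = len(items)
    n_train = int(np.floor(n * train_fraction))
    try:
        label_list = _labels_of(items, labels)
    except AttributeError:
        label_list = None
    if label_list is None or any(lab is None for lab in label_list):
        order = rng.permutation(n)
        train_idx = sorted(order[:n_train])
        eval_idx = sorted(order[n_train:])
    else:
        classes = sorted(set(label_list), key=str)
        per_class = {c: [i for i, lab in enumerate(label_list) if lab == c] for c in classes}
        quota = {c: len(per_class[c]) * train_fraction for c in classes}
        take = {c: int(np.floor(quota[c])) for c in classes}
        short = n_train - sum(take.values())
        for c in sorted(classes, key=lambda c: (-(quota[c] - take[c]), str(c)))[:short]:
            take[c] += 1
        train_idx, eval_idx = [], []
        for c in classes:
            idx = np.array(per_class[c])
            idx = idx[rng.permutation(len(idx))]
            train_idx.extend(idx[: take[c]])
            eval_idx.extend(idx[take[c] :])
        train_idx, eval_idx = sorted(train_idx), sorted(eval_idx)
    return [items[i] for i in train_idx], [items[i] for i in eval_idx]


# ---------------------------------------------------------------------------
# Classifier contract


class TSSCIClassifier:
    """Six-class predictor over encoded motion images.

    Reference backbone: a compact multilayer perceptron over the raw
    49x49x3 pixels (scikit-learn).  The contract is only the surface:
    ``predict_proba`` returns per-class probabilities summing to one,
    ``predict_label`` the argmax class.
    """

    def __init__(self, seed: int = 0, hidden: tuple[int, ...] = (64,), max_iter: int = 120):
        from sklearn.neural_network import MLPClassifier

        self._model = MLPClassifier(
            hidden_layer_sizes=hidden, max_iter=max_iter, random_state=seed,
        )
        self.classes_: tuple = ()

    def fit(self, images: Sequence, labels=None) -> "TSSCIClassifier":
        y = _labels_of(images, labels)
        if len(set(y)) < 2:
            raise DegenerateTrainingError("training data holds a single class")
        x = np.stack([_pixels(im).ravel() for im in images])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings are fine
            self._model.fit(x, y)
        self.classes_ = tuple(self._model.classes_)
        return self

    def predict_proba(self, image) -> np.ndarray:
        single = isinstance(image, TSSCIImage) or (
            isinstance(image, np.ndarray) and image.ndim == 3
        )
        batch = [image] if single else list(image)
        x = np.stack([_pixels(im).ravel() for im in batch])
        proba = self._model.predict_proba(x)
        return proba[0] if single else proba

    def predict_label(self, image):
        proba = np.atleast_2d(self.predict_proba(image))
        labels = [self.classes_[i] for i in proba.argmax(axis=1)]
        return labels[0] if len(labels) == 1 else labels

    def save(self, path: str | Path) -> None:
        import joblib

        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "TSSCIClassifier":
        import joblib

        return joblib.load(path)


def train_classifier(
    images: Sequence, labels=None, seed: int = 0,
    hidden: tuple[int, ...] = (64,), max_iter: int = 120,
) -> TSSCIClassifier:
    """Fit the reference classifier; raises on single-class data."""
    return TSSCIClassifier(seed=seed, hidden=hidden, max_iter=max_iter).fit(images, labels)


# ---------------------------------------------------------------------------
# Embedders (Siamese backbone contract)


class FlattenEmbedder:
    """Identity embedding: the image's own pixels as the latent vector."""

    def embed(self, image) -> np.ndarray:
        return _pixels(image).ravel().astype(float)


class ContrastiveEmbedder:
    """Linear Siamese embedder trained with the contrastive loss.

    Both members of a pair pass through the same projection W; training
    pulls same-class embeddings together and pushes different-class ones
    beyond the margin.  Linear, so distances are exactly ||W^T (a - b)||.
    """

    def __init__(self, dim_out: int = 32, margin: float = 1.0,
                 learning_rate: float = 1e-3, seed: int = 0):
        self.dim_out = dim_out
        self.margin = margin
        self.learning_rate = learning_rate
        self.seed = seed
        self.weights: np.ndarray | None = None
        self.history: list[float] = []

    def _init(self, dim_in: int) -> None:
        rng = np.random.default_rng(self.seed)
        self.weights = rng.normal(0.0, 1.0 / np.sqrt(dim_in), size=(dim_in, self.dim_out))

    def fit(self, images: Sequence, labels=None, epochs: int = 5,
            pairs_per_epoch: int = 400) -> "ContrastiveEmbedder":
        y = _labels_of(images, labels)
        if len(set(y)) < 2:
            raise DegenerateTrainingError("need at least two classes of pairs")
        x = np.stack([_pixels(im).ravel() for im in images])
        if self.weights is None:
            self._init(x.shape[1])
        rng = np.random.default_rng(self.seed + 1)
        by_class: dict = {}
        for i, lab in enumerate(y):
            by_class.setdefault(lab, []).append(i)
        classes = sorted(by_class, key=str)
        for _ in range(epochs):
            total = 0.0
            for _ in range(pairs_per_epoch):
                dissimilar = rng.random() < 0.5
                if dissimilar:
                    ca, cb = rng.choice(len(classes), size=2, replace=False)
                    a = rng.choice(by_class[classes[ca]])
                    b = rng.choice(by_class[classes[cb]])
                else:
                    c = classes[rng.integers(len(classes))]
                    a, b = rng.choice(by_class[c], size=2, replace=True)
                diff = x[a] - x[b]
                e = diff @ self.weights
                dw = float(np.linalg.norm(e))
                total += contrastive_loss(dw, int(dissimilar), self.margin)
                if dissimilar:
                    if 0.0 < dw < self.margin:
                        de = -(self.margin - dw) / dw * e
                    else:
                        continue
                else:
                    de = e
                self.weights -= self.learning_rate * np.outer(diff, de)
            self.history.append(total / pairs_per_epoch)
        return self

    def embed(self, image) -> np.ndarray:
        if self.weights is None:
            raise RuntimeError("embedder is not fitted")
        return _pixels(image).ravel() @ self.weights


class PairSimilarityHead:
    """Optional sigmoid dense head over concatenated pair embeddings.

    Outputs sigma(bias + sum_i w_i C_i) in (0, 1) for C = [T1, T2]; a
    learned pairwise-similarity alternative to the distance path (which
    remains the one used for scoring).
    """

    def __init__(self, dim: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.w = rng.normal(0.0, 1.0 / np.sqrt(2 * dim), size=2 * dim)
        self.bias = 0.0

    def __call__(self, t1: np.ndarray, t2: np.ndarray) -> float:
        c = np.concatenate([np.ravel(t1), np.ravel(t2)])
        return float(1.0 / (1.0 + np.exp(-(self.bias + c @ self.w))))


# ---------------------------------------------------------------------------
# Score matrix


def score_pair(reference, subject, embedder=None, config: ScoreConfig | None = None) -> float:
    """Empirical score of one subject image against one reference image."""
    embedder = embedder or FlattenEmbedder()
    e_ref = embedder.embed(reference)
    e_sub = embedder.embed(subject)
    return empirical_score(float(np.linalg.norm(e_ref - e_sub)), config)


def score_matrix(
    reference_images: Mapping[str, object] | Sequence,
    subject_images: Sequence,
    embedder=None,
    config: ScoreConfig | None = None,
    subject_labels=None,
) -> pd.DataFrame:
    """Mean score of every subject class against every reference class.

    Rows are the expert's reference exercises, columns the subjects'
    exercise classes; each cell is the average empirical score.  All six
    classes must be present on both sides.
    """
    embedder = embedder or FlattenEmbedder()
    config = config or ScoreConfig()
    if not isinstance(reference_images, Mapping):
        reference_images = {im.label: im for im in reference_images}
    missing = [c for c in CLASS_LABELS if c not in reference_images]
    if missing:
        raise MissingClassError(f"reference classes missing: {missing}")
    sub_labels = _labels_of(subject_images, subject_labels)
    by_class: dict[str, list] = {c: [] for c in CLASS_LABELS}
    for im, lab in zip(subject_images, sub_labels):
        if lab in by_class:
            by_class[lab].append(im)
    empty = [c for c in CLASS_LABELS if not by_class[c]]
    if empty:
        raise MissingClassError(f"subject classes missing: {empty}")
    ref_embed = {c: embedder.embed(reference_images[c]) for c in CLASS_LABELS}
    sub_embed = {c: [embedder.embed(im) for im in by_class[c]] for c in CLASS_LABELS}
    matrix = np.zeros((len(CLASS_LABELS), len(CLASS_LABELS)))
    for r, ref_class in enumerate(CLASS_LABELS):
        for c, sub_class in enumerate(CLASS_LABELS):
            scores = [
                empirical_score(float(np.linalg.norm(ref_embed[ref_class] - e)), config)
                for e in sub_embed[sub_class]
            ]
            matrix[r, c] = float(np.mean(scores))
    return pd.DataFrame(matrix, index=list(CLASS_LABELS), columns=list(CLASS_LABELS))
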