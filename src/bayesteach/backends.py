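"""Synthetic classifier/featurizer backends.

Every other module is exercised against these backends, so the full
pipeline — fitting the explainee, scoring explanations, building saliency
maps and 2AFC sessions — runs end-to-end with no downloads and with known
ground truth. Two generators are provided:

* :func:`make_gaussian_feature_dataset` draws labelled feature vectors
  from the exact generative model the PLDA explainee assumes (latent class
  centres ``v_c ~ N(0, diag(psi))``, items ``u ~ N(v_c, I)``, observed
  ``x = A u + m``), so fitted parameters can be checked against truth.
* :func:`make_toy_image_backend` builds small images whose class is
  carried by a known pixel region, with a deterministic closed-form
  probabilistic classifier over them, so a saliency method's attention
  can be checked against the region that actually drives the decision.

A backend exposes ``categories``, ``featurize(item)`` and
``predict_proba(item, mask=None)``; any object with that surface (for
example a wrapper around a real network) can be plugged into the saliency
and trial-generation modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
from scipy.special import softmax

from ._rng import substream
from .plda import FeatureDataset, PLDAModel, classify, to_latent

__all__ = [
    "GaussianFeatureSpec",
    "ToyImageSpec",
    "make_gaussian_feature_dataset",
    "make_toy_image_backend",
    "ToyImageBackend",
    "PLDAFeatureClassifier",
]

logger = logging.getLogger(__name__)


@dataclass
class GaussianFeatureSpec:
    """Parameters of the PLDA generative model used to synthesize features."""

    n_categories: int = 10
    items_per_category: int = 50
    feature_dim: int = 3
    psi_true: np.ndarray | None = None  # default: ones
    shift_true: np.ndarray | None = None  # default: zeros
    transform_true: np.ndarray | None = None  # default: identity
    seed: int | None = None

    def __post_init__(self) -> None:
        D = self.feature_dim
        if self.n_categories < 2 or self.items_per_category < 2 or D < 1:
            raise ValueError("need >= 2 categories, >= 2 items each, D >= 1")
        self.psi_true = (
            np.ones(D) if self.psi_true is None else np.asarray(self.psi_true, dtype=float)
        )
        self.shift_true = (
            np.zeros(D) if self.shift_true is None else np.asarray(self.shift_true, dtype=float)
        )
        self.transform_true = (
            np.eye(D)
            if self.transform_true is None
            else np.asarray(self.transform_true, dtype=float)
        )
        if self.psi_true.shape != (D,) or np.any(self.psi_true < 0):
            raise ValueError("psi_true must be a nonnegative length-D vector")
        if self.transform_true.shape != (D, D):
            raise ValueError("transform_true must be D x D")
        if abs(np.linalg.det(self.transform_true)) < 1e-12:
            raise ValueError("transform_true must be invertible")


def make_gaussian_feature_dataset(spec: GaussianFeatureSpec):
    """Draw a labelled feature dataset from the PLDA generative model.

    Returns ``(dataset, truth)`` where ``truth`` records the generating
    parameters and the sampled class centres for recovery tests.
    """
    rng = substream(spec.seed, "gaussian-features")
    K, n, D = spec.n_categories, spec.items_per_category, spec.feature_dim
    centers = rng.standard_normal((K, D)) * np.sqrt(spec.psi_true)
    U = centers[:, None, :] + rng.standard_normal((K, n, D))
    X = U.reshape(K * n, D) @ spec.transform_true.T + spec.shift_true
    labels = np.repeat([f"cat{k:03d}" for k in range(K)], n)
    dataset = FeatureDataset(X=X, labels=labels)
    truth = {
        "psi_true": spec.psi_true.copy(),
        "shift_true": spec.shift_true.copy(),
        "transform_true": spec.transform_true.copy(),
        "centers": centers,
    }
    return dataset, truth


class PLDAFeatureClassifier:
    """Backend over feature vectors: a fitted PLDA model plus its training set.

    ``predict_proba(x)`` is the closed-form posterior over categories given
    all latent training examples of each category (uniform prior).
    """

    def __init__(self, model: PLDAModel, data: FeatureDataset):
        self.model = model
        self.categories = list(data.categories)
        self._class_latents = {
            cat: to_latent(data.X[data.rows_for(cat)], model) for cat in self.categories
        }
        # per-category predictive moments (posterior over the class centre
        # given all its training latents), for the vectorized bulk path
        psi = model.psi
        means, variances = [], []
        for cat in self.categories:
            U = self._class_latents[cat]
            n = U.shape[0]
            denom = n * psi + 1.0
            means.append(n * psi / denom * U.mean(axis=0))
            variances.append(psi / denom + 1.0)
        self._pred_means = np.array(means)  # (K, D)
        self._pred_vars = np.array(variances)  # (K, D)

    def class_latents(self, category) -> np.ndarray:
        return self._class_latents[category]

    def featurize(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float)

    def predict_proba(self, x: np.ndarray, mask=None) -> dict:
        if mask is not None:
            raise ValueError("feature-space classifier does not accept pixel masks")
        return classify(x, self.model, self._class_latents)

    def predict(self, x: np.ndarray):
        probs = self.predict_proba(x)
        vals = np.array([probs[c] for c in self.categories])
        return self.categories[int(np.argmax(vals))]

    def predict_many(self, X: np.ndarray) -> np.ndarray:
        """Argmax category for each row of X; ties go to the lowest index.

        Vectorized over items via the precomputed per-category predictive
        moments; agrees with :meth:`predict` item by item.
        """
        U = to_latent(np.atleast_2d(np.asarray(X, dtype=float)), self.model)
        # (n, K): sum over D of the diagonal-Gaussian log density
        z = U[:, None, :] - self._pred_means[None, :, :]
        logdens = -0.5 * np.sum(
            np.log(2.0 * np.pi * self._pred_vars)[None] + z * z / self._pred_vars[None],
            axis=2,
        )
        picks = np.argmax(logdens, axis=1)
        return np.array([self.categories[i] for i in picks], dtype=object)


@dataclass
class ToyImageSpec:
    """Small images whose category is carried by a known pixel region.

    ``regions`` maps each category to a rectangle ``(row0, row1, col0,
    col1)`` (half-open) of elevated intensity. Overlapping regions are
    allowed — they manufacture confusable categories — and are logged.
    """

    height: int = 32
    width: int = 32
    regions: dict = field(default_factory=dict)
    images_per_category: int = 10
    background: float = 0.2
    contrast: float = 0.6
    noise_sd: float = 0.05
    gain: float = 30.0  # softmax sharpness of the closed-form classifier
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.regions:
            # two default categories: left and right vertical bands
            w = self.width
            self.regions = {
                "left": (0, self.height, 0, w // 3),
                "right": (0, self.height, 2 * w // 3, w),
            }
        if len(self.regions) < 2:
            raise ValueError("need at least two categories")
        for cat, (r0, r1, c0, c1) in self.regions.items():
            if not (0 <= r0 < r1 <= self.height and 0 <= c0 < c1 <= self.width):
                raise ValueError(f"region for {cat!r} is out of bounds")
        cats = list(self.regions)
        for i, a in enumerate(cats):
            for b in cats[i + 1 :]:
                if _regions_overlap(self.regions[a], self.regions[b]):
                    logger.info(
                        "regions for %r and %r overlap; these categories are "
                        "confusable by construction",
                        a,
                        b,
                    )


def _regions_overlap(r, s) -> bool:
    return r[0] < s[1] and s[0] < r[1] and r[2] < s[3] and s[2] < r[3]


class ToyImageBackend:
    """Deterministic probabilistic classifier whose attention is known.

    The score of category ``c`` for a (masked) image is the mean intensity
    inside that category's region; probabilities are a softmax of
    ``gain * scores``. Masking is plain elementwise multiplication of the
    [0, 1] image, so zeroing a region provably lowers its category's score.
    """

    def __init__(self, spec: ToyImageSpec):
        self.spec = spec
        self.categories = list(spec.regions)

    def region(self, category):
        return self.spec.regions[category]

    def featurize(self, image: np.ndarray) -> np.ndarray:
        """Mean intensity inside each category region, in category order."""
        img = self._gray(image)
        return np.array(
            [img[r0:r1, c0:c1].mean() for (r0, r1, c0, c1) in
             (self.spec.regions[c] for c in self.categories)]
        )

    @staticmethod
    def _gray(image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=float)
        if img.ndim == 3:
            img = img.mean(axis=2)
        return img

    def predict_proba(self, image: np.ndarray, mask: np.ndarray | None = None) -> dict:
        img = self._gray(image)
        if mask is not None:
            mask = np.asarray(mask, dtype=float)
            if mask.shape != img.shape:
                raise ValueError("mask and image shapes differ")
            img = img * mask
        scores = np.array(
            [img[r0:r1, c0:c1].mean() for (r0, r1, c0, c1) in
             (self.spec.regions[c] for c in self.categories)]
        )
        probs = softmax(self.spec.gain * scores)
        return dict(zip(self.categories, probs))

    def predict(self, image: np.ndarray):
        probs = self.predict_proba(image)
        vals = np.array([probs[c] for c in self.categories])
        return self.categories[int(np.argmax(vals))]


def make_toy_image_backend(spec: ToyImageSpec):
    """Generate the toy images and their classifier.

    Returns ``(backend, images, labels)`` where ``images`` maps item id to
    a float image in [0, 1] and ``labels`` maps item id to its category.
    """
    rng = substream(spec.seed, "toy-images")
    backend = ToyImageBackend(spec)
    images: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}
    for cat in backend.categories:
        r0, r1, c0, c1 = spec.regions[cat]
        for i in range(spec.images_per_category):
            img = np.full((spec.height, spec.width), spec.background)
            img[r0:r1, c0:c1] += spec.contrast
            if spec.noise_sd > 0:
                img += rng.normal(0.0, spec.noise_sd, size=img.shape)
            item_id = f"{cat}_{i:03d}"
            images[item_id] = np.clip(img, 0.0, 1.0)
            labels[item_id] = cat
    return backend, images, labels
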