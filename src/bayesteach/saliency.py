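"""Pixel-level Bayesian teaching: saliency maps from random masks.

A mask ``m`` in [0, 1]^{W x H} is scored by the probability that the
classifier assigns the conditioning category to the masked image; the
saliency map is the Monte-Carlo expectation of the masks weighted by
those probabilities,

    E[M | y, d]  ~=  sum_i m_i g(y | d, m_i) / sum_i g(y | d, m_i).

Masks are sampled from a smooth prior: a stationary Gaussian process with
constant mean, separable RBF kernel on the pixel grid, squashed through a
sigmoid. The GP mean controls how much of each mask is effectively zero;
the marginal standard deviation controls how sharply mask values swing
between 0 and 1. Sampling is exact — the separable kernel factorizes over
rows and columns, so a draw is ``mean + sd * L_r Z L_c^T`` with the 1-D
Cholesky factors, never a full (W*H)^2 covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import matplotlib
import numpy as np
from scipy.special import expit

from ._rng import substream

__all__ = [
    "GPMaskConfig",
    "SaliencyMap",
    "sample_gp_fields",
    "sample_gp_masks",
    "expected_saliency",
    "render_blur",
    "render_jet",
    "blur_window_width",
]


@dataclass
class GPMaskConfig:
    """Prior over masks: sigmoid-squashed stationary GP on the pixel grid.

    Defaults follow the 224x224 display size: mean -100, marginal sd 100
    (so roughly 16% of each mask is "on" and pre-squash values span about
    [-500, 300]), RBF length scale 0.1 * width = 22.4 pixels, 1000 Monte
    Carlo samples. ``length_scale=None`` keeps the 0.1 * width scaling on
    non-default grids.
    """

    width: int = 224
    height: int = 224
    mean: float = -100.0
    marginal_sd: float = 100.0
    length_scale: float | None = None
    n_samples: int = 1000
    jitter: float = 1e-6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")
        if self.length_scale is None:
            self.length_scale = 0.1 * self.width
        if self.marginal_sd <= 0 or self.length_scale <= 0:
            raise ValueError("marginal_sd and length_scale must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")


@dataclass
class SaliencyMap:
    """Per-pixel expected mask value in [0, 1] for one conditioning label."""

    values: np.ndarray
    label: object
    n_samples: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("saliency values must form a 2-D grid")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("saliency values must lie in [0, 1]")


def _axis_cholesky(n: int, length_scale: float, jitter: float) -> np.ndarray:
    d = np.arange(n, dtype=float)
    K = np.exp(-0.5 * (d[:, None] - d[None, :]) ** 2 / length_scale**2)
    try:
        return np.linalg.cholesky(K + jitter * np.eye(n))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"axis kernel of size {n} is not positive definite with jitter "
            f"{jitter}; increase GPMaskConfig.jitter"
        ) from err


def sample_gp_fields(config: GPMaskConfig) -> np.ndarray:
    """Draw raw (pre-sigmoid) GP functions on the grid.

    Returns an array of shape ``(n_samples, height, width)``. The
    covariance between pixels (r, c) and (r', c') is
    ``sd^2 * exp(-((r-r')^2 + (c-c')^2) / (2 l^2))``, realized exactly via
    the row/column factorization of the RBF kernel.
    """
    L_r = _axis_cholesky(config.height, config.length_scale, config.jitter)
    L_c = _axis_cholesky(config.width, config.length_scale, config.jitter)
    rng = substream(config.seed, "gp-masks")
    Z = rng.standard_normal((config.n_samples, config.height, config.width))
    fields = np.einsum("ij,njk,lk->nil", L_r, Z, L_c)
    return config.mean + config.marginal_sd * fields


def sample_gp_masks(config: GPMaskConfig) -> np.ndarray:
    """Sigmoid-squashed GP samples: ``n_samples`` masks with values in [0, 1]."""
    return expit(sample_gp_fields(config))


def _scale01(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.max() > 1.0:  # 8-bit input
        img = img / 255.0
    return img


def expected_saliency(
    image: np.ndarray,
    label,
    classifier,
    masks: Sequence[np.ndarray] | np.ndarray,
) -> SaliencyMap:
    """Monte-Carlo expected saliency map of ``image`` for category ``label``.

    ``classifier`` follows the backend contract: ``predict_proba(image,
    mask)`` returns a mapping from category to probability. Each mask is
    applied by elementwise multiplication of the [0, 1]-scaled image (per
    channel), its weight is the classifier's probability for ``label``,
    and the map is the weighted average of the masks.
    """
    masks = np.asarray(masks, dtype=float)
    if masks.ndim == 2:
        masks = masks[None]
    img = _scale01(image)
    if masks.shape[1:] != img.shape[:2]:
        raise ValueError(
            f"mask grid {masks.shape[1:]} does not match image grid {img.shape[:2]}"
        )
    weights = np.empty(masks.shape[0])
    for i, m in enumerate(masks):
        probs = classifier.predict_proba(img, m)
        weights[i] = probs[label]
    total = weights.sum()
    if total <= 0:
        raise ZeroDivisionError(
            f"degenerate expectation: every mask weight is zero for label {label!r}"
        )
    values = np.tensordot(weights, masks, axes=1) / total
    return SaliencyMap(values=np.clip(values, 0.0, 1.0), label=label, n_samples=masks.shape[0])


def blur_window_width(z: np.ndarray | float) -> np.ndarray:
    """Blur window width per saliency value: ``ceil(30 / (1 + exp(20 z - 10)))``.

    Important pixels (z near 1) get width 1 (no blur); unimportant pixels
    (z near 0) get width 30.
    """
    z = np.asarray(z, dtype=float)
    return np.ceil(30.0 / (1.0 + np.exp(20.0 * z - 10.0))).astype(int)


def render_blur(image: np.ndarray, smap: SaliencyMap) -> np.ndarray:
    """Render a saliency map by spatially varying box blur of the image.

    Each output pixel is the mean of the original image over a w x w
    window centred on it (w from :func:`blur_window_width`), clipped to
    the image bounds — near edges the window becomes rectangular and only
    in-bounds pixels are averaged. Even widths span floor((w-1)/2) pixels
    before and ceil((w-1)/2) after the centre. Channels blur independently.
    """
    img = _scale01(image)
    H, W = img.shape[:2]
    if smap.values.shape != (H, W):
        raise ValueError("saliency map and image dimensions differ")
    w = blur_window_width(smap.values)
    before = (w - 1) // 2
    after = w - 1 - before
    rows = np.arange(H)[:, None]
    cols = np.arange(W)[None, :]
    r0 = np.clip(rows - before, 0, H - 1)
    r1 = np.clip(rows + after, 0, H - 1)
    c0 = np.clip(cols - before, 0, W - 1)
    c1 = np.clip(cols + after, 0, W - 1)

    chans = img[..., None] if img.ndim == 2 else img
    out = np.empty_like(chans)
    counts = (r1 - r0 + 1) * (c1 - c0 + 1)
    for k in range(chans.shape[2]):
        S = np.zeros((H + 1, W + 1))
        np.cumsum(np.cumsum(chans[:, :, k], axis=0), axis=1, out=S[1:, 1:])
        box = S[r1 + 1, c1 + 1] - S[r0, c1 + 1] - S[r1 + 1, c0] + S[r0, c0]
        out[:, :, k] = box / counts
    return out[:, :, 0] if img.ndim == 2 else out


def render_jet(image: np.ndarray, smap: SaliencyMap, alpha: float = 0.4) -> np.ndarray:
    """Alpha-composite the jet colormap of the saliency map over the image.

    High saliency renders red, low renders blue (decreasing importance
    red -> green -> blue). ``out = (1 - alpha) * image + alpha * jet(map)``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    img = _scale01(image)
    if smap.values.shape != img.shape[:2]:
        raise ValueError("saliency map and image dimensions differ")
    jet = matplotlib.colormaps["jet"](smap.values)[..., :3]
    if img.ndim == 2:
        img = np.repeat(img[..., None], 3, axis=2)
    return (1.0 - alpha) * img + alpha * jet
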