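"""Probabilistic linear discriminant analysis (PLDA) explainee model.

PLDA is a latent-variable Gaussian model of labelled feature vectors:
an item ``x`` of class ``c`` is generated as

    x = m + A u,   u ~ N(v_c, I),   v_c ~ N(0, diag(psi)),

so that in the latent space reached by ``u = A^{-1}(x - m)`` the
within-class covariance is the identity and the between-class covariance
is the diagonal matrix ``diag(psi)``. Because both covariances are
diagonal simultaneously, the class-predictive density of a new item given
a handful of examples from one class has a closed form that factorizes
over coordinates — this is what makes PLDA usable as a probabilistic
"explainee" whose beliefs after seeing a few examples can be evaluated
exactly.

Fitting follows the maximum-likelihood recipe of simultaneous
diagonalization of the between- and within-class scatter matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
from scipy.special import log_softmax

__all__ = [
    "FeatureDataset",
    "PLDAModel",
    "fit_plda",
    "to_latent",
    "from_latent",
    "class_predictive_logdensity",
    "classify",
    "truncate_psi",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class FeatureDataset:
    """Labelled numeric feature vectors: one row per item.

    Parameters
    ----------
    X : (n, D) array of finite floats.
    labels : length-n sequence of category identifiers.
    categories : ordered list of the distinct categories; derived from
        ``labels`` (sorted) when not given.
    item_ids : optional per-row identifiers; defaults to ``0..n-1``.
    """

    X: np.ndarray
    labels: np.ndarray
    categories: list = field(default_factory=list)
    item_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] < 1:
            raise ValueError("X must be a 2-D table with at least one feature column")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature table contains missing or non-finite values")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.X.shape[0],):
            raise ValueError("labels must have one entry per row of X")
        if not self.categories:
            self.categories = sorted(set(self.labels.tolist()))
        if self.item_ids is None:
            self.item_ids = np.arange(self.X.shape[0])
        else:
            self.item_ids = np.asarray(self.item_ids)

    @property
    def n_items(self) -> int:
        return self.X.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.X.shape[1]

    def rows_for(self, category) -> np.ndarray:
        """Indices of the items belonging to ``category``."""
        return np.flatnonzero(self.labels == category)


@dataclass
class PLDAModel:
    """Fitted PLDA parameters.

    ``shift`` (m) and ``transform`` (A) define the affine map from feature
    space into the latent space; ``psi`` is the diagonal of the latent
    between-class covariance.
    """

    shift: np.ndarray
    transform: np.ndarray
    psi: np.ndarray
    feature_dim: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift, dtype=float)
        self.transform = np.asarray(self.transform, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        D = self.feature_dim
        if self.shift.shape != (D,) or self.transform.shape != (D, D) or self.psi.shape != (D,):
            raise ValueError("inconsistent parameter shapes for feature_dim=%d" % D)
        if not np.all(np.isfinite(self.shift)):
            raise ValueError("shift must be finite")
        if np.any(self.psi < 0):
            raise ValueError("psi must be elementwise nonnegative")

    def to_json(self, path) -> None:
        payload = {
            "shift": self.shift.tolist(),
            "transform": self.transform.ravel().tolist(),  # row-major
            "psi": self.psi.tolist(),
            "feature_dim": int(self.feature_dim),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PLDAModel":
        with open(path) as fh:
            payload = json.load(fh)
        D = int(payload["feature_dim"])
        return cls(
            shift=np.array(payload["shift"]),
            transform=np.array(payload["transform"]).reshape(D, D),
            psi=np.array(payload["psi"]),
            feature_dim=D,
            metadata=payload.get("metadata", {}),
        )


def _scatter_matrices(data: FeatureDataset):
    """Global mean plus within/between scatter, weighted by class counts."""
    X = data.X
    n, D = X.shape
    m = X.mean(axis=0)
    S_w = np.zeros((D, D))
    S_b = np.zeros((D, D))
    counts = []
    for cat in data.categories:
        rows = data.rows_for(cat)
        if rows.size < 2:
            raise ValueError(
                f"category {cat!r} has {rows.size} item(s); at least 2 are required to fit"
            )
        counts.append(rows.size)
        Xc = X[rows]
        mu_c = Xc.mean(axis=0)
        R = Xc - mu_c
        S_w += R.T @ R
        d = mu_c - m
        S_b += rows.size * np.outer(d, d)
    S_w /= n
    S_b /= n
    return m, S_w, S_b, np.array(counts)


def fit_plda(data: FeatureDataset, regularization: float = 1e-6) -> PLDAModel:
    """Fit PLDA by simultaneous diagonalization of the scatter matrices.

    The generalized symmetric eigenproblem ``S_b w = lambda S_w w`` yields
    a basis ``W`` with ``W^T S_w W = I`` and ``W^T S_b W = diag(lambda)``;
    the transform is ``A = W^{-T} sqrt(n/(n-1))`` and the latent
    between-class variances are ``psi = max(0, (n-1)/n * lambda - 1/n)``
    with ``n`` the (average) class size — the bias-corrected ML solution.

    ``regularization`` is added to the diagonal of the within-class scatter;
    with 0 a singular scatter raises, naming the first offending dimension.
    Components are ordered by decreasing psi.
    """
    if regularization < 0:
        raise ValueError("regularization must be nonnegative")
    m, S_w, S_b, counts = _scatter_matrices(data)
    D = data.feature_dim
    if regularization == 0:
        eigvals = np.linalg.eigvalsh(S_w)
        if eigvals[0] <= max(1e-12 * max(eigvals[-1], 1.0), 0.0):
            diag = np.diag(S_w)
            bad = int(np.argmin(diag))
            raise np.linalg.LinAlgError(
                "within-class scatter is singular with regularization=0 "
                f"(feature dimension {bad} has near-zero within-class variance)"
            )
    S_w_reg = S_w + regularization * np.eye(D)
    lam, W = scipy.linalg.eigh(S_b, S_w_reg)  # ascending; W^T S_w_reg W = I
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    W = W[:, order]
    n_bar = counts.mean()
    if n_bar <= 1:
        raise ValueError("need more than one item per class on average")
    A = np.linalg.inv(W).T * np.sqrt(n_bar / (n_bar - 1.0))
    psi = np.clip((n_bar - 1.0) / n_bar * lam - 1.0 / n_bar, 0.0, None)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond):
        raise np.linalg.LinAlgError("fitted transform is numerically singular")
    meta = {
        "regularization": float(regularization),
        "n_items": int(data.n_items),
        "n_categories": len(data.categories),
        "mean_class_size": float(n_bar),
        "transform_condition_number": float(cond),
    }
    return PLDAModel(shift=m, transform=A, psi=psi, feature_dim=D, metadata=meta)


def to_latent(x: np.ndarray, model: PLDAModel) -> np.ndarray:
    """Map a feature vector into latent space: ``u = A^{-1} (x - m)``."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != model.feature_dim:
        raise ValueError(
            f"expected vectors of length {model.feature_dim}, got {x.shape[-1]}"
        )
    return np.linalg.solve(model.transform, (x - model.shift).T).T


def from_latent(u: np.ndarray, model: PLDAModel) -> np.ndarray:
    """Inverse of :func:`to_latent`: ``x = A u + m``."""
    u = np.asarray(u, dtype=float)
    return (model.transform @ u.T).T + model.shift


def class_predictive_logdensity(
    u_star: np.ndarray, examples: Sequence[np.ndarray], psi: np.ndarray
) -> float:
    """Log density of a latent item under the class implied by ``examples``.

    With n latent examples of mean ``ubar``, the class centre has posterior
    N(n psi/(n psi + 1) * ubar, psi/(n psi + 1)) per coordinate, so the
    predictive for a new item is

        N(u* | n psi/(n psi + 1) * ubar,  psi/(n psi + 1) + 1)

    evaluated coordinatewise (psi is the diagonal between-class variance).
    For n = 2 the mean is psi/(2 psi + 1) * (u1 + u2).
    """
    psi = np.asarray(psi, dtype=float)
    if np.any(psi < 0):
        raise ValueError("psi must be elementwise nonnegative")
    U = np.atleast_2d(np.asarray(examples, dtype=float))
    n = U.shape[0]
    if n < 1:
        raise ValueError("need at least one example")
    u_star = np.asarray(u_star, dtype=float)
    if u_star.shape != (U.shape[1],) or psi.shape != (U.shape[1],):
        raise ValueError("u_star, examples and psi must share their dimension")
    ubar = U.mean(axis=0)
    denom = n * psi + 1.0
    mean = n * psi / denom * ubar
    var = psi / denom + 1.0
    z = u_star - mean
    return float(-0.5 * np.sum(LOG_2PI + np.log(var) + z * z / var))


def classify(
    x: np.ndarray,
    model: PLDAModel,
    class_examples: Mapping[object, Sequence[np.ndarray]],
) -> dict:
    """Posterior over categories for a feature vector, uniform class prior.

    ``class_examples`` maps each category to the latent vectors of its
    (training) examples; the posterior is the softmax of the per-class
    predictive log densities of ``to_latent(x)``.
    """
    if len(class_examples) < 2:
        raise ValueError("need at least two categories to classify")
    u = to_latent(x, model)
    cats = list(class_examples)
    logps = np.empty(len(cats))
    for i, cat in enumerate(cats):
        ex = np.asarray(class_examples[cat], dtype=float)
        if ex.size == 0:
            raise ValueError(f"category {cat!r} has no examples")
        logps[i] = class_predictive_logdensity(u, ex, model.psi)
    post = np.exp(log_softmax(logps))
    return dict(zip(cats, post))


def truncate_psi(model: PLDAModel, k: int) -> PLDAModel:
    """Keep only the top-k between-class variances, zeroing the rest.

    Off by default in fitting; provided for very high-dimensional features
    where most latent directions carry no class signal.
    """
    if not 1 <= k <= model.feature_dim:
        raise ValueError("k must be in [1, feature_dim]")
    psi = model.psi.copy()
    keep = np.argsort(psi)[::-1][:k]
    mask = np.zeros_like(psi, dtype=bool)
    mask[keep] = True
    psi[~mask] = 0.0
    return PLDAModel(
        shift=model.shift,
        transform=model.transform,
        psi=psi,
        feature_dim=model.feature_dim,
        metadata={**model.metadata, "psi_truncated_to": int(k)},
    )
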