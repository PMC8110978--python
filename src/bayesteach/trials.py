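"""Confusion-matrix-driven 2AFC stimulus design.

A session probes how well an observer predicts a classifier's behaviour:
each trial shows a target item and two category options, one of which is
the classifier's prediction. Model-correct trials pair the prediction
with one of its two most confusable categories (so agreement is not
trivially inferable from the ground truth); model-error trials pair the
wrong prediction with the ground truth. The default design is 150 trials
with twice as many model errors as correct classifications (50/100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .plda import FeatureDataset

__all__ = [
    "ConfusionMatrix",
    "Trial",
    "SessionManifest",
    "compute_confusion_matrix",
    "select_study_categories",
    "generate_session",
]

MANIFEST_SCHEMA_VERSION = 1


@dataclass
class ConfusionMatrix:
    """Counts of (true category, predicted category) pairs."""

    counts: np.ndarray
    categories: list

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        K = len(self.categories)
        if K < 2 or self.counts.shape != (K, K):
            raise ValueError("counts must be K x K with K >= 2")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    def row_normalized(self) -> np.ndarray:
        rows = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = self.counts / rows
        return np.nan_to_num(P)

    def accuracy(self) -> np.ndarray:
        """Per-category accuracy: row-normalized diagonal."""
        return np.diag(self.row_normalized())

    def confusability(self) -> np.ndarray:
        """Symmetrized off-diagonal confusion: avg of both directions."""
        P = self.row_normalized()
        C = 0.5 * (P + P.T)
        np.fill_diagonal(C, 0.0)
        return C


@dataclass
class Trial:
    """One 2AFC item: the model's prediction versus an alternative."""

    trial_id: int
    target_id: object
    ground_truth: object
    y_star: object
    y_alt: object
    model_correct: bool
    f_L: float | None = None
    policy: str | None = None
    bin: int | None = None
    examples: object = None  # CandidateSet or None
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.y_star == self.y_alt:
            raise ValueError("the two 2AFC options must differ")
        if self.model_correct != (self.y_star == self.ground_truth):
            raise ValueError("model_correct must equal (y_star == ground_truth)")
        if not self.model_correct and self.y_alt != self.ground_truth:
            raise ValueError("model-error trials must offer the ground-truth category")

    @property
    def options(self) -> frozenset:
        return frozenset((self.y_star, self.y_alt))


@dataclass
class SessionManifest:
    """An ordered set of trials plus the design counts that produced it."""

    trials: list[Trial]
    n_correct: int
    n_error: int
    seed: int | None = None
    metadata: dict = field(default_factory=dict)
    schema_version: int = MANIFEST_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if len(self.trials) != self.n_correct + self.n_error:
            raise ValueError("trial count must equal n_correct + n_error")
        got = sum(t.model_correct for t in self.trials)
        if got != self.n_correct:
            raise ValueError(
                f"manifest claims {self.n_correct} model-correct trials but holds {got}"
            )

    def __len__(self) -> int:
        return len(self.trials)


def compute_confusion_matrix(classifier, dataset: FeatureDataset) -> ConfusionMatrix:
    """Confusion counts of the classifier on the dataset (argmax posterior).

    Posterior ties resolve to the lowest category index in
    ``classifier.categories``.
    """
    if dataset.n_items == 0:
        raise ValueError("dataset is empty")
    cats = list(classifier.categories)
    index = {c: i for i, c in enumerate(cats)}
    missing = set(dataset.labels.tolist()) - set(cats)
    if missing:
        raise ValueError(f"dataset labels outside classifier categories: {sorted(missing)}")
    counts = np.zeros((len(cats), len(cats)), dtype=int)
    for label, pred in zip(dataset.labels, _predict_all(classifier, dataset.X)):
        counts[index[label], index[pred]] += 1
    return ConfusionMatrix(counts=counts, categories=cats)


def _predict_all(classifier, X: np.ndarray) -> np.ndarray:
    """All predictions, via the classifier's bulk path when it has one."""
    if hasattr(classifier, "predict_many"):
        return np.asarray(classifier.predict_many(X), dtype=object)
    return np.array([classifier.predict(x) for x in X], dtype=object)


def _rank(scores: np.ndarray, descending: bool = True) -> np.ndarray:
    """Stable ranking with ties broken by category index."""
    idx = np.arange(scores.size)
    key = -scores if descending else scores
    return idx[np.lexsort((idx, key))]


def select_study_categories(
    confusion: ConfusionMatrix,
    k: int = 25,
    pool: int = 100,
    seed: int | None = None,
) -> list:
    """Categories spanning easy, hard, and confusable model behaviour.

    Four pools are formed from the confusion matrix — the ``pool`` most
    accurate categories, those most confusable with them, the ``pool``
    least accurate, and those most confusable with *them* (confusability
    of c with a set = the largest symmetrized off-diagonal row-normalized
    mass between c and any member). ``k`` categories are sampled from each
    pool, unioned and deduplicated.
    """
    K = len(confusion.categories)
    if K < max(2, k):
        raise ValueError(f"need at least {max(2, k)} categories, got {K}")
    pool = min(pool, K)
    rng = substream(seed, "study-categories")
    acc = confusion.accuracy()
    C = confusion.confusability()

    easy = _rank(acc, descending=True)[:pool]
    hard = _rank(acc, descending=False)[:pool]

    def most_confusable_with(members: np.ndarray) -> np.ndarray:
        score = C[:, members].max(axis=1)
        return _rank(score, descending=True)[:pool]

    chosen: set[int] = set()
    for subset in (easy, most_confusable_with(easy), hard, most_confusable_with(hard)):
        take = min(k, subset.size)
        chosen.update(int(i) for i in rng.choice(subset, size=take, replace=False))
    return [confusion.categories[i] for i in sorted(chosen)]


def generate_session(
    classifier,
    dataset: FeatureDataset,
    categories,
    n_correct: int = 50,
    n_error: int = 100,
    seed: int | None = None,
) -> SessionManifest:
    """Build a 2AFC session from the classifier's behaviour on the dataset.

    Targets are items whose ground truth *and* prediction both fall in the
    study ``categories``; ``n_correct`` are drawn from the
    prediction-equals-truth stratum and ``n_error`` from the rest, without
    replacement (no target repeats). Correct trials draw the alternative
    uniformly from the two categories most confusable with the prediction
    within the study set; error trials offer {ground truth, prediction}.
    Trial order is shuffled.
    """
    if n_correct < 0 or n_error < 0 or n_correct + n_error < 1:
        raise ValueError("need at least one trial")
    cats = list(categories)
    cat_set = set(cats)
    preds = _predict_all(classifier, dataset.X)
    in_study = np.array(
        [lab in cat_set and pred in cat_set for lab, pred in zip(dataset.labels, preds)]
    )
    correct_pool = np.flatnonzero(in_study & (preds == dataset.labels))
    error_pool = np.flatnonzero(in_study & (preds != dataset.labels))
    if correct_pool.size < n_correct or error_pool.size < n_error:
        raise ValueError(
            "insufficient items to fill the design: "
            f"{correct_pool.size} model-correct available (need {n_correct}), "
            f"{error_pool.size} model-error available (need {n_error})"
        )

    # study-set confusion for the "two most confusable" alternatives
    sub = dataset.X[in_study]
    sub_ds = FeatureDataset(
        X=sub, labels=dataset.labels[in_study], categories=cats,
        item_ids=dataset.item_ids[in_study],
    )
    # reuse predictions already computed rather than re-running the classifier
    idx = {c: i for i, c in enumerate(cats)}
    counts = np.zeros((len(cats), len(cats)), dtype=int)
    for lab, pred in zip(sub_ds.labels, preds[in_study]):
        counts[idx[lab], idx[pred]] += 1
    confusion = ConfusionMatrix(counts=counts, categories=cats)
    C = confusion.confusability()
    top2 = {}
    for c in cats:
        row = C[idx[c]].copy()
        row[idx[c]] = -np.inf  # a category is never its own alternative
        top2[c] = [cats[j] for j in _rank(row, descending=True)[:2]]

    rng = substream(seed, "session")
    chosen_correct = rng.choice(correct_pool, size=n_correct, replace=False)
    chosen_error = rng.choice(error_pool, size=n_error, replace=False)

    trials: list[Trial] = []
    for i in chosen_correct:
        y_star = preds[i]
        y_alt = top2[y_star][int(rng.integers(2))]
        trials.append(
            Trial(
                trial_id=-1,
                target_id=dataset.item_ids[i],
                ground_truth=dataset.labels[i],
                y_star=y_star,
                y_alt=y_alt,
                model_correct=True,
            )
        )
    for i in chosen_error:
        trials.append(
            Trial(
                trial_id=-1,
                target_id=dataset.item_ids[i],
                ground_truth=dataset.labels[i],
                y_star=preds[i],
                y_alt=dataset.labels[i],
                model_correct=False,
            )
        )
    order = rng.permutation(len(trials))
    trials = [trials[j] for j in order]
    for t_id, trial in enumerate(trials):
        trial.trial_id = t_id
    return SessionManifest(
        trials=trials,
        n_correct=n_correct,
        n_error=n_error,
        seed=seed,
        metadata={"n_items_in_study": int(in_study.sum())},
    )
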