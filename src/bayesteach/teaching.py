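"""Bayesian teaching over example sets.

The teacher scores a candidate explanation — two examples from the
model-predicted category and two from the alternative — by the *simulated
explainee fidelity*: the probability that a probabilistic explainee
(the PLDA model) shown only those four examples would classify the target
the way the target model did. Selection probabilities over the candidate
space are proportional to this fidelity (uniform prior over candidates),
and the experimental conditions are defined by threshold / binning
policies on it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, logsumexp

from ._rng import substream
from .plda import class_predictive_logdensity

__all__ = [
    "CandidateSet",
    "TeachingDistribution",
    "SelectionPolicy",
    "simulated_explainee_fidelity",
    "compute_fidelities",
    "compute_fidelities_batch",
    "teaching_distribution",
    "build_candidate_sets",
    "select_examples",
    "fidelity_bin",
]

logger = logging.getLogger(__name__)


@dataclass
class CandidateSet:
    """One candidate explanation: an unordered pair of item ids per category."""

    pair_target: tuple
    pair_alt: tuple
    fidelity: float | None = None

    def __post_init__(self) -> None:
        if len(self.pair_target) != 2 or len(self.pair_alt) != 2:
            raise ValueError("each pair must contain exactly two item ids")
        if self.pair_target[0] == self.pair_target[1] or self.pair_alt[0] == self.pair_alt[1]:
            raise ValueError("the two items within a pair must be distinct")


@dataclass
class TeachingDistribution:
    """Normalized selection probabilities over a candidate list."""

    candidates: list[CandidateSet]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if len(self.candidates) != self.probabilities.size:
            raise ValueError("candidates and probabilities must be parallel")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")


@dataclass
class SelectionPolicy:
    """How example sets are chosen for trials.

    kind='helpful'    — uniform among candidates with fidelity > helpful_threshold
    kind='random'     — fidelities of the selected sets spread evenly over the
                        n_bins equal-width bins of [0, 1] (round-robin)
    kind='misleading' — uniform among candidates with fidelity < misleading_threshold
    """

    kind: str = "helpful"
    helpful_threshold: float = 0.8
    misleading_threshold: float = 0.2
    n_bins: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("helpful", "random", "misleading"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if not 0.0 < self.misleading_threshold < self.helpful_threshold < 1.0:
            raise ValueError(
                "thresholds must satisfy 0 < misleading_threshold < helpful_threshold < 1"
            )
        if self.n_bins < 1:
            raise ValueError("n_bins must be at least 1")


def simulated_explainee_fidelity(
    target: np.ndarray,
    pair_target: Sequence[np.ndarray],
    pair_alt: Sequence[np.ndarray],
    psi: np.ndarray,
) -> float:
    """Probability the explainee assigns the target to the taught category.

    With equal priors on the two categories this is the density ratio

        f(d* | pair_target) / (f(d* | pair_target) + f(d* | pair_alt)),

    computed in log space from the closed-form class-predictive densities,
    so it stays finite even when both raw densities underflow.
    """
    l_t = class_predictive_logdensity(target, pair_target, psi)
    l_a = class_predictive_logdensity(target, pair_alt, psi)
    if not (math.isfinite(l_t) or math.isfinite(l_a)):
        raise ArithmeticError(
            f"both class-predictive log densities are non-finite ({l_t}, {l_a}); "
            "check the latent vectors and psi for overflow"
        )
    return float(expit(l_t - l_a))


def compute_fidelities(
    candidates: Sequence[CandidateSet],
    target: np.ndarray,
    latents: Mapping[object, np.ndarray],
    psi: np.ndarray,
) -> list[CandidateSet]:
    """Fill the cached fidelity of each candidate in place and return them.

    ``latents`` maps item ids (as used in the candidate pairs) to latent
    vectors.
    """
    for cand in candidates:
        u_t = [latents[i] for i in cand.pair_target]
        u_a = [latents[i] for i in cand.pair_alt]
        cand.fidelity = simulated_explainee_fidelity(target, u_t, u_a, psi)
    return list(candidates)


def compute_fidelities_batch(
    candidates: Sequence[CandidateSet],
    target: np.ndarray,
    latents: Mapping[object, np.ndarray],
    psi: np.ndarray,
) -> list[CandidateSet]:
    """Fast path of :func:`compute_fidelities` for large candidate pools.

    Candidate pools built as a Cartesian product share a small number of
    distinct pairs, so the class-predictive log density is evaluated once
    per distinct pair and the fidelities follow from a vectorized sigmoid
    of the log-density differences. Numerically identical to the
    per-candidate path.
    """
    cache: dict[tuple, float] = {}

    def logdens(pair: tuple) -> float:
        key = tuple(sorted(pair, key=repr))
        if key not in cache:
            cache[key] = class_predictive_logdensity(
                target, [latents[i] for i in pair], psi
            )
        return cache[key]

    l_t = np.array([logdens(c.pair_target) for c in candidates])
    l_a = np.array([logdens(c.pair_alt) for c in candidates])
    f = expit(l_t - l_a)
    for cand, fi in zip(candidates, f):
        cand.fidelity = float(fi)
    return list(candidates)


def teaching_distribution(candidates: Sequence[CandidateSet]) -> TeachingDistribution:
    """Selection probabilities proportional to fidelity over the candidates.

    Normalization is done through log-sum-exp; the candidate list provided
    is the implemented candidate space.
    """
    if len(candidates) < 1:
        raise ValueError("need at least one candidate")
    f = np.array([c.fidelity for c in candidates], dtype=float)
    if np.any(np.isnan(f)):
        raise ValueError("all candidates must have computed fidelities")
    if np.all(f == 0):
        raise ZeroDivisionError("degenerate teaching distribution: every fidelity is 0")
    with np.errstate(divide="ignore"):
        logf = np.log(f)
    probs = np.exp(logf - logsumexp(logf))
    return TeachingDistribution(candidates=list(candidates), probabilities=probs)


def _pair_from_rank(rank: int, n: int) -> tuple[int, int]:
    """Unrank an unordered index pair from 0..n(n-1)/2-1 (lexicographic)."""
    i = int((2 * n - 1 - math.sqrt((2 * n - 1) ** 2 - 8 * rank)) // 2)
    # guard against float edge cases
    while rank >= (i + 1) * n - (i + 1) * (i + 2) // 2:
        i += 1
    while rank < i * n - i * (i + 1) // 2:
        i -= 1
    j = rank - (i * n - i * (i + 1) // 2) + i + 1
    return i, j


def _sample_pairs(items: Sequence, n_pairs: int, rng: np.random.Generator) -> list[tuple]:
    n = len(items)
    if n < 2:
        raise ValueError("need at least two items per category to form pairs")
    total = n * (n - 1) // 2
    if n_pairs >= total:
        if n_pairs > total:
            logger.info(
                "requested %d pairs but only %d distinct pairs exist; "
                "enumerating all of them",
                n_pairs,
                total,
            )
        return [(items[i], items[j]) for i in range(n) for j in range(i + 1, n)]
    ranks = rng.choice(total, size=n_pairs, replace=False)
    return [tuple(items[k] for k in _pair_from_rank(int(r), n)) for r in ranks]


def build_candidate_sets(
    items_target: Sequence,
    items_alt: Sequence,
    n_pairs_per_category: int = 1000,
    seed: int | None = None,
) -> list[CandidateSet]:
    """Cartesian product of sampled unordered example pairs per category.

    Pairs are distinct-item, duplicate-free; requesting more pairs than
    exist falls back to full enumeration. The candidate count is the
    product of the two pair counts.
    """
    if n_pairs_per_category < 1:
        raise ValueError("n_pairs_per_category must be at least 1")
    rng_t = substream(seed, "candidate-pairs-target")
    rng_a = substream(seed, "candidate-pairs-alt")
    pairs_t = _sample_pairs(items_target, n_pairs_per_category, rng_t)
    pairs_a = _sample_pairs(items_alt, n_pairs_per_category, rng_a)
    return [CandidateSet(pair_target=pt, pair_alt=pa) for pt in pairs_t for pa in pairs_a]


def fidelity_bin(f: float, n_bins: int = 5) -> int:
    """Equal-width bin index of a fidelity in [0, 1]; 1.0 joins the top bin."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("fidelity must be in [0, 1]")
    return min(int(f * n_bins), n_bins - 1)


def select_examples(
    candidates: Sequence[CandidateSet],
    policy: SelectionPolicy,
    n_trials: int,
) -> list[tuple[CandidateSet, int]]:
    """Draw n_trials example sets under the policy; returns (candidate, bin).

    helpful/misleading draw uniformly within the threshold stratum and fail
    hard when it is empty (the stratum defines the condition). The random
    policy cycles through the fidelity bins round-robin so the per-bin
    counts are as equal as possible; an empty bin falls back to the nearest
    non-empty bin with a logged warning.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    f = np.array([c.fidelity for c in candidates], dtype=float)
    if f.size == 0 or np.any(np.isnan(f)):
        raise ValueError("candidates must be non-empty with computed fidelities")
    rng = substream(policy.seed, "selection")
    n_bins = policy.n_bins

    if policy.kind == "helpful":
        stratum = np.flatnonzero(f > policy.helpful_threshold)
        if stratum.size == 0:
            raise ValueError(
                f"no candidate has fidelity > {policy.helpful_threshold}; "
                "the helpful condition is infeasible on this candidate pool"
            )
        picks = rng.choice(stratum, size=n_trials)
        return [(candidates[i], fidelity_bin(f[i], n_bins)) for i in picks]

    if policy.kind == "misleading":
        stratum = np.flatnonzero(f < policy.misleading_threshold)
        if stratum.size == 0:
            raise ValueError(
                f"no candidate has fidelity < {policy.misleading_threshold}; "
                "the misleading condition is infeasible on this candidate pool"
            )
        picks = rng.choice(stratum, size=n_trials)
        return [(candidates[i], fidelity_bin(f[i], n_bins)) for i in picks]

    # random policy: even coverage of the fidelity bins
    bins = np.minimum((f * n_bins).astype(int), n_bins - 1)
    by_bin = [np.flatnonzero(bins == b) for b in range(n_bins)]
    nonempty = [b for b in range(n_bins) if by_bin[b].size > 0]
    if not nonempty:
        raise ValueError("no candidates available in any fidelity bin")
    out: list[tuple[CandidateSet, int]] = []
    for t in range(n_trials):
        b = t % n_bins
        if by_bin[b].size == 0:
            nearest = min(nonempty, key=lambda nb: (abs(nb - b), nb))
            logger.warning(
                "fidelity bin %d/%d is empty; falling back to nearest non-empty bin %d",
                b,
                n_bins,
                nearest,
            )
            b = nearest
        i = int(rng.choice(by_bin[b]))
        out.append((candidates[i], int(bins[i])))
    return out
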