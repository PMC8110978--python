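"""Idealized explainee agents and second-order fidelity metrics.

Fidelity here is agreement with the *model's* prediction, not with the
ground truth: sensitivity is fidelity on trials the model got right,
specificity is fidelity on trials it got wrong. Three reference agents
bracket the space of observers: one guessing uniformly (50% everywhere),
one with a perfect model of the classifier (100% everywhere), and a
belief-projecting agent that assumes the classifier mirrors its own
(perfect first-order) judgement — always answering the ground truth, for
100% sensitivity, 0% specificity, and 1/3 fidelity on a design with twice
as many model errors as correct classifications.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .trials import SessionManifest

__all__ = [
    "AgentResponseTable",
    "FidelityReport",
    "simulate_agent",
    "fidelity_metrics",
    "familiarity_score",
    "AGENT_KINDS",
]

AGENT_KINDS = ("random", "perfect", "belief_projecting")


@dataclass
class AgentResponseTable:
    """Per-trial choices of one simulated agent."""

    agent: str
    trial_ids: list
    choices: list
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.trial_ids) != len(self.choices):
            raise ValueError("trial_ids and choices must be parallel")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trial_id": self.trial_ids, "agent": self.agent, "choice": self.choices}
        )


@dataclass
class FidelityReport:
    """Fidelity and its decomposition; undefined strata stay None, never 0."""

    fidelity: float | None
    sensitivity: float | None
    specificity: float | None
    counts: dict = field(default_factory=dict)


def simulate_agent(kind: str, manifest: SessionManifest, seed: int | None = None) -> AgentResponseTable:
    """Simulate one idealized agent over every trial of a session.

    random — uniform over the two options; perfect — always the model's
    prediction; belief_projecting — always the ground-truth category
    (guaranteed to be an option by the manifest invariants).
    """
    if kind not in AGENT_KINDS:
        raise ValueError(f"unknown agent kind {kind!r}; expected one of {AGENT_KINDS}")
    rng = substream(seed, f"agent-{kind}")
    trial_ids, choices = [], []
    for trial in manifest.trials:
        if kind == "random":
            choice = trial.y_star if rng.integers(2) == 0 else trial.y_alt
        elif kind == "perfect":
            choice = trial.y_star
        else:
            if trial.ground_truth not in trial.options:
                raise ValueError(
                    f"trial {trial.trial_id} does not offer its ground truth; "
                    "the belief-projecting agent is undefined on it"
                )
            choice = trial.ground_truth
        trial_ids.append(trial.trial_id)
        choices.append(choice)
    return AgentResponseTable(agent=kind, trial_ids=trial_ids, choices=choices, seed=seed)


def fidelity_metrics(responses: AgentResponseTable, manifest: SessionManifest) -> FidelityReport:
    """Fidelity, sensitivity and specificity of a response table.

    fidelity = P(choice == model prediction) over all trials; sensitivity
    restricts to model-correct trials, specificity to model-error trials.
    An empty stratum yields None for its metric.
    """
    by_trial = dict(zip(responses.trial_ids, responses.choices))
    missing = [t.trial_id for t in manifest.trials if t.trial_id not in by_trial]
    if missing:
        raise ValueError(f"responses missing for trials {missing[:5]}...")
    agree_correct = agree_error = 0
    n_correct = n_error = 0
    for trial in manifest.trials:
        agree = by_trial[trial.trial_id] == trial.y_star
        if trial.model_correct:
            n_correct += 1
            agree_correct += agree
        else:
            n_error += 1
            agree_error += agree
    total = n_correct + n_error
    return FidelityReport(
        fidelity=(agree_correct + agree_error) / total if total else None,
        sensitivity=agree_correct / n_correct if n_correct else None,
        specificity=agree_error / n_error if n_error else None,
        counts={
            "n_trials": total,
            "n_correct": n_correct,
            "n_error": n_error,
            "agree_correct": agree_correct,
            "agree_error": agree_error,
        },
    )


def familiarity_score(ratings) -> float:
    """Mean of binary familiarity judgements across raters."""
    arr = np.asarray(ratings)
    if arr.size < 1:
        raise ValueError("need at least one rater")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("ratings must be binary (0 or 1)")
    return float(arr.mean())
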