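"""Run configuration: one validated object for a full teaching session.

Defaults are the study's printed parameters: 224x224 masks with GP mean
-100, marginal sd 100, length scale 22.4 px and 1000 Monte Carlo samples;
helpful threshold 0.8 with five fidelity bins; 1000 sampled pairs per
category; 50 model-correct and 100 model-error trials.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .saliency import GPMaskConfig
from .teaching import SelectionPolicy

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]

_SESSION_KEYS = {"n_correct", "n_error", "n_pairs_per_category"}
_BACKEND_KEYS = {
    "kind", "n_categories", "items_per_category", "feature_dim",
    "height", "width", "images_per_category", "noise_sd", "gain",
}
_TOP_KEYS = {"backend", "mask", "policy", "session", "seed", "output_dir"}


@dataclass
class RunConfig:
    backend: dict = field(default_factory=lambda: {"kind": "gaussian"})
    mask: GPMaskConfig = field(default_factory=GPMaskConfig)
    policy: SelectionPolicy = field(default_factory=SelectionPolicy)
    n_correct: int = 50
    n_error: int = 100
    n_pairs_per_category: int = 1000
    seed: int | None = None
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.n_correct < 0 or self.n_error < 0:
            raise ValueError("session counts n_correct/n_error must be nonnegative")
        if self.n_pairs_per_category < 1:
            raise ValueError("n_pairs_per_category must be at least 1")
        if self.seed is not None and not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        unknown = set(self.backend) - _BACKEND_KEYS
        if unknown:
            raise ValueError(f"unknown backend keys: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return {
            "backend": dict(self.backend),
            "mask": dataclasses.asdict(self.mask),
            "policy": dataclasses.asdict(self.policy),
            "session": {
                "n_correct": self.n_correct,
                "n_error": self.n_error,
                "n_pairs_per_category": self.n_pairs_per_category,
            },
            "seed": self.seed,
            "output_dir": self.output_dir,
        }


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {where}: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    An empty file yields the all-defaults config; unknown keys raise with
    their names; invalid values raise naming the field and constraint.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping at the top level")
    _check_keys(raw, _TOP_KEYS, "config")
    mask_raw = dict(raw.get("mask", {}))
    _check_keys(mask_raw, {f.name for f in dataclasses.fields(GPMaskConfig)}, "mask")
    policy_raw = dict(raw.get("policy", {}))
    _check_keys(policy_raw, {f.name for f in dataclasses.fields(SelectionPolicy)}, "policy")
    session_raw = dict(raw.get("session", {}))
    _check_keys(session_raw, _SESSION_KEYS, "session")
    return RunConfig(
        backend=dict(raw.get("backend", {"kind": "gaussian"})),
        mask=GPMaskConfig(**mask_raw),
        policy=SelectionPolicy(**policy_raw),
        n_correct=session_raw.get("n_correct", 50),
        n_error=session_raw.get("n_error", 100),
        n_pairs_per_category=session_raw.get("n_pairs_per_category", 1000),
        seed=raw.get("seed"),
        output_dir=raw.get("output_dir", "."),
    )


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    """Stable hash of the full configuration, for output provenance."""
    canon = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
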