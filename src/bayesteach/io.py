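"""Readers and writers for the package's plain-text formats.

Features travel as CSV (a ``label`` column plus numeric feature columns)
or JSON; fitted models as JSON; session manifests as CSV/JSON with a
schema version; saliency grids as CSV for bit-exact comparison; rendered
maps and toy images as PNG. Every writer has a lossless reader
counterpart, and :func:`write_sidecar` records config hash, seed and
library versions next to any output.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .plda import FeatureDataset
from .trials import MANIFEST_SCHEMA_VERSION, SessionManifest, Trial

__all__ = [
    "read_features",
    "write_features",
    "read_manifest",
    "write_manifest",
    "write_responses",
    "read_saliency_csv",
    "write_saliency_csv",
    "load_image",
    "save_image",
    "write_sidecar",
]

_MANIFEST_COLUMNS = [
    "trial_id", "target_id", "ground_truth", "y_star", "y_alt", "model_correct",
    "f_L", "policy", "bin", "example_target_1", "example_target_2",
    "example_alt_1", "example_alt_2", "condition",
]


def write_features(dataset: FeatureDataset, path) -> None:
    path = Path(path)
    df = pd.DataFrame(dataset.X, columns=[f"f{i}" for i in range(dataset.feature_dim)])
    df.insert(0, "label", dataset.labels)
    if path.suffix == ".json":
        payload = {
            "labels": dataset.labels.tolist(),
            "features": dataset.X.tolist(),
            "categories": list(dataset.categories),
        }
        path.write_text(json.dumps(payload))
    else:
        df.to_csv(path, index=False, float_format="%.17g")


def read_features(path) -> FeatureDataset:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        return FeatureDataset(
            X=np.array(payload["features"], dtype=float),
            labels=np.array(payload["labels"]),
            categories=list(payload.get("categories", [])),
        )
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError("feature CSV must contain a 'label' column")
    X = df.drop(columns=["label"]).to_numpy(dtype=float)
    return FeatureDataset(X=X, labels=df["label"].to_numpy())


def _float_or_empty(x) -> str:
    return "" if x is None else repr(float(x))


def write_manifest(manifest: SessionManifest, path) -> None:
    """Write a session manifest as CSV (or JSON for a ``.json`` path)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "schema_version": manifest.schema_version,
            "n_correct": manifest.n_correct,
            "n_error": manifest.n_error,
            "seed": manifest.seed,
            "metadata": manifest.metadata,
            "trials": [_trial_record(t) for t in manifest.trials],
        }
        path.write_text(json.dumps(payload))
        return
    rows = []
    for t in manifest.trials:
        rec = _trial_record(t)
        rec["f_L"] = _float_or_empty(rec["f_L"])
        rows.append(rec)
    df = pd.DataFrame(rows, columns=_MANIFEST_COLUMNS)
    with open(path, "w", newline="") as fh:
        fh.write(
            f"# bayesteach manifest schema={manifest.schema_version} "
            f"n_correct={manifest.n_correct} n_error={manifest.n_error} "
            f"seed={manifest.seed if manifest.seed is not None else ''}\n"
        )
        df.to_csv(fh, index=False)


def _trial_record(t: Trial) -> dict:
    ex = t.examples
    return {
        "trial_id": t.trial_id,
        "target_id": t.target_id,
        "ground_truth": t.ground_truth,
        "y_star": t.y_star,
        "y_alt": t.y_alt,
        "model_correct": t.model_correct,
        "f_L": t.f_L,
        "policy": t.policy,
        "bin": t.bin,
        "example_target_1": ex.pair_target[0] if ex else None,
        "example_target_2": ex.pair_target[1] if ex else None,
        "example_alt_1": ex.pair_alt[0] if ex else None,
        "example_alt_2": ex.pair_alt[1] if ex else None,
        "condition": t.condition,
    }


def _trial_from_record(rec: dict) -> Trial:
    from .teaching import CandidateSet

    examples = None
    if rec.get("example_target_1") is not None:
        examples = CandidateSet(
            pair_target=(rec["example_target_1"], rec["example_target_2"]),
            pair_alt=(rec["example_alt_1"], rec["example_alt_2"]),
            fidelity=rec.get("f_L"),
        )
    return Trial(
        trial_id=int(rec["trial_id"]),
        target_id=rec["target_id"],
        ground_truth=rec["ground_truth"],
        y_star=rec["y_star"],
        y_alt=rec["y_alt"],
        model_correct=bool(rec["model_correct"]),
        f_L=rec.get("f_L"),
        policy=rec.get("policy"),
        bin=rec.get("bin"),
        examples=examples,
        condition=rec.get("condition"),
    )


def read_manifest(path) -> SessionManifest:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        version = payload.get("schema_version")
        if version != MANIFEST_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported manifest schema version {version!r}; "
                f"this reader supports version {MANIFEST_SCHEMA_VERSION}"
            )
        trials = [_trial_from_record(r) for r in payload["trials"]]
        return SessionManifest(
            trials=trials,
            n_correct=payload["n_correct"],
            n_error=payload["n_error"],
            seed=payload.get("seed"),
            metadata=payload.get("metadata", {}),
        )
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# bayesteach manifest"):
            raise ValueError("not a bayesteach manifest CSV (missing header comment)")
        fields = dict(
            kv.split("=", 1) for kv in header.removeprefix("# bayesteach manifest").split()
        )
        version = int(fields.get("schema", -1))
        if version != MANIFEST_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported manifest schema version {version}; "
                f"this reader supports version {MANIFEST_SCHEMA_VERSION}"
            )
        df = pd.read_csv(fh)
    trials = []
    for rec in df.to_dict(orient="records"):
        clean = {
            k: (None if (isinstance(v, float) and math.isnan(v)) else v)
            for k, v in rec.items()
        }
        if clean.get("bin") is not None:
            clean["bin"] = int(clean["bin"])
        trials.append(_trial_from_record(clean))
    seed_s = fields.get("seed", "")
    return SessionManifest(
        trials=trials,
        n_correct=int(fields["n_correct"]),
        n_error=int(fields["n_error"]),
        seed=int(seed_s) if seed_s else None,
    )


def write_responses(tables, path) -> None:
    """Concatenate agent response tables into one tidy CSV."""
    frames = [t.to_frame() for t in tables]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_saliency_csv(values: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(values, dtype=float), delimiter=",", fmt="%.17g")


def read_saliency_csv(path) -> np.ndarray:
    return np.loadtxt(path, delimiter=",", ndmin=2)


def save_image(image: np.ndarray, path) -> None:
    """Save a float image in [0, 1] (grayscale or RGB) as 8-bit PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255).round().astype(np.uint8)).save(path)


def load_image(path) -> np.ndarray:
    """Load an image as a float array scaled to [0, 1]."""
    return np.asarray(Image.open(path), dtype=float) / 255.0


def write_sidecar(out_path, seed=None, config=None, extra=None) -> None:
    """Write provenance metadata next to an output file."""
    import matplotlib
    import scipy

    from . import __version__
    from .config import config_hash

    meta = {
        "bayesteach_version": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "matplotlib": matplotlib.__version__,
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
    }
    if extra:
        meta.update(extra)
    Path(str(out_path) + ".meta.json").write_text(json.dumps(meta, indent=2))
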