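"""Named random substreams so one session seed reproduces every stage."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int | None, name: str) -> np.random.Generator:
    """Return a Generator for the named stage of a seeded session.

    Distinct names yield statistically independent streams from the same
    session seed (dataset, masks, selection, agents, ...). ``seed=None``
    gives fresh OS entropy.
    """
    if seed is None:
        return np.random.default_rng()
    tag = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
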