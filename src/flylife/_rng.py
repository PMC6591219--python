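"""Seed plumbing: one master seed deterministically derives per-stage streams."""

from __future__ import annotations

import numpy as np

# Stage names get stable integer tags so that adding a stage never shifts
# the streams of existing ones.
_STAGE_TAGS = {
    "lifespan": 11,
    "activity": 12,
    "fecundity": 13,
    "catalog": 14,
    "truth": 15,
    "counts": 16,
    "calibration": 21,
    "benchmark": 22,
}


def derive_seedseq(seed: int, stage: str, index: int = 0) -> np.random.SeedSequence:
    """SeedSequence for ``stage`` derived from the master ``seed``."""
    tag = _STAGE_TAGS.get(stage)
    if tag is None:
        raise KeyError(f"unknown rng stage: {stage!r}")
    return np.random.SeedSequence([int(seed) % (2**31), tag, int(index)])


def derive_rng(seed, stage: str, index: int = 0) -> np.random.Generator:
    """Return a Generator for ``stage`` derived from the master ``seed``.

    The same (seed, stage, index) triple always yields the same stream;
    distinct triples yield statistically independent streams.  ``seed`` may
    also be a Generator (returned as-is) or a SeedSequence, so replicate
    studies can hand down properly spawned child streams.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, np.random.SeedSequence):
        return np.random.default_rng(seed)
    return np.random.default_rng(derive_seedseq(seed, stage, index))
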