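"""Deterministic seed fan-out.

One pipeline-level seed expands into named per-stage child seeds so that
every stochastic stage is independently reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable 31-bit child seed for a named stage."""
    tag = zlib.crc32(stage.encode("utf-8"))
    return int(np.random.SeedSequence([int(seed), tag]).generate_state(1)[0] % (2**31))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator seeded from ``seed`` and the stage name."""
    return np.random.default_rng(stage_seed(seed, stage))
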