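"""Deterministic per-stage random streams from one global seed."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for a named pipeline stage.

    The stream depends only on (seed, stage name), so adding or removing
    stages never perturbs the randomness seen by other stages.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stage.encode("utf-8"))])
    )
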