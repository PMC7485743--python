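"""Deterministic per-stage random streams.

A single user-facing seed is expanded into independent streams keyed by
stage name, so adding or reordering one stage never perturbs the draws
of another.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator for a named stage, derived from the global seed."""
    key = zlib.crc32(stage.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))
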