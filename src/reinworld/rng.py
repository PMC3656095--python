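"""Seeding policy: one root seed per run, forked per stage by stable label.

Each pipeline stage derives its own independent stream from the run seed
and a short text label, so adding or reordering stages never perturbs the
draws of another stage, and identical (seed, label) pairs always
reproduce identical streams.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_seed(seed: int, label: str) -> list[int]:
    """Entropy for a stage stream: the run seed plus a stable label hash."""
    return [int(seed), zlib.crc32(label.encode("utf-8"))]


def stage_rng(seed: int, label: str) -> np.random.Generator:
    """Independent generator for stage ``label`` of run ``seed``."""
    return np.random.default_rng(stage_seed(seed, label))
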