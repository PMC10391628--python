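"""Seeding utilities.

A single run seed is expanded into independent, named substreams so that
changing the number of draws in one stage (e.g. bootstrap count) never
perturbs the random stream of another stage.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "substream_key"]


def substream_key(*labels: object) -> tuple[int, ...]:
    """Map an arbitrary label path to a stable spawn key (tuple of uint32)."""
    h = hashlib.sha256("\x1f".join(str(x) for x in labels).encode()).digest()
    return tuple(int.from_bytes(h[i : i + 4], "big") for i in range(0, 16, 4))


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Independent generator for stage/sample `labels` under a run `seed`.

    Identical (seed, labels) always yields an identical stream; distinct
    label paths yield statistically independent streams.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=substream_key(*labels))
    return np.random.default_rng(ss)
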