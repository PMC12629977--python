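"""Named, counter-based random streams.

Every stochastic operation in the package draws from a Philox generator keyed
by ``(seed, *tags)`` where the tags name the operation and any per-item
indices.  No global RNG state is ever used, so any output is a pure function
of its arguments and reproducible across platforms and call orders.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "child_seed"]

_MAX_SEED = 2**31


def _tag_to_int(tag: object) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) & 0xFFFFFFFF
    return zlib.crc32(str(tag).encode("utf-8"))


def stream(seed: int, *tags: object) -> np.random.Generator:
    """Return a Generator for the stream named by ``(seed, *tags)``.

    Distinct tag tuples give statistically independent streams; identical
    tuples give identical streams.
    """
    key = [int(seed) % _MAX_SEED] + [_tag_to_int(t) for t in tags]
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(key)))


def child_seed(seed: int, *tags: object) -> int:
    """Derive a sub-seed (< 2**31) from a master seed and stream tags."""
    return int(stream(seed, *tags, "child").integers(0, _MAX_SEED))
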