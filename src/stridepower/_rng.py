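"""Named, seedable random substreams.

All randomness in the package flows from one top-level integer seed. Each
logical unit of work (a replicate, a grid cell, a subject) draws from an
independent Generator keyed by (seed, *labels), so results are reproducible
regardless of evaluation order and safe to parallelise.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    raise TypeError(f"substream keys must be int or str, got {type(key)!r}")


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream identified by ``(seed, *keys)``.

    Parameters
    ----------
    seed : int
        Top-level run seed.
    *keys : int or str
        Labels identifying the unit of work, e.g. ``("fgn", length, rep)``.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
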