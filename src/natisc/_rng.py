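"""Named, reproducible random streams.

A single user-facing integer seed is expanded into independent
substreams keyed by strings ("signal", "noise", participant ids, ...),
so that each simulated quantity is reproducible regardless of the order
in which the generating functions are called.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream_rng"]


def stream_rng(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream identified by ``keys``.

    The stream is a deterministic function of ``seed`` and the key
    strings; distinct key tuples give statistically independent streams
    (via ``SeedSequence`` spawn keys derived from CRC32 of each key).
    """
    if not (0 <= int(seed) < 2**63):
        raise ValueError(f"seed must be a non-negative integer, got {seed!r}")
    spawn_key = tuple(zlib.crc32(str(k).encode("utf8")) for k in keys)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=spawn_key)
    return np.random.default_rng(ss)
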