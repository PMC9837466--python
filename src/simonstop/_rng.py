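"""Named random substreams.

Every source of randomness in the package derives from a single master seed
through a named substream, so that reruns with the same seed are bit-identical
and the streams for design, behavior, EEG noise and permutations never alias.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The spawn key is built from CRC32 hashes of the name path, so the same
    (seed, names) pair always yields the same stream and distinct name paths
    yield statistically independent streams.
    """
    key = tuple(zlib.crc32(n.encode("utf-8")) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))
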