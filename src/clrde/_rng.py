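"""Deterministic random-stream derivation.

All randomness in the pipeline flows from one user seed.  Substreams are
keyed by *content* (sample identifiers, condition membership, purpose tags),
never by column or row position, so that permuting the input table or
renaming condition labels cannot change the draws attached to a sample.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["hash_id", "substream"]


def hash_id(s: str) -> int:
    """Stable 63-bit integer digest of a string identifier."""
    h = hashlib.sha256(s.encode("utf-8")).digest()
    return int.from_bytes(h[:8], "little") & 0x7FFF_FFFF_FFFF_FFFF


def substream(seed: int, *keys: str | int) -> np.random.Generator:
    """A Generator keyed by ``seed`` and a tuple of content keys.

    String keys are hashed; integer keys are used as-is.  The same
    (seed, keys) pair always yields a bit-identical stream.
    """
    entropy = [int(seed) & 0x7FFF_FFFF]
    for k in keys:
        entropy.append(hash_id(k) if isinstance(k, str) else int(k))
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(entropy)))
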