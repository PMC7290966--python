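"""Deterministic sub-seed derivation.

Every stochastic stage of an analysis draws its randomness from a seed
derived by hashing the master seed together with a tuple of string/number
tokens naming the stage (e.g. ``(subject_id, "sweep", T_index, run)``).
This makes every simulation independently reproducible without threading
generator state through the pipeline.
"""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, *tokens: object) -> int:
    """Derive a 31-bit seed from a master seed and a token tuple.

    The derivation is a SHA-256 hash of the repr of the tokens, so it is
    stable across processes and platforms and insensitive to numpy RNG
    internals.
    """
    key = repr((int(master_seed),) + tokens).encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:4], "big") & 0x7FFFFFFF
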