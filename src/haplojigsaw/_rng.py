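"""Deterministic seed derivation.

Every source of randomness in the package is a :class:`numpy.random.Generator`
derived from a single master seed plus a path of context keys (stage name,
autosome, iteration index, ...).  String keys are mixed in via CRC32 so the
scheme is stable across runs and platforms.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed_sequence"]


def _key_to_uint32(key: int | str) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8")) & 0xFFFFFFFF
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    raise TypeError(f"seed key must be int or str, got {type(key)!r}")


def derive_seed_sequence(master_seed: int, *keys: int | str) -> np.random.SeedSequence:
    """SeedSequence for ``master_seed`` refined by a path of context keys."""
    return np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=tuple(_key_to_uint32(k) for k in keys)
    )


def derive_rng(master_seed: int, *keys: int | str) -> np.random.Generator:
    """Generator seeded from ``master_seed`` and a path of context keys."""
    return np.random.default_rng(derive_seed_sequence(master_seed, *keys))
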