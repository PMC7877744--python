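"""Seed-substream derivation.

One master integer seed drives every random choice in the pipeline. Substreams
are derived with ``numpy.random.SeedSequence`` keyed on the master seed plus a
tuple of stable integer keys; string keys (task names, DOF names, conditions)
are mapped to integers through CRC-32 so the scheme is reproducible across
runs, platforms and process restarts. Any single trial, iteration or k-means
replicate can therefore be regenerated in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        if key < 0:
            raise ValueError(f"seed keys must be non-negative, got {key}")
        return int(key)
    return zlib.crc32(str(key).encode("utf-8"))


def seed_sequence(master_seed: int, *keys: int | str) -> np.random.SeedSequence:
    """SeedSequence for the substream identified by ``keys`` under ``master_seed``."""
    return np.random.SeedSequence([int(master_seed)] + [_key_to_int(k) for k in keys])


def substream(master_seed: int, *keys: int | str) -> np.random.Generator:
    """Independent Generator for the substream identified by ``keys``."""
    return np.random.default_rng(seed_sequence(master_seed, *keys))


def subseed(master_seed: int, *keys: int | str) -> int:
    """A 31-bit integer seed for APIs that take a plain int."""
    return int(seed_sequence(master_seed, *keys).generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
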