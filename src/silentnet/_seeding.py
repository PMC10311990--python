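"""Deterministic seed derivation.

All randomness in the package flows from a single master seed. Sub-streams
for independent stages (weight construction, raster generation, stimulation,
training, testing) are derived by hashing the master seed together with a
stage path, so any single stage or replicate can be re-run in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def _tag_to_int(tag: object) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) & 0xFFFFFFFF
    return zlib.crc32(str(tag).encode("utf-8"))


def derive_seed(master_seed: int, *path: object) -> int:
    """Derive a child seed (< 2**31) from a master seed and a stage path.

    The same (master_seed, path) always yields the same child seed, and
    distinct paths yield statistically independent streams.
    """
    ss = np.random.SeedSequence([int(master_seed)] + [_tag_to_int(t) for t in path])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def derive_rng(master_seed: int, *path: object) -> np.random.Generator:
    """Return a numpy Generator seeded from ``derive_seed(master_seed, *path)``."""
    return np.random.default_rng(derive_seed(master_seed, *path))
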