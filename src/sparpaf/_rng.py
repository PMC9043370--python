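"""Deterministic RNG derivation.

A single global seed is fanned out to per-stage / per-subject generators via
``numpy.random.SeedSequence`` with a stable key derived from string or integer
labels, so re-running one stage never perturbs the random stream of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def derive_seed(seed: int, *keys: int | str) -> int:
    """Derive a child seed (< 2**31) from ``seed`` and a label path."""
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *(_key_to_int(k) for k in keys)])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) & 0x7FFFFFFF


def derive_rng(seed: int, *keys: int | str) -> np.random.Generator:
    """A ``numpy.random.Generator`` keyed by ``seed`` and a label path."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *(_key_to_int(k) for k in keys)])
    )
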