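"""Shared helpers: seed derivation and validation."""

from __future__ import annotations

import hashlib

import numpy as np

MAX_SEED = 2**31 - 1


def derive_seed(root_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from a root seed and a stage name.

    Uses blake2s of ``"{root_seed}:{stage}"`` reduced mod 2**31-1 so the
    mapping is stable across runs, platforms and Python hash randomization.
    """
    digest = hashlib.blake2s(f"{root_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % MAX_SEED


def as_rng(rng) -> np.random.Generator:
    """Coerce an int seed / Generator / None into a numpy Generator."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def check_fraction(name: str, value: float) -> float:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value!r}")
    return float(value)
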