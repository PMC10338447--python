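"""Small shared helpers: seed derivation and validation."""

from __future__ import annotations

import hashlib

import numpy as np


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed deterministically from a master seed.

    Uses SHA-256 of ``"{master_seed}:{stage}"`` truncated to 31 bits so the
    result is a valid seed everywhere (numpy, sklearn) and stable across runs
    and platforms.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def check_proportion(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def check_positive(value: int, name: str) -> None:
    if value <= 0:
        raise ValueError(f"{name} must be positive, got {value!r}")


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
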