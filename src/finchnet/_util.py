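"""Small shared helpers: seed fan-out and frame validation."""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

SEC_PER_DAY = 86400


def child_seed(seed: int, name: str) -> int:
    """Derive a stable per-stage seed from a global seed and a stage name.

    Uses SHA-256 so the mapping is reproducible across processes and Python
    versions (built-in hash() is salted). Result is < 2**31.
    """
    digest = hashlib.sha256(f"{seed}/{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


def require_columns(df: pd.DataFrame, cols, where: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{where}: missing columns {missing}")


def as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
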