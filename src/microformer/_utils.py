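"""Shared helpers: seeded substreams and small numeric utilities."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["rng_for", "cosine_similarity"]


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Return a Generator for a named substream of a global seed.

    Substreams are derived by hashing the stream name, so adding a new
    consumer never shifts the draws of existing ones.
    """
    tag = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two vectors; 0 if either has zero norm."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))
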