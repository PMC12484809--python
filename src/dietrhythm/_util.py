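"""Shared helpers: seeded substreams and table coercion."""

from __future__ import annotations

import hashlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator derived from ``seed`` and a stable stream name.

    Streams with distinct names are statistically independent, and adding a
    new named stream never perturbs draws taken from existing ones.
    """
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def substream_seed(seed: int, name: str) -> int:
    """Derive a child integer seed for APIs that take a plain seed."""
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return (int(seed) ^ int.from_bytes(digest[8:16], "little")) % (2**63)
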