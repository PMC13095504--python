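"""Named child-seed scheme.

All randomness in the package flows from one integer seed. Each stage
derives an independent stream from ``(seed, name...)`` so stages can be
regenerated in isolation without perturbing each other.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(seed: int, *names: str) -> np.random.SeedSequence:
    """Derive a named :class:`numpy.random.SeedSequence` child of ``seed``.

    The name is hashed with CRC-32, which is stable across platforms and
    Python processes (unlike the builtin ``hash``).
    """
    entropy = [int(seed) & 0xFFFFFFFF] + [zlib.crc32(n.encode()) for n in names]
    return np.random.SeedSequence(entropy)


def child_rng(seed: int, *names: str) -> np.random.Generator:
    """A Generator seeded by the named child stream of ``seed``."""
    return np.random.default_rng(child_seed(seed, *names))
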