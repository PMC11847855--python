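"""Reproducible random-number plumbing.

Every stochastic operation in the package draws from a named substream derived
from a single master seed, so a (config, seed) pair fully determines a run.
Substreams are independent `numpy` generators keyed by string labels.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["spawn_rng", "as_rng"]


def _label_key(label: object) -> int:
    return zlib.crc32(str(label).encode("utf-8"))


def spawn_rng(master_seed: int, *labels: object) -> np.random.Generator:
    """Return a generator for the substream named by ``labels``.

    The same (master_seed, labels) pair always yields the same stream, and
    streams with different labels are statistically independent.
    """
    key = tuple(_label_key(l) for l in labels)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(master_seed), spawn_key=key))


def as_rng(seed_or_rng) -> np.random.Generator:
    """Coerce an int seed, ``None`` or a Generator into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
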