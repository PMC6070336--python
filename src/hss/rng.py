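"""Seeded random-stream plumbing.

Every generator in the package draws from a ``numpy.random.Generator``.
Independent substreams are derived from a single root seed and a fixed string
label, so that adding or reordering one generator call never perturbs the
stream of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "as_generator"]


def _label_key(label: str) -> int:
    # stable across runs and platforms (unlike hash())
    return zlib.crc32(label.encode("utf8"))


def substream(seed: int, *labels: str | int) -> np.random.Generator:
    """Return an independent ``Generator`` for ``(seed, labels...)``."""
    keys = [_label_key(l) if isinstance(l, str) else int(l) for l in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed), *keys]))


def as_generator(rng: np.random.Generator | int | None) -> np.random.Generator:
    """Accept a Generator, an integer seed, or None (fresh entropy)."""
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)
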