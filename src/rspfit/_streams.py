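"""Named, independent random streams derived from one master seed.

Every stochastic operation in the package takes a seed (or an already-built
Generator) and derives its randomness through here, so that e.g. the
landscape, the survey design and the detections can each be regenerated
independently without replaying the others.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "as_rng"]


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named stream under ``seed``.

    The stream key is a CRC32 of the name, so streams are stable across
    sessions and platforms and distinct names give independent streams.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def as_rng(seed_or_rng: int | np.random.Generator, name: str = "default") -> np.random.Generator:
    """Coerce an int seed or an existing Generator into a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return stream(int(seed_or_rng), name)
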