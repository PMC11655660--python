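"""Deterministic seed derivation.

Every stochastic stage derives its generator from a master seed plus a
tuple of string/integer tags identifying the stage (e.g. ``("subject", 3)``
or ``("decode", "WM", "alphanumeric", "rep", 7)``).  The scheme hashes each
tag with CRC-32 and feeds ``[master, crc(tag1), crc(tag2), ...]`` to
``numpy.random.SeedSequence``, so derived streams are independent of the
order in which stages run and reproducible across processes.
"""

from __future__ import annotations

import zlib

import numpy as np


def _crc(tag) -> int:
    return zlib.crc32(str(tag).encode("utf8"))


def seed_sequence(master: int, *tags) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master) % (2**31)] + [_crc(t) for t in tags])


def derive_rng(master: int, *tags) -> np.random.Generator:
    """A :class:`numpy.random.Generator` keyed by ``master`` and ``tags``."""
    return np.random.default_rng(seed_sequence(master, *tags))


def derive_int(master: int, *tags) -> int:
    """A 31-bit integer seed keyed by ``master`` and ``tags`` (suitable for
    scikit-learn ``random_state``)."""
    return int(seed_sequence(master, *tags).generate_state(1)[0] % (2**31))
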