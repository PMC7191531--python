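"""Seed-derivation helpers shared by all pipeline stages.

Every stage draws from its own pseudorandom stream derived from the master
seed by a fixed textual label, so that regenerating one stage never perturbs
another and the whole pipeline is reproducible from a single integer.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1  # sklearn random_state must fit in a signed 32-bit int


def child_seed(master: int, *labels: object) -> int:
    """Derive a deterministic child seed below 2**31 from a master seed.

    Labels are arbitrary hashable stage identifiers (strings, ints); the
    derivation is a CRC over their textual form, stable across platforms
    and Python versions (unlike built-in ``hash``).
    """
    key = "|".join(str(x) for x in (master, *labels))
    return zlib.crc32(key.encode("utf-8")) % _MOD


def rng_for(master: int, *labels: object) -> np.random.Generator:
    """A numpy Generator seeded from :func:`child_seed`."""
    return np.random.default_rng(child_seed(master, *labels))
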