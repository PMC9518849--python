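"""Deterministic seed derivation.

A single master seed drives a whole study run.  Every stage derives its own
child seed by hashing the master seed together with a stage/scenario tag, so
adding a new scenario to a run never perturbs the random streams of existing
ones.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "rng_for"]


def child_seed(master_seed: int, *tags: object) -> int:
    """Derive a deterministic child seed (< 2**31) from a master seed and tags.

    Tags are arbitrary hashable/stringifiable labels, e.g.
    ``child_seed(7, "tracts", "nama3", 0)``.
    """
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for tag in tags:
        h.update(b"\x1f")
        h.update(str(tag).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def rng_for(master_seed: int, *tags: object) -> np.random.Generator:
    """A ``numpy`` generator seeded with :func:`child_seed`."""
    return np.random.default_rng(child_seed(master_seed, *tags))
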