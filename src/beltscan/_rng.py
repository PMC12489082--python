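"""Seed management: one root seed, named substreams per pipeline stage.

All stochastic elements draw from a :class:`numpy.random.Generator` derived
from the root seed and a stage name, so a run is reproducible from the root
seed alone and stages can be re-run independently.
"""

from __future__ import annotations

import hashlib

import numpy as np


def substream(root_seed: int, *names: str | int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The stream key is derived by hashing the root seed together with the
    names, so distinct stage names yield statistically independent streams
    and the mapping is stable across platforms and sessions.
    """
    h = hashlib.sha256()
    h.update(str(int(root_seed)).encode())
    for name in names:
        h.update(b"/")
        h.update(str(name).encode())
    # 128 bits of entropy for the SeedSequence
    digest = int.from_bytes(h.digest()[:16], "little")
    return np.random.default_rng(np.random.SeedSequence(digest))


def subseed(root_seed: int, *names: str | int) -> int:
    """A plain integer seed (< 2**31) for libraries that take one."""
    h = hashlib.sha256()
    h.update(str(int(root_seed)).encode())
    for name in names:
        h.update(b"/")
        h.update(str(name).encode())
    return int.from_bytes(h.digest()[:4], "little") % (2**31)
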