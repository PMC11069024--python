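"""Deterministic child-stream derivation from one root seed.

Every stochastic operator takes an integer seed; replicate/level streams are
derived with :func:`child_seed` so that a run is fully reproducible from its
root seed and the derivation keys are loggable.
"""

from __future__ import annotations

import logging
import zlib

import numpy as np

log = logging.getLogger(__name__)


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode())


def child_seed(root: int, *keys) -> np.random.SeedSequence:
    """Seed sequence for the child stream identified by ``keys``."""
    entropy = [int(root) & 0xFFFFFFFFFFFFFFFF] + [_key_to_int(k) for k in keys]
    log.debug("derived child stream root=%s keys=%s", root, keys)
    return np.random.SeedSequence(entropy)


def rng_from(root: int, *keys) -> np.random.Generator:
    return np.random.default_rng(child_seed(root, *keys))
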