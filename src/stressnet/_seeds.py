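"""Deterministic seed derivation.

A single master seed spawns independent sub-streams via a counter-based
derivation (numpy SeedSequence spawn keys), so ensemble runs, the two
synthetic studies, and pipeline stages each get their own uncorrelated
stream while the whole artifact remains a pure function of the master seed.
String key parts (stage names) are hashed with CRC32 before entering the
spawn key.
"""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def _key(parts: tuple) -> tuple[int, ...]:
    out = []
    for p in parts:
        if isinstance(p, str):
            out.append(zlib.crc32(p.encode("utf-8")))
        else:
            out.append(int(p))
    return tuple(out)


def derive_seed(master: int, *parts) -> int:
    """Derive a child integer seed (< 2**31) from a master seed and key parts."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=_key(parts))
    return int(ss.generate_state(1)[0]) & MAX_SEED


def derive_rng(master: int, *parts) -> np.random.Generator:
    """Derive an independent numpy Generator from a master seed and key parts."""
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=_key(parts))
    return np.random.default_rng(ss)
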