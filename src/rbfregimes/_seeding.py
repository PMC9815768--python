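"""Named RNG substream derivation.

Every source of randomness in the package flows through an explicit seed.
Substreams are derived from a master seed plus a tuple of string tags, so
that e.g. changing the selection regime never perturbs the dataset draw.
"""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def _tags(names: tuple) -> list[int]:
    return [zlib.crc32(str(n).encode("utf8")) for n in names]


def substream(seed: int, *names) -> np.random.Generator:
    """Return an independent ``Generator`` for the named substream."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & MAX_SEED, *_tags(names)]))


def child_seed(seed: int, *names) -> int:
    """Derive a stable integer seed (< 2**31) for the named substream."""
    ss = np.random.SeedSequence([int(seed) & MAX_SEED, *_tags(names)])
    return int(ss.generate_state(1, np.uint32)[0] & MAX_SEED)
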