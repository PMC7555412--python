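"""Namespaced random-number streams.

Every randomized stage draws from its own `numpy` Generator derived from the
single config seed plus a stage name (and optional extra keys such as a
genotype).  Streams for different stages are statistically independent, so
permuting the inputs of one stage never perturbs another — the property the
stratified bootstrap relies on.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng"]


def _key(token: str | int) -> int:
    if isinstance(token, int):
        return token & 0xFFFFFFFF
    return zlib.crc32(token.encode("utf-8"))


def stage_rng(seed: int, stage: str, *extra: str | int) -> np.random.Generator:
    """Return a Generator namespaced by ``(seed, stage, *extra)``."""
    entropy = [int(seed) & 0x7FFFFFFF, _key(stage), *(_key(t) for t in extra)]
    return np.random.default_rng(np.random.SeedSequence(entropy))
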