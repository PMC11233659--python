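"""Deterministic random-stream derivation.

Every stochastic quantity in the package draws from a `numpy` Generator whose
SeedSequence entropy is the tuple (study seed, stream tag, *keys). Streams are
therefore stable under changes elsewhere in the study: adding subjects or
blocks never perturbs the draws of existing ones.
"""
from __future__ import annotations

import numpy as np

TAG_DESIGN = 1
TAG_SUBJECT = 2
TAG_TRIAL = 3
TAG_RECRUIT = 4
TAG_POWER = 5


def stream(seed: int, tag: int, *keys: int) -> np.random.Generator:
    """Generator for the stream identified by (seed, tag, keys)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(tag), *map(int, keys)]))
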