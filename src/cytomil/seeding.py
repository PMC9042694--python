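"""Named random substreams derived from a single root seed.

All stochastic stages (synthesis, splitting, jitter, negative sampling,
weight init, shuffling, bootstrap) draw from independent substreams so that
changing e.g. the number of bootstrap replicates never perturbs training.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for the substream ``name`` under root ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def child_seed(seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) for the named substream."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    return int(ss.generate_state(1)[0] % (2**31))
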