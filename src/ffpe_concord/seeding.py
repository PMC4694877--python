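"""Named random substreams.

Every stochastic operation draws from a generator keyed by the global
seed plus a tuple of string labels (module name, sample kind, ...), so
adding a new stage never perturbs the draws of an existing one and
identical configuration yields bit-identical output.
"""
from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *labels: object) -> np.random.Generator:
    """Return a Generator deterministic in (seed, labels)."""
    key = tuple(zlib.crc32(str(lab).encode("utf-8")) for lab in labels)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=key)
    return np.random.default_rng(ss)
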