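"""Nucleotide coding helpers shared across modules.

Bases are coded as uint8: A=0, C=1, G=2, T=3, N=4.  All genomic
coordinates inside the package are 1-based inclusive (VCF convention);
conversion to/from 0-based half-open happens only at the BED boundary.
"""
from __future__ import annotations

import numpy as np

BASES = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

# complement in code space: A<->T, C<->G, N->N
COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back to a nucleotide string."""
    return _DECODE[codes].tobytes().decode("ascii")


def complement_base(base: str) -> str:
    return decode(COMPLEMENT[encode(base)])


def gc_fraction(codes: np.ndarray) -> float:
    if codes.size == 0:
        return float("nan")
    return float(np.mean((codes == C) | (codes == G)))
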