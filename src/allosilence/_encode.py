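"""Byte-level nucleotide encoding shared by the numba kernels.

Bases are mapped to small integer codes: A=0, C=1, G=2, T=3, N=4.  Any
other character also maps to 4 (treated as N, i.e. never a match).
"""

from __future__ import annotations

import numpy as np

#: codes in alphabet order; index into this with a code to get the base byte
BASE_BYTES = np.frombuffer(b"ACGTN", dtype=np.uint8)

_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE_TABLE[_b] = _i
    _ENCODE_TABLE[_b + 32] = _i  # lowercase

#: complement of each code (N stays N)
COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_TABLE[raw]


def decode(codes: np.ndarray) -> str:
    """Decode uint8 codes back into an uppercase string."""
    return BASE_BYTES[codes].tobytes().decode("ascii")


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse-complement an encoded sequence."""
    return COMPLEMENT[codes][::-1]


def pack_sequences(seqs) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate encoded sequences into (codes, offsets).

    offsets has length n+1; sequence i lives at codes[offsets[i]:offsets[i+1]].
    """
    lengths = np.fromiter((len(s) for s in seqs), dtype=np.int64)
    offsets = np.zeros(len(lengths) + 1, dtype=np.int64)
    np.cumsum(lengths, out=offsets[1:])
    codes = np.empty(int(offsets[-1]), dtype=np.uint8)
    for i, s in enumerate(seqs):
        codes[offsets[i] : offsets[i + 1]] = encode(s) if isinstance(s, str) else s
    return codes, offsets
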