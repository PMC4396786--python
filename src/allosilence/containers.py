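"""In-memory containers for reference contigs and read libraries.

Read libraries are stored packed: one uint8 array of base codes, one of
Phred scores, and an offsets array, so that a library of hundreds of
thousands of variable-length 454-style reads costs two bytes per base
and can be handed directly to the numba kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from ._encode import decode, encode, pack_sequences
from .errors import MalformedRecordError


@dataclass(frozen=True)
class ReferenceContig:
    """A parental cDNA contig against which reads are counted."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadLibrary:
    """One tissue x species set of quality-scored single-end reads.

    Attributes
    ----------
    library_id:
        Unique label, e.g. ``"rye_anther"``.
    species:
        ``"parent"`` or ``"polyploid"``.
    seq:
        Packed base codes (A=0..T=3, N=4) for all reads.
    qual:
        Packed Phred scores, same shape as ``seq``.
    offsets:
        int64 array of length ``n_reads + 1``.
    ids:
        Optional per-read identifiers; synthesized as ``lib:000001`` when absent.
    true_source:
        Optional truth plumbing from the simulator: index of the gene (or
        comparator) each read was drawn from, -1 when unknown.
    """

    library_id: str
    species: str
    seq: np.ndarray
    qual: np.ndarray
    offsets: np.ndarray
    ids: list[str] | None = None
    true_source: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.seq.shape != self.qual.shape:
            raise MalformedRecordError(
                f"library {self.library_id}: packed seq/qual length mismatch"
            )

    @property
    def n_reads(self) -> int:
        return len(self.offsets) - 1

    def __len__(self) -> int:
        return self.n_reads

    def read_id(self, i: int) -> str:
        if self.ids is not None:
            return self.ids[i]
        return f"{self.library_id}:{i:07d}"

    def get(self, i: int) -> tuple[str, str, np.ndarray]:
        """Return (id, sequence string, quality array) for read ``i``."""
        lo, hi = int(self.offsets[i]), int(self.offsets[i + 1])
        return self.read_id(i), decode(self.seq[lo:hi]), self.qual[lo:hi].copy()

    def __iter__(self) -> Iterator[tuple[str, str, np.ndarray]]:
        for i in range(self.n_reads):
            yield self.get(i)

    @classmethod
    def from_records(
        cls,
        library_id: str,
        species: str,
        records: Sequence[tuple[str, str, Sequence[int]]],
    ) -> "ReadLibrary":
        """Build a packed library from (id, sequence, qualities) triples."""
        ids = []
        quals = []
        seqs = []
        for rid, s, q in records:
            if len(s) != len(q):
                raise MalformedRecordError(
                    f"read {rid}: sequence length {len(s)} != quality length {len(q)}"
                )
            ids.append(rid)
            seqs.append(s)
            quals.append(np.asarray(q, dtype=np.uint8))
        seq, offsets = pack_sequences(seqs)
        qual = np.concatenate(quals) if quals else np.empty(0, dtype=np.uint8)
        return cls(library_id, species, seq, qual.astype(np.uint8), offsets, ids=ids)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.seq, self.qual, self.offsets


def encode_contigs(contigs: Sequence[ReferenceContig]) -> tuple[np.ndarray, np.ndarray]:
    """Pack contig sequences for the kernels (order preserved)."""
    return pack_sequences([c.sequence for c in contigs])


__all__ = ["ReferenceContig", "ReadLibrary", "encode_contigs", "encode", "decode"]
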