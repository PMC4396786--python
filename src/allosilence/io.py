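"""FASTA / FASTQ input and output.

FASTQ uses the Sanger dialect (Phred+33) throughout; four lines per
record, no wrapping.  Parsing goes through Biopython so malformed files
fail with a clear message, writing uses a direct formatter because the
simulator can emit libraries of 10^5-10^6 reads.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .containers import ReadLibrary, ReferenceContig
from .errors import FormatError


def read_fasta(path: str | Path) -> list[ReferenceContig]:
    path = Path(path)
    try:
        return [
            ReferenceContig(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")
        ]
    except ValueError as exc:  # pragma: no cover - biopython error text varies
        raise FormatError(f"{path}: {exc}") from exc


def write_fasta(contigs: Iterable[ReferenceContig], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path, library_id: str, species: str) -> ReadLibrary:
    """Load a Sanger FASTQ file into a packed :class:`ReadLibrary`."""
    path = Path(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            records.append((rec.id, str(rec.seq).upper(), quals))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return ReadLibrary.from_records(library_id, species, records)


def write_fastq(lib: ReadLibrary, path: str | Path) -> None:
    from ._encode import BASE_BYTES

    offsets = lib.offsets
    seq = BASE_BYTES[lib.seq]
    qual = (lib.qual + 33).astype(np.uint8)
    with open(path, "wb") as fh:
        for i in range(lib.n_reads):
            lo, hi = int(offsets[i]), int(offsets[i + 1])
            fh.write(b"@" + lib.read_id(i).encode() + b"\n")
            fh.write(seq[lo:hi].tobytes() + b"\n+\n")
            fh.write(qual[lo:hi].tobytes() + b"\n")


def write_tsv(df, path: str | Path) -> None:
    """Write a DataFrame as TSV with a stable float format (reproducible bytes)."""
    df.to_csv(path, sep="\t", float_format="%.6g")


__all__ = ["read_fasta", "write_fasta", "read_fastq", "write_fastq", "write_tsv"]
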