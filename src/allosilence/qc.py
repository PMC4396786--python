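"""Two-rule Phred quality control applied before mapping.

Rule 1 (trimming): the maximal run of bases with Phred score below the
end-trim threshold (default 15) is removed from each end of the read.
Rule 2 (masking): every remaining base with Phred score below the mask
threshold (default 20) is replaced by N, its quality kept.  Reads
shorter than a minimum surviving length after trimming are rejected and
counted.  Both ends are trimmed by default; flags allow 3'-only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from ._encode import decode, encode
from .containers import ReadLibrary
from .errors import MalformedRecordError


@dataclass(frozen=True)
class QCParams:
    end_trim_threshold: int = 15
    mask_threshold: int = 20
    min_surviving_length: int = 50
    trim_five_prime: bool = True
    trim_three_prime: bool = True

    def __post_init__(self) -> None:
        if self.end_trim_threshold > self.mask_threshold:
            warnings.warn(
                "end_trim_threshold exceeds mask_threshold; trimmed ends would "
                "otherwise have been masked",
                stacklevel=2,
            )


@dataclass
class QCReport:
    library_id: str
    n_input: int
    n_rejected: int
    n_masked_bases: int
    n_trimmed_bases: int

    @property
    def n_passed(self) -> int:
        return self.n_input - self.n_rejected

    def to_row(self) -> dict:
        return {
            "library": self.library_id,
            "input_reads": self.n_input,
            "passed_reads": self.n_passed,
            "rejected_reads": self.n_rejected,
            "masked_bases": self.n_masked_bases,
            "trimmed_bases": self.n_trimmed_bases,
        }


def qc_read(
    sequence: str,
    qualities,
    params: QCParams = QCParams(),
    read_id: str = "read",
) -> tuple[str, np.ndarray] | None:
    """Clean a single read; returns (sequence, qualities) or None if rejected."""
    quals = np.asarray(qualities, dtype=np.int64)
    if len(sequence) != quals.size:
        raise MalformedRecordError(
            f"read {read_id}: sequence length {len(sequence)} != quality length {quals.size}"
        )
    codes = encode(sequence)
    a, b = 0, quals.size - 1
    if params.trim_five_prime:
        while a <= b and quals[a] < params.end_trim_threshold:
            a += 1
    if params.trim_three_prime:
        while b >= a and quals[b] < params.end_trim_threshold:
            b -= 1
    if b - a + 1 < max(params.min_surviving_length, 1):
        return None
    kept = codes[a : b + 1].copy()
    q = quals[a : b + 1].copy()
    kept[q < params.mask_threshold] = 4  # N, quality preserved
    return decode(kept), q.astype(np.uint8)


def qc_library(lib: ReadLibrary, params: QCParams = QCParams()) -> tuple[ReadLibrary, QCReport]:
    """Clean a whole library (order preserving), dropping rejected reads."""
    seq, qual, off, keep, n_masked, n_trimmed = _kernels.qc_batch(
        lib.seq,
        lib.qual,
        lib.offsets,
        params.end_trim_threshold,
        params.mask_threshold,
        max(params.min_surviving_length, 1),
        params.trim_five_prime,
        params.trim_three_prime,
    )
    keep_mask = keep.astype(bool)
    ids = None
    if lib.ids is not None:
        ids = [rid for rid, k in zip(lib.ids, keep_mask) if k]
    src = lib.true_source[keep_mask] if lib.true_source is not None else None
    cleaned = ReadLibrary(
        lib.library_id, lib.species, seq, qual, off, ids=ids, true_source=src
    )
    report = QCReport(
        lib.library_id,
        n_input=lib.n_reads,
        n_rejected=int(lib.n_reads - keep_mask.sum()),
        n_masked_bases=int(n_masked),
        n_trimmed_bases=int(n_trimmed),
    )
    return cleaned, report
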