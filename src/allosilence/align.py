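"""Desk-scale local aligner: exact affine-gap Smith-Waterman semantics.

Two scoring presets mirror the two uses in the pipeline:

* read-to-reference mapping uses a heavy mismatch penalty (-10) so that
  reads from a diverged partner subgenome (~70-97% identity) score below
  the acceptance floor and are left unassigned -- this is what makes
  "uniquely mapped" subgenome-specific;
* gene-to-comparator homology search uses a mild penalty (-2) so that
  70-100% identical homologs align over their full length and can be
  binned by percent identity.

``align_local`` computes exact best-scoring local alignments (repeated
Smith-Waterman with masking to emit secondary blocks); the bulk mapper
``ReferenceIndex.map_library`` seeds candidate contigs/diagonals with
exact k-mer matches and scores them with a banded version of the same
DP.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import _kernels
from ._encode import encode, revcomp
from .containers import ReferenceContig, ReadLibrary, encode_contigs
from .errors import ConfigurationError


@dataclass(frozen=True)
class ScoringScheme:
    """Integer scoring parameters for local alignment.

    A gap of length L costs ``gap_open + L * gap_extend``.  ``word_size``
    is the exact-match seed length used to shortlist candidates.
    """

    match: int = 1
    mismatch: int = -10
    gap_open: int = -5
    gap_extend: int = -2
    word_size: int = 16

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ConfigurationError("match reward must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ConfigurationError("penalties must be <= 0")
        if not 4 <= self.word_size <= 31:
            raise ConfigurationError("word_size must be in [4, 31]")


#: read mapping: mismatch penalty of 10 as in the original BWA-SW setup
MAPPING_SCHEME = ScoringScheme(match=1, mismatch=-10, gap_open=-5, gap_extend=-2, word_size=16)
#: homology search: BLASTN-like +1/-2
HOMOLOGY_SCHEME = ScoringScheme(match=1, mismatch=-2, gap_open=-5, gap_extend=-2, word_size=12)


@dataclass(frozen=True)
class AlignmentBlock:
    """One local alignment segment (HSP) on plus-strand subject coordinates.

    Intervals are 0-based half-open internally; the TSV reports convert
    to 1-based inclusive.  ``length`` counts alignment columns including
    gap columns; ``matches`` counts identical non-N columns.
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    length: int
    matches: int
    gaps: int
    score: int
    strand: str = "+"

    @property
    def mismatches(self) -> int:
        return self.length - self.matches - self.gaps

    @property
    def percent_identity(self) -> float:
        return 100.0 * self.matches / self.length if self.length else 0.0


@dataclass(frozen=True)
class MappingResult:
    """Outcome of mapping one read against a reference set."""

    read_id: str
    subject_id: str | None
    best_score: int
    second_score: int
    unique: bool


def _as_codes(seq) -> np.ndarray:
    if isinstance(seq, str):
        return encode(seq)
    return np.asarray(seq, dtype=np.uint8)


def _waterman_eggert(
    q: np.ndarray,
    s: np.ndarray,
    scheme: ScoringScheme,
    max_blocks: int,
    min_block_score: int,
    strand: str,
) -> list[AlignmentBlock]:
    """Extract successive non-overlapping local alignments by masking."""
    qw = q.copy()
    sw = s.copy()
    blocks: list[AlignmentBlock] = []
    for _ in range(max_blocks):
        score, qs, qe, ss, se, matches, cols, gaps = _kernels.sw_align(
            qw, sw, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
        )
        if score < min_block_score or score <= 0:
            break
        if strand == "-":
            # report on plus-strand subject coordinates and flip query back
            n = q.size
            q0, q1 = n - qe, n - qs
        else:
            q0, q1 = qs, qe
        blocks.append(
            AlignmentBlock(q0, q1, ss, se, cols, matches, gaps, int(score), strand)
        )
        qw[qs:qe] = 5  # blocked code: may not align again
        sw[ss:se] = 5
    return blocks


def align_local(
    query,
    subject,
    scheme: ScoringScheme = HOMOLOGY_SCHEME,
    max_blocks: int = 8,
    min_block_score: int = 20,
    both_strands: bool = True,
) -> list[AlignmentBlock]:
    """All non-overlapping local alignment blocks, best score first.

    When ``both_strands`` is set the reverse complement of the query is
    also aligned and the better orientation is reported (block
    coordinates stay on the plus strand of both sequences).
    """
    q = _as_codes(query)
    s = _as_codes(subject)
    if q.size == 0 or s.size == 0:
        return []
    fwd = _waterman_eggert(q, s, scheme, max_blocks, min_block_score, "+")
    if not both_strands:
        return fwd
    rev = _waterman_eggert(revcomp(q), s, scheme, max_blocks, min_block_score, "-")
    f = fwd[0].score if fwd else 0
    r = rev[0].score if rev else 0
    return fwd if f >= r else rev


class ReferenceIndex:
    """Exact k-mer index over a reference contig set, for bulk mapping.

    Contigs are indexed in lexicographic id order so that score ties
    resolve to the lexicographically smallest subject deterministically.
    """

    def __init__(self, references: Sequence[ReferenceContig], scheme: ScoringScheme = MAPPING_SCHEME):
        if len({c.id for c in references}) != len(references):
            raise ConfigurationError("reference contig ids must be unique")
        self.references = sorted(references, key=lambda c: c.id)
        self.scheme = scheme
        self.ids = [c.id for c in self.references]
        self.codes, self.offsets = encode_contigs(self.references)
        kmers, gpos = _kernels.collect_kmers(self.codes, self.offsets, scheme.word_size)
        order = np.argsort(kmers, kind="stable")
        self._kmer_sorted = kmers[order]
        self._pos_sorted = gpos[order]

    def __len__(self) -> int:
        return len(self.references)

    def map_library(
        self,
        lib: ReadLibrary,
        stride: int = 8,
        floor_frac: float = 0.6,
        margin: int = 1,
        max_occ: int = 64,
        band_pad: int = 8,
    ) -> "LibraryMapping":
        """Map every read; returns per-read assignments (contig index or -1)."""
        sch = self.scheme
        contig, best, second, unique = _kernels.map_batch(
            lib.seq,
            lib.offsets,
            self.codes,
            self.offsets,
            self._kmer_sorted,
            self._pos_sorted,
            sch.word_size,
            stride,
            sch.match,
            sch.mismatch,
            sch.gap_open,
            sch.gap_extend,
            floor_frac,
            margin,
            max_occ,
            band_pad,
        )
        assigned = np.where(unique.astype(bool), contig, -1)
        return LibraryMapping(self, lib.library_id, assigned, contig, best, second)


@dataclass
class LibraryMapping:
    """Per-read mapping outcome for one library.

    ``assigned`` holds the contig index for uniquely mapped reads and -1
    for unassigned (unmappable, sub-floor or ambiguous) reads.
    """

    index: ReferenceIndex
    library_id: str
    assigned: np.ndarray
    best_contig: np.ndarray
    best_score: np.ndarray
    second_score: np.ndarray

    @property
    def n_unique(self) -> int:
        return int((self.assigned >= 0).sum())

    @property
    def n_unassigned(self) -> int:
        return int((self.assigned < 0).sum())


def map_read(
    read,
    references: Sequence[ReferenceContig] | ReferenceIndex,
    scheme: ScoringScheme = MAPPING_SCHEME,
    floor_frac: float = 0.6,
    margin: int = 1,
    read_id: str = "read",
) -> MappingResult:
    """Map a single read with exact best-score semantics.

    The read is aligned (both strands, full DP) against every reference;
    ``unique`` requires the best score to reach the floor
    ``floor_frac * len(read) * match`` and to exceed the runner-up from
    any other contig by at least ``margin``.
    """
    if isinstance(references, ReferenceIndex):
        refs = references.references
        scheme = references.scheme
    else:
        refs = sorted(references, key=lambda c: c.id)
    q = _as_codes(read)
    best = second = 0
    best_id: str | None = None
    for contig in refs:
        blocks = align_local(q, contig.sequence, scheme, max_blocks=1, min_block_score=1)
        score = blocks[0].score if blocks else 0
        if score > best:
            second = best
            best = score
            best_id = contig.id
        elif score > second:
            second = score
    floor = floor_frac * q.size * scheme.match
    unique = best_id is not None and best >= floor and best - second >= margin
    return MappingResult(read_id, best_id if best > 0 else None, best, second, unique)


def scheme_with(scheme: ScoringScheme, **kw) -> ScoringScheme:
    return replace(scheme, **kw)
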