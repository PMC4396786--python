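"""Per-contig, per-library unique read counts and RPKM normalization.

RPKM = C / (D / 10^6) / (L / 10^3) for C unique reads on a contig of
length L nt in a library of depth D.  Depth is the number of QC-passed
reads in the library (not raw and not uniquely-mapped reads); a flag on
:func:`count_unique` switches to uniquely-mapped depth if wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import LibraryMapping
from .containers import ReferenceContig
from .errors import DomainError, IntegrityError


def rpkm(C, D, L):
    """Reads per kilobase per million reads; exact formula, vectorized."""
    C = np.asarray(C, dtype=float)
    D = np.asarray(D, dtype=float)
    L = np.asarray(L, dtype=float)
    if np.any(D <= 0):
        raise DomainError("library depth D must be > 0")
    if np.any(L <= 0):
        raise DomainError("contig length L must be > 0")
    out = C / (D / 1e6) / (L / 1e3)
    return float(out) if out.ndim == 0 else out


@dataclass
class ExpressionMatrix:
    """Counts and metadata for contigs x libraries.

    ``counts``: DataFrame indexed by contig id, one column per library.
    ``depths``: QC-passed reads per library.  ``lengths``: contig length
    in nt.  ``species``: 'parent' or 'polyploid' per library.
    ``unassigned``: reads not uniquely mapped, per library.
    """

    counts: pd.DataFrame
    depths: pd.Series
    lengths: pd.Series
    species: pd.Series
    unassigned: pd.Series

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def columns_for(self, species: str) -> list[str]:
        return [c for c in self.counts.columns if self.species[c] == species]

    @property
    def parent_columns(self) -> list[str]:
        return self.columns_for("parent")

    @property
    def polyploid_columns(self) -> list[str]:
        return self.columns_for("polyploid")

    def rpkm(self) -> pd.DataFrame:
        return self.counts.div(self.depths / 1e6, axis=1).div(self.lengths / 1e3, axis=0)


def count_unique(
    mappings: Sequence[LibraryMapping],
    references: Sequence[ReferenceContig],
    depths: Mapping[str, int],
    species: Mapping[str, str],
) -> ExpressionMatrix:
    """Tally uniquely mapped reads into a contig x library matrix.

    ``depths`` must give the QC-passed read total of each library (the
    RPKM denominator); unassigned reads are counted but excluded from
    the matrix, so every column sum plus its unassigned count equals the
    number of mapped-attempted reads.
    """
    ref_ids = [c.id for c in sorted(references, key=lambda c: c.id)]
    lengths = pd.Series(
        {c.id: len(c.sequence) for c in references}, name="length"
    ).loc[ref_ids]
    data = {}
    unassigned = {}
    for m in mappings:
        if list(m.index.ids) != ref_ids:
            raise IntegrityError(
                f"mapping for library {m.library_id} references a different contig set"
            )
        if m.library_id not in depths:
            raise IntegrityError(f"no depth recorded for library {m.library_id}")
        assigned = m.assigned
        counts = np.bincount(assigned[assigned >= 0], minlength=len(ref_ids))
        data[m.library_id] = counts
        unassigned[m.library_id] = int((assigned < 0).sum())
    counts_df = pd.DataFrame(data, index=ref_ids)
    lib_ids = list(counts_df.columns)
    return ExpressionMatrix(
        counts=counts_df,
        depths=pd.Series({l: int(depths[l]) for l in lib_ids}, name="depth"),
        lengths=lengths,
        species=pd.Series({l: species[l] for l in lib_ids}, name="species"),
        unassigned=pd.Series(unassigned, name="unassigned"),
    )


def matrix_from_counts(
    counts: pd.DataFrame,
    depths: Mapping[str, int],
    lengths: Mapping[str, int],
    species: Mapping[str, str],
) -> ExpressionMatrix:
    """Assemble an ExpressionMatrix from pre-tabulated counts (e.g. TSV)."""
    lib_ids = list(counts.columns)
    return ExpressionMatrix(
        counts=counts,
        depths=pd.Series({l: int(depths[l]) for l in lib_ids}, name="depth"),
        lengths=pd.Series({c: int(lengths[c]) for c in counts.index}, name="length"),
        species=pd.Series({l: species[l] for l in lib_ids}, name="species"),
        unassigned=pd.Series({l: 0 for l in lib_ids}, name="unassigned"),
    )
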