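"""Calling parent-subgenome genes undetected in the polyploid.

A contig is *all-undetected* when it has at least one uniquely mapped
read in some parent library and zero in every polyploid library; it is
*high-confidence* when additionally some single parent library holds at
least ``min_parent_reads`` (default 10) reads.  Each call carries a
Poisson non-detection probability: under the hypothesis that the gene
is transcribed in the polyploid at a fraction ``f`` (default 1/3) of
its parent rate, the expected polyploid read count is

    lambda = f * (C_parent / D_parent) * D_polyploid

and the probability of still sampling zero reads is P0 = exp(-lambda).
Small P0 means the zero count is unlikely under continued expression,
i.e. strong evidence for silencing or loss.  By default counts and
depths are pooled across libraries on both sides (the polyploid zero
is a zero over *all* polyploid libraries); ``per_library=True`` uses
instead the maximal single parent library rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .expression import ExpressionMatrix


def nondetection_probability(c_parent, d_parent, d_polyploid, f=1.0 / 3.0):
    """P0 = exp(-f * (C/D_parent) * D_polyploid); vectorized, exact to double."""
    c = np.asarray(c_parent, dtype=float)
    dp = np.asarray(d_parent, dtype=float)
    dt = np.asarray(d_polyploid, dtype=float)
    fv = np.asarray(f, dtype=float)
    if np.any(c < 0) or np.any(fv < 0):
        raise DomainError("read counts and expression fraction f must be >= 0")
    if np.any(dp <= 0) or np.any(dt <= 0):
        raise DomainError("library depths must be > 0")
    lam = fv * (c / dp) * dt
    out = np.exp(-lam)
    return float(out) if out.ndim == 0 else out


@dataclass
class AbsenceResult:
    """Output of :func:`call_undetected`.

    ``table`` has one row per all-undetected contig with its parent
    counts, P0 and the high-confidence flag; ``p0_all`` holds P0 for
    every contig in the matrix (used for expected-false-flag bounds).
    """

    table: pd.DataFrame
    p0_all: pd.Series
    min_parent_reads: int
    f: float

    @property
    def undetected_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def high_confidence_ids(self) -> list[str]:
        return list(self.table.index[self.table["high_confidence"]])


def call_undetected(
    matrix: ExpressionMatrix,
    min_parent_reads: int = 10,
    f: float = 1.0 / 3.0,
    per_library: bool = False,
) -> AbsenceResult:
    """Flag contigs expressed in the parent but absent from all polyploid libraries."""
    parent_cols = matrix.parent_columns
    poly_cols = matrix.polyploid_columns
    if not parent_cols:
        raise ConfigurationError("expression matrix has no parent libraries")
    if not poly_cols:
        raise ConfigurationError("expression matrix has no polyploid libraries")

    pc = matrix.counts[parent_cols]
    parent_total = pc.sum(axis=1)
    parent_max = pc.max(axis=1)
    parent_argmax = pc.idxmax(axis=1)
    poly_total = matrix.counts[poly_cols].sum(axis=1)

    d_parent_total = float(matrix.depths[parent_cols].sum())
    d_poly_total = float(matrix.depths[poly_cols].sum())
    if per_library:
        rates = pc.div(matrix.depths[parent_cols], axis=1)
        lam_rate = rates.max(axis=1)
        p0 = np.exp(-f * lam_rate.to_numpy() * d_poly_total)
    else:
        p0 = nondetection_probability(
            parent_total.to_numpy(), d_parent_total, d_poly_total, f
        )
    p0_all = pd.Series(p0, index=matrix.counts.index, name="p0")

    undetected = (poly_total == 0) & (parent_total >= 1)
    table = pd.DataFrame(
        {
            "parent_total": parent_total[undetected].astype(int),
            "max_parent_count": parent_max[undetected].astype(int),
            "max_parent_library": parent_argmax[undetected],
            "polyploid_total": poly_total[undetected].astype(int),
            "p0": p0_all[undetected],
            "high_confidence": parent_max[undetected] >= min_parent_reads,
        }
    )
    table.index.name = "contig"
    rpkm = matrix.rpkm()
    for col in parent_cols:
        table[f"rpkm_{col}"] = rpkm.loc[table.index, col]
    return AbsenceResult(table, p0_all, min_parent_reads, f)
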