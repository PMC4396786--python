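"""Independent reference implementations used only as test oracles.

These are deliberately written from the textbook definitions, not by
calling into the package, so that agreement is evidence of correctness
rather than tautology.
"""

from __future__ import annotations

import numpy as np

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def sw_best_score(query: str, subject: str, match: int, mismatch: int,
                  gap_open: int, gap_extend: int) -> int:
    """Brute-force affine-gap Smith-Waterman best local score.

    A gap of length L costs gap_open + L * gap_extend.  Columns where
    either base is N score 0.
    """
    q = [_CODE.get(c, 4) for c in query.upper()]
    s = [_CODE.get(c, 4) for c in subject.upper()]
    m, n = len(q), len(s)
    NEG = -(10**9)
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(E[i, j - 1] + gap_extend, H[i, j - 1] + gap_open + gap_extend)
            F[i, j] = max(F[i - 1, j] + gap_extend, H[i - 1, j] + gap_open + gap_extend)
            if q[i - 1] == 4 or s[j - 1] == 4:
                sub = 0
            elif q[i - 1] == s[j - 1]:
                sub = match
            else:
                sub = mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + sub, E[i, j], F[i, j])
    return int(H.max())


def pearson_chi2(table: np.ndarray) -> tuple[float, int]:
    """Textbook Pearson chi-squared: sum (O-E)^2/E with E from margins."""
    obs = np.asarray(table, dtype=float)
    total = obs.sum()
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    expected = rows @ cols / total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, df


def column_identity(aligned_query: str, aligned_subject: str) -> tuple[int, int]:
    """(matches, columns) by direct column counting of a gapped alignment.

    '-' marks a gap; N never matches.
    """
    assert len(aligned_query) == len(aligned_subject)
    matches = sum(
        1
        for a, b in zip(aligned_query.upper(), aligned_subject.upper())
        if a == b and a not in "-N"
    )
    return matches, len(aligned_query)


def random_seq(rng: np.random.Generator, n: int, n_frac: float = 0.0) -> str:
    bases = np.array(list("ACGT"))
    seq = bases[rng.integers(0, 4, n)]
    if n_frac > 0:
        seq[rng.random(n) < n_frac] = "N"
    return "".join(seq)
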