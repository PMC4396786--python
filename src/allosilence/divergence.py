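"""Sequence-divergence profile of non-detected genes vs random controls.

For each query gene and comparator collection (partner-subgenome
assemblies, diploid progenitor genomes, EST sets) the best hit is the
subject with the highest total alignment score among those having at
least one alignment block of ``min_block_length`` nt (default 100).
Percent identity of a hit is aggregated over all qualifying blocks:
sum(matches) / sum(aligned block length) * 100 -- the multi-exon "total
length of the alignment blocks" rule.  Gene sets are then binned into
percent-identity classes and compared with Pearson chi-squared
contingency tests (per class 2x2, or one global 2xk), and initial hits
can be classified by a reciprocal search back into the full parent
reference set to tell orthologs from missing homeologs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from ._encode import encode, revcomp
from .align import HOMOLOGY_SCHEME, AlignmentBlock, ScoringScheme, align_local
from .containers import ReferenceContig, encode_contigs
from .errors import ConfigurationError, DomainError

#: identity classes: a catch-all low bin, then the 5-point classes of the histograms
DEFAULT_BIN_EDGES = (0.0, 70.0, 75.0, 80.0, 85.0, 90.0, 95.0, 100.0)


@dataclass(frozen=True)
class HomologyHit:
    """Best match of one query in one comparator collection."""

    query_id: str
    collection_id: str
    subject_id: str
    blocks: tuple[AlignmentBlock, ...]
    aggregated_identity: float
    total_score: int


def aggregate_identity(blocks: Sequence[AlignmentBlock]) -> float:
    """Sum(matches) / sum(aligned length) over blocks, as a percentage."""
    cols = sum(b.length for b in blocks)
    if cols == 0:
        return 0.0
    return 100.0 * sum(b.matches for b in blocks) / cols


class HomologySearcher:
    """Best-hit search of queries against one comparator collection.

    Subjects are shortlisted by exact shared k-mers (both query strands)
    before the full local alignment, so collections of thousands of
    sequences stay tractable; the shortlist threshold is permissive
    (two shared words) and alignment scoring is exact.
    """

    def __init__(
        self,
        collection: Sequence[ReferenceContig],
        collection_id: str = "collection",
        scheme: ScoringScheme = HOMOLOGY_SCHEME,
        min_block_length: int = 100,
        min_shared_kmers: int = 2,
        max_candidates: int = 12,
    ):
        if not collection:
            raise ConfigurationError(f"collection {collection_id} is empty")
        self.collection = sorted(collection, key=lambda c: c.id)
        self.collection_id = collection_id
        self.scheme = scheme
        self.min_block_length = min_block_length
        self.min_shared_kmers = min_shared_kmers
        self.max_candidates = max_candidates
        self.codes, self.offsets = encode_contigs(self.collection)
        kmers, gpos = _kernels.collect_kmers(self.codes, self.offsets, scheme.word_size)
        order = np.argsort(kmers, kind="stable")
        self._kmer_sorted = kmers[order]
        self._pos_sorted = gpos[order]

    def _candidates(self, q: np.ndarray) -> list[int]:
        votes = np.zeros(len(self.collection), dtype=np.int64)
        off1 = np.zeros(2, dtype=np.int64)
        for strand in (q, revcomp(q)):
            off1[1] = strand.size
            kmers, _ = _kernels.collect_kmers(strand, off1, self.scheme.word_size)
            if kmers.size == 0:
                continue
            kmers = np.unique(kmers)
            lo = np.searchsorted(self._kmer_sorted, kmers, side="left")
            hi = np.searchsorted(self._kmer_sorted, kmers, side="right")
            for a, b in zip(lo, hi):
                if b - a > 200:  # highly repetitive word
                    continue
                subj = np.searchsorted(self.offsets, self._pos_sorted[a:b], side="right") - 1
                votes[subj] += 1
        ranked = np.argsort(-votes, kind="stable")
        return [int(i) for i in ranked[: self.max_candidates] if votes[i] >= self.min_shared_kmers]

    def best_hit(self, query: ReferenceContig) -> HomologyHit | None:
        q = encode(query.sequence)
        best: HomologyHit | None = None
        for ci in self._candidates(q):
            subj = self.collection[ci]
            blocks = tuple(
                b
                for b in align_local(q, subj.sequence, self.scheme)
                if b.length >= self.min_block_length
            )
            if not blocks:
                continue
            hit = HomologyHit(
                query.id,
                self.collection_id,
                subj.id,
                blocks,
                aggregate_identity(blocks),
                sum(b.score for b in blocks),
            )
            if best is None or _hit_better(hit, best):
                best = hit
        return best


def _hit_better(a: HomologyHit, b: HomologyHit) -> bool:
    """Most-similar tie-breaking: score, then identity, then subject id."""
    if a.total_score != b.total_score:
        return a.total_score > b.total_score
    if a.aggregated_identity != b.aggregated_identity:
        return a.aggregated_identity > b.aggregated_identity
    return a.subject_id < b.subject_id


def best_hit(
    query: ReferenceContig,
    collection: Sequence[ReferenceContig],
    scheme: ScoringScheme = HOMOLOGY_SCHEME,
    min_block_length: int = 100,
    collection_id: str = "collection",
) -> HomologyHit | None:
    """One-off best hit (builds a throwaway index; use HomologySearcher in loops)."""
    searcher = HomologySearcher(
        collection, collection_id, scheme, min_block_length
    )
    return searcher.best_hit(query)


def search_all(
    queries: Sequence[ReferenceContig], searcher: HomologySearcher
) -> dict[str, HomologyHit | None]:
    return {q.id: searcher.best_hit(q) for q in queries}


@dataclass
class IdentityDistribution:
    """Per-class counts of best-hit identities for one gene set."""

    bin_edges: tuple[float, ...]
    counts: np.ndarray
    unmatched: int

    @property
    def set_size(self) -> int:
        return int(self.counts.sum()) + self.unmatched

    @property
    def labels(self) -> list[str]:
        e = self.bin_edges
        return [f"{a:g}-{b:g}" for a, b in zip(e, e[1:])]

    def to_frame(self, name: str = "count") -> pd.DataFrame:
        df = pd.DataFrame({"class": self.labels + ["unmatched"],
                           name: list(self.counts) + [self.unmatched]})
        return df.set_index("class")


def identity_distribution(
    identities: Mapping[str, float | None] | Sequence[float | None],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> IdentityDistribution:
    """Bin best-hit identities into classes [lo, hi), last class closed.

    ``None`` entries (genes without a qualifying hit) go to ``unmatched``.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ConfigurationError("bin_edges must be strictly increasing (no overlap)")
    values = list(identities.values()) if isinstance(identities, Mapping) else list(identities)
    counts = np.zeros(edges.size - 1, dtype=np.int64)
    unmatched = 0
    for v in values:
        if v is None:
            unmatched += 1
            continue
        if v < edges[0] or v > edges[-1]:
            raise ConfigurationError(
                f"identity {v} outside the range covered by bin_edges"
            )
        b = int(np.searchsorted(edges, v, side="right") - 1)
        b = min(b, counts.size - 1)  # 100% falls in the top class
        counts[b] += 1
    return IdentityDistribution(tuple(edges), counts, unmatched)


def sample_control(
    reference: Sequence[ReferenceContig] | Sequence[str],
    n: int = 200,
    seed: int = 0,
    exclude: set[str] | None = None,
) -> list[str]:
    """Uniform sample of n gene ids without replacement, excluding a set."""
    ids = [c.id if isinstance(c, ReferenceContig) else c for c in reference]
    exclude = exclude or set()
    available = sorted(set(ids) - exclude)
    if n > len(available):
        raise ConfigurationError(
            f"cannot sample {n} control genes from {len(available)} available"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(available), size=n, replace=False)
    return sorted(available[i] for i in picked)


@dataclass
class ContingencyResult:
    """Pearson chi-squared test of one observed contingency table."""

    observed: np.ndarray
    chi2: float
    df: int
    p_value: float
    label: str = ""
    p_bonferroni: float | None = None


def chi2_contingency(table, label: str = "") -> ContingencyResult:
    """Pearson chi-squared with expected counts from the margins, no
    continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise DomainError("contingency table must be 2-D with non-negative cells")
    if obs.sum() <= 0:
        raise DomainError("contingency table total must be > 0")
    for axis, name in ((1, "row"), (0, "column")):
        margins = obs.sum(axis=axis)
        if np.any(margins == 0):
            idx = int(np.argmin(margins))
            raise DomainError(f"{name} {idx} of the contingency table has zero margin")
    res = stats.chi2_contingency(obs, correction=False)
    return ContingencyResult(obs, float(res.statistic), int(res.dof), float(res.pvalue), label)


def compare_distributions(
    non_detected: IdentityDistribution,
    control: IdentityDistribution,
    mode: str = "per-class",
    include_unmatched: bool = False,
) -> list[ContingencyResult]:
    """Chi-squared comparison of two identity-class distributions.

    per-class: one 2x2 table per class (in-class vs not-in-class for
    each gene set), raw p-values plus Bonferroni adjustment across the
    classes tested.  global: a single 2xk table over all non-empty
    classes.  Unmatched genes form their own class only when
    ``include_unmatched`` is set; otherwise denominators are matched
    genes only.
    """
    if non_detected.bin_edges != control.bin_edges:
        raise ConfigurationError("distributions have mismatched bin edges")
    a = non_detected.counts.astype(float)
    b = control.counts.astype(float)
    labels = non_detected.labels
    if include_unmatched:
        a = np.append(a, non_detected.unmatched)
        b = np.append(b, control.unmatched)
        labels = labels + ["unmatched"]
    na, nb = a.sum(), b.sum()
    if mode == "global":
        keep = (a + b) > 0
        res = chi2_contingency(np.vstack([a[keep], b[keep]]), label="global")
        return [res]
    if mode != "per-class":
        raise ConfigurationError(f"unknown comparison mode: {mode}")
    results = []
    for j, lab in enumerate(labels):
        table = np.array([[a[j], na - a[j]], [b[j], nb - b[j]]])
        if a[j] + b[j] == 0 or (na - a[j]) + (nb - b[j]) == 0:
            # nobody (or everybody) in this class: proportions are trivially
            # equal, the 2x2 degenerates and the test carries no information
            results.append(ContingencyResult(table, 0.0, 1, 1.0, lab))
            continue
        results.append(chi2_contingency(table, label=lab))
    k = len(results)
    for r in results:
        r.p_bonferroni = min(1.0, r.p_value * k)
    return results


def hits_frame(hits: Mapping[str, HomologyHit | None]) -> pd.DataFrame:
    """BLAST-outfmt-6-like table of best hits (plus the aggregated-identity
    and block-count columns); coordinates 1-based inclusive, top block."""
    rows = []
    for q, h in hits.items():
        if h is None:
            rows.append({"query": q, "subject": "", "pct_identity": np.nan})
            continue
        top = h.blocks[0]
        rows.append(
            {
                "query": q,
                "subject": h.subject_id,
                "pct_identity": h.aggregated_identity,
                "length": sum(b.length for b in h.blocks),
                "mismatches": sum(b.mismatches for b in h.blocks),
                "gaps": sum(b.gaps for b in h.blocks),
                "q_start": top.q_start + 1,
                "q_end": top.q_end,
                "s_start": top.s_start + 1,
                "s_end": top.s_end,
                "score": h.total_score,
                "n_blocks": len(h.blocks),
            }
        )
    return pd.DataFrame(rows).set_index("query")


def results_frame(results: Sequence[ContingencyResult]) -> pd.DataFrame:
    rows = [
        {
            "class": r.label,
            "chi2": r.chi2,
            "df": r.df,
            "p_value": r.p_value,
            "p_bonferroni": r.p_bonferroni,
        }
        for r in results
    ]
    return pd.DataFrame(rows).set_index("class")


def chi2_null_calibration(
    n1: int,
    n2: int,
    probs: Sequence[float],
    n_reps: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the per-class 2x2 test under the null.

    Both gene sets are drawn from one multinomial over the identity
    classes; returns the fraction of (replicate, class) tests with
    p < alpha.  Fully vectorized.
    """
    p = np.asarray(probs, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ConfigurationError("probs must sum to 1")
    rng = np.random.default_rng(seed)
    x = rng.multinomial(n1, p, size=n_reps).astype(float)
    y = rng.multinomial(n2, p, size=n_reps).astype(float)
    a, b = x, n1 - x
    c, d = y, n2 - y
    n = float(n1 + n2)
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / denom
    chi2 = np.where(denom > 0, chi2, 0.0)
    pvals = stats.chi2.sf(chi2, df=1)
    return float((pvals < alpha).mean())


@dataclass
class ReciprocalSummary:
    table: pd.DataFrame
    frac_reciprocal_higher: float
    frac_gt90: float
    frac_gt95: float


def reciprocal_classify(
    initial_hits: Sequence[HomologyHit],
    subjects: Sequence[ReferenceContig],
    reference: Sequence[ReferenceContig],
    scheme: ScoringScheme = HOMOLOGY_SCHEME,
    min_block_length: int = 100,
) -> ReciprocalSummary:
    """Search each initial hit's subject back against the full parent set.

    A hit is *reciprocal-higher* when the subject's best reciprocal
    identity strictly exceeds the identity of the initial query-subject
    pair -- evidence that the initial subject is the ortholog of a
    different parent gene rather than the query's homeolog.  Fractions
    of reciprocal identities above 90% and 95% are also reported.
    """
    seq_by_id = {c.id: c for c in subjects}
    searcher = HomologySearcher(
        reference, "parent_reference", scheme, min_block_length
    )
    rows = []
    for hit in initial_hits:
        subj = seq_by_id.get(hit.subject_id)
        if subj is None:
            raise ConfigurationError(
                f"subject {hit.subject_id} of hit {hit.query_id} not in subjects"
            )
        rec = searcher.best_hit(subj)
        rec_id = rec.subject_id if rec else None
        rec_ident = rec.aggregated_identity if rec else np.nan
        rows.append(
            {
                "query": hit.query_id,
                "subject": hit.subject_id,
                "initial_identity": hit.aggregated_identity,
                "reciprocal_best": rec_id,
                "reciprocal_identity": rec_ident,
                "reciprocal_higher": bool(
                    rec is not None and rec_ident > hit.aggregated_identity
                ),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        frac_higher = float(df["reciprocal_higher"].mean())
        frac90 = float((df["reciprocal_identity"] > 90).mean())
        frac95 = float((df["reciprocal_identity"] > 95).mean())
    else:
        frac_higher = frac90 = frac95 = float("nan")
    return ReciprocalSummary(df, frac_higher, frac90, frac95)


def plot_identity_histogram(
    non_detected: IdentityDistribution,
    control: IdentityDistribution,
    path,
    labels: tuple[str, str] = ("non-expressed", "random control"),
    as_percent: bool = True,
) -> None:
    """Paired-bar histogram of the two identity-class distributions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(non_detected.labels))
    a = non_detected.counts.astype(float)
    b = control.counts.astype(float)
    if as_percent:
        a = 100 * a / max(a.sum(), 1)
        b = 100 * b / max(b.sum(), 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(x - 0.2, a, width=0.4, color="black", label=labels[0])
    ax.bar(x + 0.2, b, width=0.4, color="0.6", label=labels[1])
    ax.set_xticks(x)
    ax.set_xticklabels(non_detected.labels, rotation=45, ha="right")
    ax.set_xlabel("percent identity class")
    ax.set_ylabel("% of genes" if as_percent else "genes")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
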