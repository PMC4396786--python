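"""Synthetic allopolyploid transcriptome experiments with known truth.

The generator emulates the design of the motivating study: a parental
(rye-like) reference set of cDNA contigs; comparator sequence sets
standing in for the partner (wheat A/B) subgenomes, each a mutated copy
of a parent gene landing in a controlled percent-identity class; and
454-style single-end read libraries of unequal depth from several
parent and polyploid tissues.  A configured fraction of parent genes is
deleted from the polyploid genome, another fraction is silenced
(present but untranscribed); retained genes are transcribed in the
polyploid at a fraction ``f`` (default 1/3) of their parent rate, with
the partner-subgenome comparators absorbing the remaining read mass so
that ``f`` holds exactly at fixed library depth.

Everything is driven by one integer seed; identical configurations give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from ._encode import decode
from .containers import ReadLibrary, ReferenceContig, encode_contigs
from .errors import ConfigurationError

RETAINED, DELETED, SILENCED = "retained", "deleted", "silenced"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults; see the methods note for rationale.

    ``identity_class_weights`` gives the probability of each comparator
    identity bin (edges in ``identity_bin_edges``); with
    ``divergence_bias`` on, deleted/silenced genes draw instead from
    ``biased_class_weights`` concentrated on the low-identity bins,
    reproducing the empirical coupling between subgenome gene loss and
    homeolog divergence.
    """

    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (500, 1500)
    parent_depths: tuple[int, ...] = (100_000, 180_000, 320_000)
    polyploid_depths: tuple[int, ...] = (100_000, 160_000, 260_000, 480_000)
    parent_tissues: tuple[str, ...] = ("anther", "root", "stem")
    polyploid_tissues: tuple[str, ...] = ("anther", "root", "stem", "seed")
    read_length_mean: float = 400.0
    read_length_sd: float = 80.0
    min_read_length: int = 50
    substitution_rate: float = 0.005
    indel_rate: float = 2e-4
    qual_mean: float = 33.0
    qual_end_decay: float = 14.0
    qual_sd: float = 5.0
    expression_log_range: tuple[float, float] = (1.0, 1000.0)
    deleted_fraction: float = 0.05
    silenced_fraction: float = 0.03
    expression_fraction_f: float = 1.0 / 3.0
    identity_bin_edges: tuple[float, ...] = (70, 75, 80, 85, 90, 95, 100)
    identity_class_weights: tuple[float, ...] = (0.03, 0.07, 0.10, 0.15, 0.25, 0.40)
    biased_class_weights: tuple[float, ...] = (0.45, 0.35, 0.12, 0.08, 0.0, 0.0)
    divergence_bias: bool = True
    comparator_expression: bool = True
    comparator_indel_fraction: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be >= 0")
        lo, hi = self.gene_length_range
        if not 0 < lo <= hi:
            raise ConfigurationError("gene_length_range must satisfy 0 < lo <= hi")
        for name in ("parent_depths", "polyploid_depths"):
            depths = getattr(self, name)
            if len(depths) == 0 or any(d <= 0 for d in depths):
                raise ConfigurationError(f"{name}: all library depths must be > 0")
        if self.deleted_fraction < 0 or self.silenced_fraction < 0:
            raise ConfigurationError("deleted_fraction/silenced_fraction must be >= 0")
        if self.deleted_fraction + self.silenced_fraction > 1:
            raise ConfigurationError(
                "deleted_fraction + silenced_fraction must not exceed 1"
            )
        if self.expression_fraction_f < 0:
            raise ConfigurationError("expression_fraction_f must be >= 0")
        edges = self.identity_bin_edges
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ConfigurationError("identity_bin_edges must be strictly increasing")
        if edges[-1] > 100:
            raise ConfigurationError("identity_bin_edges: bins above 100% are unreachable")
        for name in ("identity_class_weights", "biased_class_weights"):
            w = getattr(self, name)
            if len(w) != len(edges) - 1:
                raise ConfigurationError(f"{name}: need one weight per identity bin")
            if any(x < 0 for x in w):
                raise ConfigurationError(f"{name}: weights must be >= 0")
            if abs(sum(w) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name}: weights must sum to 1")
        if not 0 <= self.substitution_rate < 1 or not 0 <= self.indel_rate < 1:
            raise ConfigurationError("substitution_rate/indel_rate must be in [0, 1)")


@dataclass
class SyntheticExperiment:
    """Bundle of everything one simulated study produces."""

    config: SimulationConfig
    genes: list[ReferenceContig]
    comparators: list[ReferenceContig]
    truth: pd.DataFrame  # gene_id, status, weight, rate, identity_bin, target_identity
    parent_libraries: list[ReadLibrary]
    polyploid_libraries: list[ReadLibrary]

    @property
    def polyploid_genome(self) -> list[ReferenceContig]:
        """Genomic sequence set of the polyploid: all parent genes except the
        deleted ones, plus the partner-subgenome comparators."""
        deleted = set(self.truth.loc[self.truth.status == DELETED, "gene_id"])
        present = [g for g in self.genes if g.id not in deleted]
        return present + list(self.comparators)

    @property
    def libraries(self) -> list[ReadLibrary]:
        return self.parent_libraries + self.polyploid_libraries


def _streams(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    names = ["genes", "truth", "comparators", "libraries"]
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


def simulate_parent_genes(config: SimulationConfig) -> list[ReferenceContig]:
    """Random parental cDNA contigs over ACGT, lengths uniform in range."""
    config.validate()
    rng = _streams(config.seed)["genes"]
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    width = max(5, len(str(max(config.n_genes, 1))))
    genes = []
    for i, L in enumerate(lengths):
        codes = rng.integers(0, 4, size=int(L)).astype(np.uint8)
        genes.append(ReferenceContig(f"RYE_{i + 1:0{width}d}", decode(codes)))
    return genes


def assign_truth(config: SimulationConfig) -> pd.DataFrame:
    """Statuses and expression weights for each gene.

    Exactly ``round(n * deleted_fraction)`` genes are deleted and
    ``round(n * silenced_fraction)`` silenced; expression weights are
    log-uniform so that genes fall on both sides of the 10-read
    detection filter at the configured depths.
    """
    config.validate()
    rng = _streams(config.seed)["truth"]
    n = config.n_genes
    n_del = int(round(n * config.deleted_fraction))
    n_sil = int(round(n * config.silenced_fraction))
    status = np.array([RETAINED] * n, dtype=object)
    order = rng.permutation(n)
    status[order[:n_del]] = DELETED
    status[order[n_del : n_del + n_sil]] = SILENCED
    lo, hi = config.expression_log_range
    weights = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    rates = weights / weights.sum() if n else weights
    width = max(5, len(str(max(n, 1))))
    return pd.DataFrame(
        {
            "gene_id": [f"RYE_{i + 1:0{width}d}" for i in range(n)],
            "status": status,
            "weight": weights,
            "rate": rates,
        }
    )


def _stratified_positions(idx: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n distinct picks from idx, one per equal-width stratum (near-uniform density)."""
    n = min(n, idx.size)
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    bounds = np.linspace(0, idx.size, n + 1)
    pick = np.unique(
        np.clip((bounds[:-1] + rng.random(n) * np.diff(bounds)).astype(np.int64), 0, idx.size - 1)
    )
    if pick.size < n:  # strata collisions: top up from unused positions
        unused = np.setdiff1d(np.arange(idx.size), pick)
        extra = rng.choice(unused, size=n - pick.size, replace=False)
        pick = np.union1d(pick, extra)
    return idx[pick]


def _model_segments(scores: np.ndarray, min_cols: int, min_score: int = 20, max_seg: int = 8):
    """Maximal positive-scoring segments of a 1-D column-score profile.

    This mirrors, on the known mutation layout, how the local aligner
    carves the gene/comparator alignment into blocks: repeatedly take
    the best-sum segment, mask it, stop below ``min_score``.  Returns
    [(start, end)] of segments at least ``min_cols`` long.
    """
    s = scores.astype(np.float64).copy()
    segments = []
    for _ in range(max_seg):
        # Kadane with start tracking
        best = 0.0
        cur = 0.0
        start = 0
        b0 = b1 = -1
        for i, v in enumerate(s):
            if cur <= 0:
                cur = v
                start = i
            else:
                cur += v
            if cur > best:
                best = cur
                b0, b1 = start, i + 1
        if best < min_score or b0 < 0:
            break
        segments.append((b0, b1))
        s[b0:b1] = -np.inf
    return [(a, b) for a, b in segments if b - a >= min_cols]


def _mutate_to_identity(
    codes: np.ndarray,
    target: float,
    indel_fraction: float,
    rng: np.random.Generator,
    match: int = 1,
    mismatch: int = -2,
    gap_cost: int = -7,
    min_block: int = 100,
) -> np.ndarray:
    """Mutate a copy of ``codes`` so that its identity to the original —
    aggregated over qualifying local alignment blocks, the way the
    divergence stage measures it — lands on ``target`` percent.

    Substitutions are stratified over positions outside a few short
    conserved islands (mimicking conserved motifs and guaranteeing that
    exact seed words survive even at 70% identity; both termini are
    always islands so terminal trimming cannot inflate identity).  Near
    the scoring break-even (~70%) the best local blocks still favor the
    cleaner stretches, so a 1-D model of the block extraction is used to
    add compensating substitutions inside the surviving segments until
    the modeled aggregated identity matches the target.
    """
    L = codes.size
    n_events = int(round(L * (1.0 - target / 100.0)))
    n_indel = int(round(n_events * indel_fraction))
    n_sub = n_events - n_indel

    island_len = 18
    n_islands = max(2, L // 250)
    allowed = np.ones(L, dtype=bool)
    allowed[:island_len] = False
    allowed[max(L - island_len, 0) :] = False
    for start in rng.integers(0, max(L - island_len, 1), size=n_islands):
        allowed[start : start + island_len] = False

    sub_mask = np.zeros(L, dtype=bool)
    sub_mask[_stratified_positions(np.flatnonzero(allowed), n_sub, rng)] = True
    indel_pos = rng.choice(
        np.flatnonzero(allowed & ~sub_mask), size=n_indel, replace=False
    ) if n_indel > 0 else np.empty(0, dtype=np.int64)
    indel_del = rng.random(n_indel) < 0.5

    for _ in range(10):
        col = np.full(L, float(match))
        col[sub_mask] = mismatch
        col[indel_pos] = gap_cost
        segs = _model_segments(col, min_block)
        if not segs:
            break
        kept = np.zeros(L, dtype=bool)
        for a, b in segs:
            kept[a:b] = True
        n_match = int((kept & ~sub_mask).sum()) - int(np.isin(indel_pos, np.flatnonzero(kept)).sum())
        realized = 100.0 * n_match / kept.sum()
        excess = realized - target
        if excess <= 0.5:
            break
        room = np.flatnonzero(kept & allowed & ~sub_mask)
        room = room[~np.isin(room, indel_pos)]
        n_add = min(max(1, int(round(excess / 100.0 * kept.sum()))), room.size)
        if n_add == 0:
            break
        sub_mask[_stratified_positions(room, n_add, rng)] = True

    out = codes.copy()
    pos = np.flatnonzero(sub_mask)
    out[pos] = (out[pos] + rng.integers(1, 4, size=pos.size)) % 4
    seq = list(out)
    for p, is_del in sorted(zip(indel_pos.tolist(), indel_del.tolist()), reverse=True):
        if is_del and len(seq) > 1:
            del seq[p]
        else:
            seq.insert(p, int(rng.integers(0, 4)))
    return np.array(seq, dtype=np.uint8)


def derive_comparator_set(
    genes: Sequence[ReferenceContig],
    config: SimulationConfig,
    truth: pd.DataFrame | None = None,
) -> tuple[list[ReferenceContig], pd.DataFrame]:
    """One comparator (partner-subgenome homeolog) per parent gene.

    Each comparator is the parent sequence mutated to land inside a
    percent-identity bin drawn from the configured class weights; with
    ``divergence_bias`` on, deleted/silenced genes draw from the
    low-identity biased weights instead.  Returns the comparators and a
    table of (gene_id, identity_bin, target_identity).
    """
    config.validate()
    rng = _streams(config.seed)["comparators"]
    edges = np.asarray(config.identity_bin_edges, dtype=float)
    base_w = np.asarray(config.identity_class_weights, dtype=float)
    bias_w = np.asarray(config.biased_class_weights, dtype=float)
    lost = set()
    if truth is not None and config.divergence_bias:
        lost = set(truth.loc[truth.status != RETAINED, "gene_id"])
    comparators = []
    rows = []
    for g in genes:
        w = bias_w if g.id in lost else base_w
        b = int(rng.choice(w.size, p=w))
        target = float(rng.uniform(edges[b], edges[b + 1]))
        codes, _ = encode_contigs([g])
        mutated = _mutate_to_identity(
            codes, target, config.comparator_indel_fraction, rng
        )
        comparators.append(ReferenceContig("WCOMP_" + g.id.split("_", 1)[1], decode(mutated)))
        rows.append(
            {
                "gene_id": g.id,
                "identity_bin": f"{edges[b]:g}-{edges[b + 1]:g}",
                "target_identity": target,
            }
        )
    return comparators, pd.DataFrame(rows)


def _library_rates(
    truth: pd.DataFrame, config: SimulationConfig, species: str
) -> np.ndarray:
    """Per-source sampling probabilities over [genes..., comparators...].

    Parent libraries draw only from the parent genes.  Polyploid
    libraries draw retained genes at exactly ``f`` times their parent
    rate, deleted and silenced genes at rate zero, and (when enabled)
    the partner-subgenome comparators absorb the remaining probability
    mass in proportion to their parent counterparts' rates.
    """
    n = len(truth)
    r = truth["rate"].to_numpy()
    if species == "parent":
        p = np.concatenate([r, np.zeros(n)])
        return p / p.sum()
    f = config.expression_fraction_f
    retained = (truth["status"] == RETAINED).to_numpy()
    rye = np.where(retained, f * r, 0.0)
    mass = rye.sum()
    if mass > 1.0:
        raise ConfigurationError(
            "expression_fraction_f too large: polyploid rye-subgenome read mass exceeds 1"
        )
    if config.comparator_expression:
        comp = r * ((1.0 - mass) / r.sum())
        p = np.concatenate([rye, comp])
    else:
        p = np.concatenate([rye, np.zeros(n)])
        if p.sum() == 0:
            raise ConfigurationError(
                "polyploid libraries have no expressed source (f=0 and comparator_expression off)"
            )
    return p / p.sum()


def simulate_libraries(
    genes: Sequence[ReferenceContig],
    comparators: Sequence[ReferenceContig],
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[list[ReadLibrary], list[ReadLibrary]]:
    """Draw all parent and polyploid read libraries at the configured depths."""
    config.validate()
    rng = _streams(config.seed)["libraries"]
    src_codes, src_off = encode_contigs(list(genes) + list(comparators))
    src_len = np.diff(src_off)

    def one(lib_id: str, species: str, depth: int, kseed: int) -> ReadLibrary:
        p = _library_rates(truth, config, species)
        u = rng.random(depth)
        cdf = np.cumsum(p)
        cdf[-1] = 1.0
        src_idx = np.searchsorted(cdf, u, side="right").astype(np.int64)
        slen = src_len[src_idx]
        req = np.rint(rng.normal(config.read_length_mean, config.read_length_sd, depth))
        req = np.clip(req, config.min_read_length, slen).astype(np.int64)
        starts = (rng.random(depth) * (slen - req + 1)).astype(np.int64)
        strands = rng.integers(0, 2, size=depth).astype(np.int64)
        seq, qual, off = _kernels.make_reads(
            src_codes,
            src_off,
            src_idx,
            req,
            starts,
            strands,
            config.substitution_rate,
            config.indel_rate,
            config.qual_mean,
            config.qual_end_decay,
            config.qual_sd,
            kseed,
        )
        return ReadLibrary(lib_id, species, seq, qual, off, true_source=src_idx)

    kernel_seeds = rng.integers(0, 2**31 - 1, size=len(config.parent_depths) + len(config.polyploid_depths))
    parent_libs = []
    for i, (tissue, depth) in enumerate(zip(config.parent_tissues, config.parent_depths)):
        parent_libs.append(one(f"parent_{tissue}", "parent", int(depth), int(kernel_seeds[i])))
    polyploid_libs = []
    off = len(config.parent_depths)
    for i, (tissue, depth) in enumerate(
        zip(config.polyploid_tissues, config.polyploid_depths)
    ):
        polyploid_libs.append(
            one(f"polyploid_{tissue}", "polyploid", int(depth), int(kernel_seeds[off + i]))
        )
    return parent_libs, polyploid_libs


def simulate_experiment(config: SimulationConfig) -> SyntheticExperiment:
    """Run the full generator: genes, truth, comparators, libraries."""
    config.validate()
    if len(config.parent_tissues) < len(config.parent_depths) or len(
        config.polyploid_tissues
    ) < len(config.polyploid_depths):
        raise ConfigurationError("need one tissue name per library depth")
    genes = simulate_parent_genes(config)
    truth = assign_truth(config)
    comparators, classes = derive_comparator_set(genes, config, truth)
    truth = truth.merge(classes, on="gene_id", how="left")
    parent_libs, poly_libs = simulate_libraries(genes, comparators, truth, config)
    return SyntheticExperiment(config, genes, comparators, truth, parent_libs, poly_libs)


def small_config(**overrides) -> SimulationConfig:
    """A reduced configuration for quick, fully-featured test runs."""
    base = SimulationConfig(
        n_genes=80,
        gene_length_range=(300, 700),
        parent_depths=(4000, 6000),
        polyploid_depths=(5000, 8000),
        parent_tissues=("anther", "root"),
        polyploid_tissues=("anther", "root"),
        read_length_mean=250.0,
        read_length_sd=50.0,
        deleted_fraction=0.1,
        silenced_fraction=0.05,
        seed=11,
    )
    return replace(base, **overrides)
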