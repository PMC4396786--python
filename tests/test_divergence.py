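import numpy as np
import pytest

from allosilence.align import AlignmentBlock, HOMOLOGY_SCHEME
from allosilence.containers import ReferenceContig
from allosilence.divergence import (
    DEFAULT_BIN_EDGES,
    HomologySearcher,
    aggregate_identity,
    best_hit,
    chi2_contingency,
    chi2_null_calibration,
    compare_distributions,
    identity_distribution,
    reciprocal_classify,
    sample_control,
)
from allosilence.errors import ConfigurationError, DomainError

from _oracles import column_identity, pearson_chi2, random_seq


def _block(length, matches, score=None):
    return AlignmentBlock(0, length, 0, length, length, matches, 0, score or matches)


def test_aggregate_identity_total_block_length_rule():
    # (90 + 180) / (100 + 200) = 90.0%
    assert aggregate_identity([_block(100, 90), _block(200, 180)]) == pytest.approx(90.0)
    assert aggregate_identity([]) == 0.0


def test_best_hit_identical_subject_and_block_filter(rng):
    gene = ReferenceContig("q", random_seq(rng, 400))
    exact = ReferenceContig("s_exact", gene.sequence)
    short = ReferenceContig("s_short", gene.sequence[:80] + random_seq(rng, 300))
    hit = best_hit(gene, [short, exact])
    assert hit is not None
    assert hit.subject_id == "s_exact"
    assert hit.aggregated_identity == pytest.approx(100.0)
    # a subject whose only alignable block is 80 nt does not qualify
    assert best_hit(gene, [short]) is None


def test_best_hit_multi_exon_matches_column_oracle(rng):
    gene = ReferenceContig("q", random_seq(rng, 500))
    exon1, exon2 = gene.sequence[:150], gene.sequence[300:450]
    subject = ReferenceContig("s", exon1 + random_seq(rng, 250) + exon2)
    hit = best_hit(gene, [subject])
    assert hit is not None and len(hit.blocks) == 2
    matches = cols = 0
    for b in hit.blocks:  # exact-copy exons: blocks are gapless
        m, c = column_identity(
            gene.sequence[b.q_start : b.q_end], subject.sequence[b.s_start : b.s_end]
        )
        matches += m
        cols += c
    assert hit.aggregated_identity == pytest.approx(100.0 * matches / cols)
    assert hit.aggregated_identity > 99.0


def test_identity_distribution_binning():
    dist = identity_distribution([91.0, 93.0, 74.0], DEFAULT_BIN_EDGES)
    by_label = dict(zip(dist.labels, dist.counts))
    assert by_label["70-75"] == 1
    assert by_label["90-95"] == 2
    assert dist.unmatched == 0
    assert dist.set_size == 3


def test_identity_distribution_edge_cases():
    empty = identity_distribution([], DEFAULT_BIN_EDGES)
    assert empty.counts.sum() == 0 and empty.set_size == 0
    with_unmatched = identity_distribution([None, 100.0], DEFAULT_BIN_EDGES)
    assert with_unmatched.unmatched == 1
    assert with_unmatched.counts[-1] == 1  # 100% closes into the top class
    with pytest.raises(ConfigurationError):
        identity_distribution([50.0], (70, 60, 90))


def test_sample_control_deterministic_and_excluding():
    ids = [f"g{i:03d}" for i in range(300)]
    a = sample_control(ids, n=50, seed=9, exclude={"g000", "g001"})
    b = sample_control(ids, n=50, seed=9, exclude={"g000", "g001"})
    assert a == b
    assert len(set(a)) == 50
    assert not {"g000", "g001"} & set(a)
    assert sample_control(ids, n=0, seed=1) == []
    with pytest.raises(ConfigurationError):
        sample_control(ids, n=301, seed=1)


def test_chi2_hand_computed_example():
    res = chi2_contingency([[10, 90], [50, 50]])
    # margins give E = (30, 70, 30, 70); chi2 = 400*(2/30 + 2/70)
    assert res.chi2 == pytest.approx(400 * (2 / 30 + 2 / 70))
    assert res.df == 1
    assert res.p_value < 1e-9


def test_chi2_equal_proportions_is_zero():
    res = chi2_contingency([[20, 80], [20, 80]])
    assert res.chi2 == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_chi2_zero_margin_names_the_margin():
    with pytest.raises(DomainError, match="column 0"):
        chi2_contingency([[0, 5], [0, 5]])
    with pytest.raises(DomainError, match="row 1"):
        chi2_contingency([[1, 5], [0, 0]])


def test_chi2_matches_independent_formula(rng):
    for _ in range(50):
        shape = (2, int(rng.integers(2, 6)))
        table = rng.integers(1, 200, size=shape)
        res = chi2_contingency(table)
        expected, df = pearson_chi2(table)
        assert res.chi2 == pytest.approx(expected, abs=1e-9)
        assert res.df == df


def test_compare_identical_distributions_is_null():
    d = identity_distribution([72, 81, 93, 97], DEFAULT_BIN_EDGES)
    for r in compare_distributions(d, d, mode="per-class"):
        assert r.chi2 == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)


def test_single_class_per_class_equals_global():
    # one class only: both modes degenerate to the same trivial null result
    edges = (0.0, 100.0)
    a = identity_distribution([50, 60, 70], edges)
    b = identity_distribution([80, 90], edges)
    per_class = compare_distributions(a, b, mode="per-class")
    glob = compare_distributions(a, b, mode="global")
    assert len(per_class) == 1
    assert per_class[0].chi2 == glob[0].chi2 == pytest.approx(0.0)
    assert per_class[0].p_value == glob[0].p_value == pytest.approx(1.0)


def test_compare_modes_and_bonferroni(rng):
    a = identity_distribution(list(rng.uniform(70, 100, 80)), DEFAULT_BIN_EDGES)
    b = identity_distribution(list(rng.uniform(85, 100, 80)), DEFAULT_BIN_EDGES)
    per_class = compare_distributions(a, b, mode="per-class")
    assert len(per_class) == len(DEFAULT_BIN_EDGES) - 1
    k = len(per_class)
    for r in per_class:
        assert r.p_bonferroni == pytest.approx(min(1.0, r.p_value * k))
    glob = compare_distributions(a, b, mode="global")
    assert len(glob) == 1 and glob[0].df >= 1
    with pytest.raises(ConfigurationError):
        compare_distributions(
            a, identity_distribution([], (0, 50, 100)), mode="per-class"
        )


def test_null_calibration_close_to_alpha():
    rate = chi2_null_calibration(
        150, 150, (0.2, 0.2, 0.2, 0.2, 0.2), n_reps=2000, alpha=0.05, seed=4
    )
    assert 0.03 < rate < 0.07


class TestReciprocal:
    def setup_method(self):
        rng = np.random.default_rng(12)
        self.gene_a = ReferenceContig("RYE_A", random_seq(rng, 600))
        self.gene_b = ReferenceContig("RYE_B", random_seq(rng, 600))
        self.rng = rng

    def _mutated(self, seq, rate):
        out = list(seq)
        n = int(len(out) * rate)
        for p in self.rng.choice(len(out), size=n, replace=False):
            out[p] = "ACGT"[("ACGT".index(out[p]) + 1) % 4]
        return "".join(out)

    def test_ortholog_of_other_gene_is_reciprocal_higher(self):
        # subject is hit by gene A at ~85% identity, but is a near-copy
        # (ortholog) of gene B: the reciprocal search must prefer B
        subject = ReferenceContig("EST_1", self._mutated(self.gene_a.sequence, 0.15))
        gene_b = ReferenceContig("RYE_B", self._mutated(subject.sequence, 0.02))
        hit_a = best_hit(self.gene_a, [subject])
        assert hit_a is not None and hit_a.aggregated_identity < 90
        summary = reciprocal_classify([hit_a], [subject], [self.gene_a, gene_b])
        row = summary.table.iloc[0]
        assert row["reciprocal_best"] == "RYE_B"
        assert row["reciprocal_identity"] > hit_a.aggregated_identity
        assert bool(row["reciprocal_higher"])

    def test_own_ortholog_at_same_identity_is_not_higher(self):
        subject = ReferenceContig("EST_2", self.gene_a.sequence)
        hit = best_hit(self.gene_a, [subject])
        summary = reciprocal_classify([hit], [subject], [self.gene_a, self.gene_b])
        row = summary.table.iloc[0]
        assert row["reciprocal_best"] == "RYE_A"
        assert not row["reciprocal_higher"]
        assert summary.frac_reciprocal_higher == 0.0

    def test_self_built_comparator_gives_zero_reciprocal_higher(self, tiny_exp):
        # comparators are the flagged genes' own sequences: the reciprocal
        # best is the query itself at the same identity
        genes = tiny_exp.genes[:6]
        subjects = [ReferenceContig(f"C_{g.id}", g.sequence) for g in genes]
        searcher = HomologySearcher(subjects, "self")
        hits = [searcher.best_hit(g) for g in genes]
        summary = reciprocal_classify([h for h in hits if h], subjects, tiny_exp.genes)
        assert summary.frac_reciprocal_higher == 0.0
        assert summary.frac_gt95 == 1.0
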