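import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allosilence.align import HOMOLOGY_SCHEME, align_local
from allosilence.divergence import aggregate_identity
from allosilence.errors import ConfigurationError
from allosilence.io import read_fastq, write_fastq
from allosilence.simulate import (
    SimulationConfig,
    assign_truth,
    derive_comparator_set,
    simulate_experiment,
    simulate_parent_genes,
    small_config,
)


def test_gene_lengths_and_alphabet():
    cfg = small_config(n_genes=100, gene_length_range=(500, 1500), seed=7)
    genes = simulate_parent_genes(cfg)
    assert len(genes) == 100
    for g in genes:
        assert 500 <= len(g.sequence) <= 1500
        assert set(g.sequence) <= set("ACGT")


def test_seeded_determinism_is_byte_identical(tmp_path):
    cfg = small_config(seed=42)
    a = simulate_experiment(cfg)
    b = simulate_experiment(cfg)
    assert [g.sequence for g in a.genes] == [g.sequence for g in b.genes]
    assert [c.sequence for c in a.comparators] == [c.sequence for c in b.comparators]
    pd.testing.assert_frame_equal(a.truth, b.truth)
    for la, lb in zip(a.libraries, b.libraries):
        write_fastq(la, tmp_path / "a.fastq")
        write_fastq(lb, tmp_path / "b.fastq")
        assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()


def test_zero_genes_is_valid_degenerate_case():
    cfg = small_config(n_genes=0, deleted_fraction=0, silenced_fraction=0)
    assert simulate_parent_genes(cfg) == []
    assert len(assign_truth(cfg)) == 0


def test_truth_statuses_partition_exactly():
    cfg = small_config(n_genes=200, deleted_fraction=0.07, silenced_fraction=0.031)
    truth = assign_truth(cfg)
    counts = truth.status.value_counts()
    assert counts.get("deleted", 0) == round(200 * 0.07)
    assert counts.get("silenced", 0) == round(200 * 0.031)
    assert counts.sum() == 200
    assert truth["rate"].sum() == pytest.approx(1.0)


@pytest.mark.parametrize(
    "overrides, message",
    [
        (dict(n_genes=-1), "n_genes"),
        (dict(gene_length_range=(0, 10)), "gene_length_range"),
        (dict(parent_depths=(0,)), "parent_depths"),
        (dict(deleted_fraction=0.7, silenced_fraction=0.5), "deleted_fraction"),
        (dict(identity_class_weights=(0.5, 0.5, 0, 0, 0, 0.1)), "identity_class_weights"),
        (dict(identity_bin_edges=(70, 80, 90, 101), identity_class_weights=(1, 0, 0), biased_class_weights=(1, 0, 0)), "unreachable"),
    ],
)
def test_invalid_configs_name_the_field(overrides, message):
    with pytest.raises(ConfigurationError, match=message):
        small_config(**overrides).validate()


def test_depths_are_exact_and_sources_respect_truth(tiny_exp):
    cfg = tiny_exp.config
    for lib, depth in zip(tiny_exp.parent_libraries, cfg.parent_depths):
        assert lib.n_reads == depth
    for lib, depth in zip(tiny_exp.polyploid_libraries, cfg.polyploid_depths):
        assert lib.n_reads == depth
    # deleted and silenced genes emit zero polyploid reads, by construction
    truth = tiny_exp.truth
    lost_idx = set(truth.index[truth.status != "retained"])
    for lib in tiny_exp.polyploid_libraries:
        assert not (set(np.unique(lib.true_source)) & lost_idx)
    # parent libraries draw only from parent genes
    n = cfg.n_genes
    for lib in tiny_exp.parent_libraries:
        assert lib.true_source.max() < n


def test_comparator_identity_lands_in_drawn_bin():
    """Bin 90-95 drawn for ~1-kb genes: realized aggregated identity in [89, 96]."""
    cfg = small_config(
        n_genes=12,
        gene_length_range=(950, 1050),
        identity_class_weights=(0, 0, 0, 0, 1.0, 0),
        biased_class_weights=(0, 0, 0, 0, 1.0, 0),
        seed=3,
    )
    genes = simulate_parent_genes(cfg)
    comps, classes = derive_comparator_set(genes, cfg, assign_truth(cfg))
    for g, c in zip(genes, comps):
        blocks = [
            b for b in align_local(g.sequence, c.sequence, HOMOLOGY_SCHEME) if b.length >= 100
        ]
        assert blocks, f"{g.id}: no qualifying alignment"
        assert 89.0 <= aggregate_identity(blocks) <= 96.0


def test_single_bin_class_weights_bound_identity():
    cfg = small_config(
        n_genes=10,
        identity_class_weights=(0, 0, 0, 0, 0, 1.0),
        biased_class_weights=(0, 0, 0, 0, 0, 1.0),
        seed=9,
    )
    genes = simulate_parent_genes(cfg)
    comps, classes = derive_comparator_set(genes, cfg, assign_truth(cfg))
    for g, c, t in zip(genes, comps, classes["target_identity"]):
        assert 95.0 <= t <= 100.0
        blocks = [
            b for b in align_local(g.sequence, c.sequence, HOMOLOGY_SCHEME) if b.length >= 100
        ]
        assert aggregate_identity(blocks) >= 94.0


def test_divergence_bias_lowers_lost_gene_identity(tiny_exp):
    truth = tiny_exp.truth
    lost = truth[truth.status != "retained"]["target_identity"]
    kept = truth[truth.status == "retained"]["target_identity"]
    assert lost.mean() < kept.mean()


def test_equal_rates_without_loss_match_parent_counts():
    """f=1, no deletion/silencing: per-gene parent vs polyploid read counts
    agree within binomial sampling error (chi-squared GOF p > 0.001)."""
    cfg = small_config(
        n_genes=60,
        deleted_fraction=0.0,
        silenced_fraction=0.0,
        expression_fraction_f=1.0,
        parent_depths=(20000,),
        polyploid_depths=(20000,),
        parent_tissues=("root",),
        polyploid_tissues=("root",),
        seed=21,
    )
    exp = simulate_experiment(cfg)
    parent = np.bincount(exp.parent_libraries[0].true_source, minlength=120)
    poly = np.bincount(exp.polyploid_libraries[0].true_source, minlength=120)
    ok = 0
    tested = 0
    for g in range(60):
        o = np.array([parent[g], poly[g]])
        if o.sum() < 10:
            continue
        tested += 1
        p = stats.chisquare(o, f_exp=o.sum() / 2 * np.ones(2)).pvalue
        ok += p > 0.001
    assert tested > 30
    assert ok / tested >= 0.95


def test_polyploid_rye_fraction_is_f(tiny_exp):
    """Retained genes are sampled in the polyploid at exactly f times their
    parent rate; comparators absorb the rest of the library."""
    cfg = tiny_exp.config
    truth = tiny_exp.truth
    retained_rate = truth.loc[truth.status == "retained", "rate"].sum()
    expected_rye_fraction = cfg.expression_fraction_f * retained_rate
    lib = tiny_exp.polyploid_libraries[1]
    rye_reads = (lib.true_source < cfg.n_genes).mean()
    assert rye_reads == pytest.approx(expected_rye_fraction, abs=0.02)


def test_fastq_round_trip(tmp_path, tiny_exp):
    lib = tiny_exp.parent_libraries[0]
    path = tmp_path / "lib.fastq"
    write_fastq(lib, path)
    back = read_fastq(path, lib.library_id, lib.species)
    assert back.n_reads == lib.n_reads
    for i in (0, 1, lib.n_reads - 1):
        rid_a, seq_a, q_a = lib.get(i)
        rid_b, seq_b, q_b = back.get(i)
        assert (rid_a, seq_a) == (rid_b, seq_b)
        assert list(q_a) == list(q_b)
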