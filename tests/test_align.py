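import numpy as np
import pytest

from allosilence.align import (
    HOMOLOGY_SCHEME,
    MAPPING_SCHEME,
    ReferenceIndex,
    ScoringScheme,
    align_local,
    map_read,
)
from allosilence.containers import ReadLibrary, ReferenceContig
from allosilence.errors import ConfigurationError

from _oracles import random_seq, sw_best_score


def test_identity_alignment(rng):
    seq = random_seq(rng, 200)
    blocks = align_local(seq, seq, HOMOLOGY_SCHEME)
    top = blocks[0]
    assert top.score == 200
    assert top.percent_identity == 100.0
    assert top.length == 200
    assert (top.q_start, top.q_end) == (0, 200)


def test_ten_substitutions_give_95_percent(rng):
    seq = random_seq(rng, 200)
    mutated = list(seq)
    # interior positions so local trimming cannot drop them
    for p in rng.choice(np.arange(10, 190), size=10, replace=False):
        mutated[p] = "ACGT"[("ACGT".index(mutated[p]) + 1) % 4]
    top = align_local(seq, "".join(mutated), HOMOLOGY_SCHEME)[0]
    assert top.percent_identity == pytest.approx(95.0)
    assert top.length == 200


def test_reverse_complement_same_identity(rng):
    seq = random_seq(rng, 150)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[c] for c in reversed(seq))
    fwd = align_local(seq, seq, HOMOLOGY_SCHEME)[0]
    rev = align_local(rc, seq, HOMOLOGY_SCHEME)[0]
    assert rev.score == fwd.score
    assert rev.percent_identity == fwd.percent_identity
    assert rev.strand == "-"
    assert not align_local(rc, seq, HOMOLOGY_SCHEME, both_strands=False)


def test_empty_sequences_empty_result():
    assert align_local("", "ACGT") == []
    assert align_local("ACGT", "") == []


def test_n_bases_never_match():
    top = align_local("ACGTNNACGT", "ACGTAAACGT", HOMOLOGY_SCHEME, min_block_score=1)[0]
    assert top.matches == 8
    assert top.length == 10


@pytest.mark.parametrize("scheme", [MAPPING_SCHEME, HOMOLOGY_SCHEME])
def test_top_score_equals_bruteforce_smith_waterman(scheme, rng):
    """Seeded/banded machinery must not change exact best-score semantics."""
    for _ in range(30):
        n1 = int(rng.integers(20, 300))
        n2 = int(rng.integers(20, 300))
        q = random_seq(rng, n1, n_frac=0.02)
        # half the cases: related sequences, so scores are non-trivial
        if rng.random() < 0.5:
            s = q[: int(rng.integers(10, n1))] + random_seq(rng, int(rng.integers(0, 50)))
        else:
            s = random_seq(rng, n2, n_frac=0.02)
        expected = sw_best_score(
            q, s, scheme.match, scheme.mismatch, scheme.gap_open, scheme.gap_extend
        )
        blocks = align_local(q, s, scheme, both_strands=False, min_block_score=1)
        got = blocks[0].score if blocks else 0
        assert got == expected


def test_blocks_do_not_overlap(rng):
    gene = random_seq(rng, 400)
    # two "exons" of the gene spliced around an unrelated linker
    subject = gene[:150] + random_seq(rng, 200) + gene[250:]
    blocks = align_local(gene, subject, HOMOLOGY_SCHEME)
    assert len(blocks) >= 2
    spans = sorted((b.s_start, b.s_end) for b in blocks)
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        assert a1 <= b0
    assert blocks == sorted(blocks, key=lambda b: -b.score)


def test_invalid_scheme_rejected():
    with pytest.raises(ConfigurationError):
        ScoringScheme(match=0)
    with pytest.raises(ConfigurationError):
        ScoringScheme(mismatch=3)


class TestMapRead:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.r1 = ReferenceContig("R1", random_seq(rng, 500))
        self.r2 = ReferenceContig("R2", random_seq(rng, 500))
        self.rng = rng

    def test_exact_substring_maps_uniquely(self):
        res = map_read(self.r1.sequence[100:300], [self.r1, self.r2])
        assert res.unique and res.subject_id == "R1"
        assert res.best_score == 200

    def test_repeated_gene_tie_is_unassigned(self):
        dup = ReferenceContig("R9", self.r1.sequence)
        res = map_read(self.r1.sequence[100:300], [self.r1, self.r2, dup])
        assert not res.unique
        assert res.best_score == res.second_score == 200
        assert res.subject_id == "R1"  # lexicographically first of the tie

    def test_diverged_subgenome_read_falls_below_floor(self):
        # ~80% identity: every 5th base substituted; -10 mismatch sinks it
        read = list(self.r1.sequence[100:300])
        for p in range(0, 200, 5):
            read[p] = "ACGT"[("ACGT".index(read[p]) + 1) % 4]
        res = map_read("".join(read), [self.r1, self.r2])
        assert not res.unique
        assert res.best_score < 0.6 * 200


def test_map_library_agrees_with_exact_per_read_mapping(tiny_exp):
    """The banded bulk mapper must reproduce full-DP mapping decisions."""
    from allosilence.qc import qc_library

    index = ReferenceIndex(tiny_exp.genes)
    lib, _ = qc_library(tiny_exp.parent_libraries[0])
    n = 150
    sub = ReadLibrary(
        "sub",
        "parent",
        lib.seq[: lib.offsets[n]],
        lib.qual[: lib.offsets[n]],
        lib.offsets[: n + 1],
    )
    mapping = index.map_library(sub)
    for i in range(n):
        _, seq, _ = sub.get(i)
        exact = map_read(seq, index)
        fast_id = index.ids[mapping.assigned[i]] if mapping.assigned[i] >= 0 else None
        assert fast_id == (exact.subject_id if exact.unique else None)
        if exact.unique:
            assert mapping.best_score[i] == exact.best_score


def test_reference_index_requires_unique_ids():
    c = ReferenceContig("X", "ACGTACGTACGTACGTACGT")
    with pytest.raises(ConfigurationError):
        ReferenceIndex([c, c])
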