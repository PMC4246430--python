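"""Mismatch-tolerant matcher vs an all-pairs Hamming oracle, plus counting."""

import numpy as np
import pandas as pd
import pytest

from sagesac.read_processing import Read
from sagesac.tag_alignment import (
    MULTI,
    UNIQUE,
    UNMAPPED,
    Assignment,
    TagMatcher,
    count_assignments,
)

from conftest import make_count_matrix


def brute_force_match(read, tags, genes, n_max=2, e_max=70, m_max=10):
    """Independent oracle: score every reference tag, apply stratum rules."""
    hits = []
    for idx, tag in enumerate(tags):
        mm_pos = [i for i in range(len(tag)) if read.sequence[i] != tag[i]]
        if len(mm_pos) > n_max:
            continue
        qsum = sum(read.qualities[i] for i in mm_pos)
        if qsum <= e_max:
            hits.append((len(mm_pos), qsum, idx))
    if not hits or len(hits) > m_max:
        return Assignment(read.id, UNMAPPED)
    best = min(hits)
    ties = [h for h in hits if h[:2] == best[:2]]
    if len(ties) > 1:
        return Assignment(read.id, MULTI, mismatches=best[0])
    return Assignment(read.id, UNIQUE, genes[best[2]], best[0])


def random_tags(rng, n):
    tags, seen = [], set()
    while len(tags) < n:
        t = "CATG" + "".join(rng.choice(list("ACGT"), 19))
        if t not in seen:
            seen.add(t)
            tags.append(t)
    return tags


@pytest.fixture(scope="module")
def matcher_fixture():
    rng = np.random.default_rng(5)
    tags = random_tags(rng, 300)
    genes = [f"g{i}" for i in range(len(tags))]
    return rng, tags, genes, TagMatcher(tags, genes)


class TestMatchRead:
    def test_exact_match_unique(self, matcher_fixture):
        _, tags, genes, matcher = matcher_fixture
        read = Read("r", tags[17], (30,) * 23)
        a = matcher.match_read(read)
        assert a == Assignment("r", UNIQUE, genes[17], 0)

    def test_three_mismatches_unmapped(self, matcher_fixture):
        _, tags, _, matcher = matcher_fixture
        seq = list(tags[0])
        for i in (5, 10, 15):
            seq[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[i]]
        # mutate until distance >=3 from every tag (rare to need retries)
        read = Read("r", "".join(seq), (30,) * 23)
        oracle = brute_force_match(read, tags, list(range(len(tags))))
        a = matcher.match_read(read)
        assert a.status == oracle.status

    def test_quality_sum_gate(self, matcher_fixture):
        _, tags, genes, matcher = matcher_fixture
        seq = list(tags[3])
        seq[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[10]]
        quals = [30] * 23
        quals[10] = 71  # exceeds the 70 mismatch-quality budget
        a = matcher.match_read(Read("r", "".join(seq), tuple(quals)))
        oracle = brute_force_match(Read("r", "".join(seq), tuple(quals)), tags, genes)
        assert a == oracle
        assert a.status == UNMAPPED

    def test_wrong_length_rejected(self, matcher_fixture):
        *_, matcher = matcher_fixture
        with pytest.raises(ValueError):
            matcher.match_read(Read("r", "ACGT", (30,) * 4))

    def test_oracle_equivalence_randomized(self, matcher_fixture):
        """2,000 reads (exact copies, 1-3 planted errors, random junk)
        assigned identically to the brute-force all-pairs scan."""
        rng, tags, genes, matcher = matcher_fixture
        reads = []
        for i in range(2000):
            kind = i % 4
            if kind == 3:
                seq = "".join(rng.choice(list("ACGT"), 23))
            else:
                seq = list(tags[rng.integers(len(tags))])
                for pos in rng.choice(23, size=kind, replace=False):
                    seq[pos] = "ACGT"[rng.integers(4)]
                seq = "".join(seq)
            quals = tuple(int(q) for q in rng.integers(2, 41, 23))
            reads.append(Read(f"r{i}", seq, quals))
        for read in reads:
            assert matcher.match_read(read) == brute_force_match(read, tags, genes)


class TestCounting:
    def test_simple_tabulation(self):
        meta = pd.DataFrame(
            {"sample_id": ["s1", "s2"], "day": ["E13", "E13"],
             "replicate": [1, 2]}
        ).set_index("sample_id")
        assigns = {
            "s1": [Assignment("a", UNIQUE, "gA", 0)] * 3
            + [Assignment("b", MULTI), Assignment("c", UNMAPPED)],
            "s2": [Assignment("d", UNIQUE, "gB", 1)],
        }
        cm, stats = count_assignments(assigns, meta, ["gA", "gB"])
        assert cm.counts.loc["gA", "s1"] == 3
        assert cm.counts.loc["gB", "s2"] == 1
        assert cm.counts.to_numpy().sum() == 4
        assert stats["s1"]["reads"] == 5
        assert stats["s1"]["unique"] + stats["s1"]["multi"] + stats["s1"]["unmapped"] == 5

    def test_all_unmapped_zero_matrix(self):
        meta = pd.DataFrame(
            {"sample_id": ["s1"], "day": ["E13"], "replicate": [1]}
        ).set_index("sample_id")
        cm, _ = count_assignments(
            {"s1": [Assignment("a", UNMAPPED)]}, meta, ["gA", "gB"]
        )
        assert cm.counts.shape == (2, 1) and (cm.counts == 0).all().all()

    def test_unknown_sample_rejected(self):
        meta = pd.DataFrame(
            {"sample_id": ["s1"], "day": ["E13"], "replicate": [1]}
        ).set_index("sample_id")
        with pytest.raises(ValueError):
            count_assignments({"sX": []}, meta, ["gA"])

    def test_zero_error_simulation_recovers_counts(self, small_dataset):
        """epsilon=0 reads re-counted through the matcher reproduce the
        generating count matrix exactly."""
        ds = small_dataset
        matcher = TagMatcher.from_reference(ds.reference)
        # trim simulated 50-mers to tag length first
        from sagesac.read_processing import trim_read

        assigns = {
            s: matcher.match_all([trim_read(r) for r in reads])
            for s, reads in ds.reads.items()
        }
        cm, stats = count_assignments(
            assigns, ds.true_counts.metadata, ds.reference.retained_genes
        )
        pd.testing.assert_frame_equal(cm.counts, ds.true_counts.counts)

    def test_count_matrix_subset_and_drop(self):
        cm = make_count_matrix(
            [[1, 2, 3], [4, 5, 6]], ["E13", "E13", "E15"]
        )
        sub = cm.subset_genes(["g1"])
        assert sub.counts.shape == (1, 3)
        dropped = cm.drop_samples([cm.samples[0]])
        assert dropped.counts.shape == (2, 2)
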