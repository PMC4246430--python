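"""Anchor finding, tag extraction and reference filtering, checked against
brute-force enumeration on randomized transcripts."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sagesac.synthetic_data import SimulationConfig, simulate_transcriptome
from sagesac.tag_reference import (
    AMBIGUOUS,
    NO_ANCHOR,
    REDUNDANT,
    RETAINED,
    TOO_SHORT,
    Transcript,
    build_tag_reference,
    extract_tag,
    find_anchor,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


def brute_force_anchor(sequence: str, motif: str):
    hits = [
        i
        for i in range(len(sequence) - len(motif) + 1)
        if sequence[i : i + len(motif)] == motif
    ]
    return max(hits) if hits else None


class TestFindAnchor:
    @pytest.mark.parametrize(
        "seq,motif,expected",
        [
            ("AACATGTTCATGGG", "CATG", 8),
            ("AAAA", "CATG", None),
            ("CATG", "CATG", 0),
            ("CANTG", "CATG", None),  # N never matches
        ],
    )
    def test_examples(self, seq, motif, expected):
        assert find_anchor(seq, motif) == expected

    def test_rejects_non_dna(self):
        with pytest.raises(ValueError):
            find_anchor("ACGU", "CATG")
        with pytest.raises(ValueError):
            find_anchor("", "CATG")

    @settings(max_examples=200, deadline=None)
    @given(dna)
    def test_matches_brute_force(self, seq):
        assert find_anchor(seq, "CATG") == brute_force_anchor(seq, "CATG")


class TestExtractTag:
    def test_mid_sequence_slice(self):
        seq = "A" * 7 + "CATG" + "G" * 19  # length 30, anchor at 7
        assert extract_tag(seq, 7) == seq[7:30]

    def test_too_short_tail(self):
        seq = "A" * 25
        assert extract_tag(seq, 10) is None  # 15 bases remain < 23

    def test_exact_boundary(self):
        seq = "CATG" + "T" * 19
        assert extract_tag(seq, 0) == seq

    def test_out_of_range(self):
        with pytest.raises(IndexError):
            extract_tag("ACGT", 10)


class TestBuildReference:
    def test_five_transcript_fixture(self):
        """Hand-enumerated statuses: duplicate pair, no anchor, short, clean."""
        shared_tail = "ACGTACGTACGTACGTACG"
        dup_tag = "CATG" + shared_tail
        transcripts = [
            Transcript("dup1", "TTTT" + dup_tag),
            Transcript("dup2", "GGGG" + dup_tag),
            Transcript("noanchor", "ATTGATTGATTG"),
            Transcript("short", "TTTTTTCATGAAAA"),  # 10 bases from anchor
            Transcript("clean", "TTTT" + "CATG" + "TTCCTTCCTTCCTTCCTTC"),
        ]
        ref = build_tag_reference(transcripts)
        statuses = {e.gene_id: e.status for e in ref.entries}
        assert statuses == {
            "dup1": REDUNDANT,
            "dup2": REDUNDANT,
            "noanchor": NO_ANCHOR,
            "short": TOO_SHORT,
            "clean": RETAINED,
        }
        assert len(ref.tag_index) == 1
        assert ref.tag_index["CATG" + "TTCCTTCCTTCCTTCCTTC"] == "clean"

    def test_retained_tags_start_with_motif_and_unique(self, small_dataset):
        tags = [e.tag for e in small_dataset.reference.entries if e.status == RETAINED]
        assert all(t.startswith("CATG") and len(t) == 23 for t in tags)
        assert len(set(tags)) == len(tags)

    def test_empty_input(self):
        ref = build_tag_reference([])
        assert ref.entries == [] and ref.tag_index == {}

    def test_duplicate_ids_rejected(self):
        t = Transcript("x", "CATG" + "A" * 19)
        with pytest.raises(ValueError):
            build_tag_reference([t, t])

    def test_ambiguous_base_in_tag(self):
        t = Transcript("n", "TT" + "CATG" + "AAAN" + "C" * 15)
        ref = build_tag_reference([t])
        assert ref.entries[0].status == AMBIGUOUS

    def test_brute_force_oracle_500_random(self):
        """Statuses and index match independent flat-table enumeration on
        500 planted-structure transcripts."""
        cfg = SimulationConfig(
            n_genes=500, frac_no_anchor=0.12, frac_too_short=0.1,
            frac_duplicate=0.14, frac_ambiguous=0.04, seed=7,
        )
        transcripts, expected = simulate_transcriptome(cfg)
        ref = build_tag_reference(transcripts)

        # independent oracle: scan every motif position, slice, count tags
        oracle = {}
        tag_of = {}
        for t in transcripts:
            pos = brute_force_anchor(t.sequence, "CATG")
            if pos is None:
                oracle[t.id] = NO_ANCHOR
            elif len(t.sequence) - pos < 23:
                oracle[t.id] = TOO_SHORT
            elif "N" in t.sequence[pos : pos + 23]:
                oracle[t.id] = AMBIGUOUS
            else:
                tag_of[t.id] = t.sequence[pos : pos + 23]
        multiplicity = Counter(tag_of.values())
        for gid, tag in tag_of.items():
            oracle[gid] = REDUNDANT if multiplicity[tag] > 1 else RETAINED

        got = {e.gene_id: e.status for e in ref.entries}
        assert got == oracle
        assert got == dict(expected)  # generator bookkeeping agrees too
        assert set(ref.tag_index.values()) == {
            g for g, s in oracle.items() if s == RETAINED
        }

    def test_determinism(self):
        cfg = SimulationConfig(n_genes=50, seed=9)
        t1, _ = simulate_transcriptome(cfg)
        t2, _ = simulate_transcriptome(cfg)
        r1, r2 = build_tag_reference(t1), build_tag_reference(t2)
        assert [(e.gene_id, e.status, e.tag) for e in r1.entries] == [
            (e.gene_id, e.status, e.tag) for e in r2.entries
        ]

    def test_adding_transcript_monotonicity(self):
        """A new transcript can only demote retained -> redundant."""
        base = [
            Transcript("a", "TT" + "CATG" + "A" * 19),
            Transcript("b", "TT" + "CATG" + "C" * 19),
        ]
        before = {e.gene_id: e.status for e in build_tag_reference(base).entries}
        extra = Transcript("c", "GG" + "CATG" + "A" * 19)  # duplicates a's tag
        after = {
            e.gene_id: e.status
            for e in build_tag_reference(base + [extra]).entries
        }
        assert before == {"a": RETAINED, "b": RETAINED}
        assert after["a"] == REDUNDANT and after["b"] == RETAINED

    def test_tsv_round_trip(self, tmp_path, small_dataset):
        ref = small_dataset.reference
        path = tmp_path / "ref.tags.tsv"
        ref.to_tsv(path)
        back = type(ref).from_tsv(path)
        assert back.tag_index == ref.tag_index
        assert [(e.gene_id, e.status) for e in back.entries] == [
            (e.gene_id, e.status) for e in ref.entries
        ]
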