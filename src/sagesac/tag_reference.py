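"""Restriction-anchored SAGE tag reference construction.

SOLiD-SAGE tags are sequenced from the 3'-most NlaIII site (CATG) of each
transcript: EcoP15I cuts 27 bp downstream of the anchor and reads are
subsequently trimmed to 23 bp, so the mapped region is the 23-mer beginning
at the first base of the 3'-most CATG.  A transcript contributes a usable
tag only when (i) it carries the anchor motif, (ii) at least ``tag_length``
bases remain from the anchor start to the 3' end, (iii) the tag region
contains no ambiguous base, and (iv) the resulting 23-mer is unique among
all transcripts.  Transcripts failing (iv) are *all* excluded (a shared tag
cannot be attributed to a single mRNA).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

# Transcript / entry statuses, in reporting order.
RETAINED = "retained"
NO_ANCHOR = "no_anchor"
TOO_SHORT = "too_short"
AMBIGUOUS = "ambiguous_base"
REDUNDANT = "redundant"
STATUSES = (RETAINED, NO_ANCHOR, TOO_SHORT, AMBIGUOUS, REDUNDANT)

DEFAULT_MOTIF = "CATG"
DEFAULT_TAG_LENGTH = 23


@dataclass(frozen=True)
class Transcript:
    """A reference mRNA sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"transcript {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TagReferenceEntry:
    gene_id: str
    status: str
    tag: Optional[str] = None


@dataclass
class TagReference:
    """The tag-to-gene lookup plus per-transcript exclusion bookkeeping."""

    entries: list[TagReferenceEntry]
    anchor_motif: str = DEFAULT_MOTIF
    tag_length: int = DEFAULT_TAG_LENGTH
    tag_index: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tag_index:
            self.tag_index = {
                e.tag: e.gene_id for e in self.entries if e.status == RETAINED
            }

    def status_counts(self) -> dict[str, int]:
        counts = {s: 0 for s in STATUSES}
        for e in self.entries:
            counts[e.status] += 1
        return counts

    @property
    def retained_genes(self) -> list[str]:
        return [e.gene_id for e in self.entries if e.status == RETAINED]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# motif={self.anchor_motif}\ttag_length={self.tag_length}\n")
            fh.write("gene_id\tstatus\ttag\n")
            for e in self.entries:
                fh.write(f"{e.gene_id}\t{e.status}\t{e.tag or '.'}\n")

    @classmethod
    def from_tsv(cls, path) -> "TagReference":
        motif, tag_length = DEFAULT_MOTIF, DEFAULT_TAG_LENGTH
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for part in line[1:].split("\t"):
                        key, _, val = part.strip().partition("=")
                        if key == "motif":
                            motif = val
                        elif key == "tag_length":
                            tag_length = int(val)
                    continue
                if not line or line.startswith("gene_id\t"):
                    continue
                gene_id, status, tag = line.split("\t")
                entries.append(
                    TagReferenceEntry(gene_id, status, None if tag == "." else tag)
                )
        return cls(entries, anchor_motif=motif, tag_length=tag_length)


def find_anchor(sequence: str, motif: str = DEFAULT_MOTIF) -> Optional[int]:
    """0-based start of the 3'-most occurrence of ``motif``, or ``None``.

    ``N`` never matches the motif.  Non-DNA characters are rejected.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not motif:
        raise ValueError("empty motif")
    sequence = sequence.upper()
    bad = set(sequence) - VALID_BASES
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    pos = sequence.rfind(motif.upper())
    return pos if pos >= 0 else None


def extract_tag(
    sequence: str, anchor_pos: int, tag_length: int = DEFAULT_TAG_LENGTH
) -> Optional[str]:
    """The ``tag_length``-mer starting at ``anchor_pos``, or ``None`` if fewer
    than ``tag_length`` bases remain to the 3' end (too short)."""
    if not 0 <= anchor_pos < len(sequence):
        raise IndexError(f"anchor position {anchor_pos} out of range")
    if len(sequence) - anchor_pos < tag_length:
        return None
    return sequence[anchor_pos : anchor_pos + tag_length].upper()


def build_tag_reference(
    transcripts: Iterable[Transcript],
    motif: str = DEFAULT_MOTIF,
    tag_length: int = DEFAULT_TAG_LENGTH,
    include_anchor: bool = True,
) -> TagReference:
    """Assign each transcript a status and build the unique-tag index.

    ``include_anchor=False`` switches to the alternative tag coordinate in
    which the tag is the ``tag_length``-mer strictly downstream of the
    anchor motif.
    """
    transcripts = list(transcripts)
    ids = [t.id for t in transcripts]
    if len(set(ids)) != len(ids):
        dup = [g for g, c in Counter(ids).items() if c > 1]
        raise ValueError(f"duplicate transcript ids: {dup}")

    candidates: list[tuple[str, str, Optional[str]]] = []  # (gene, status, tag)
    for t in transcripts:
        pos = find_anchor(t.sequence, motif)
        if pos is None:
            candidates.append((t.id, NO_ANCHOR, None))
            continue
        start = pos if include_anchor else pos + len(motif)
        if start >= t.length or t.length - start < tag_length:
            candidates.append((t.id, TOO_SHORT, None))
            continue
        tag = t.sequence[start : start + tag_length]
        if "N" in tag:
            candidates.append((t.id, AMBIGUOUS, None))
            continue
        candidates.append((t.id, RETAINED, tag))

    tag_multiplicity = Counter(tag for _, s, tag in candidates if s == RETAINED)
    entries = []
    for gene_id, status, tag in candidates:
        if status == RETAINED and tag_multiplicity[tag] > 1:
            entries.append(TagReferenceEntry(gene_id, REDUNDANT, tag))
        else:
            entries.append(TagReferenceEntry(gene_id, status, tag))
    return TagReference(entries, anchor_motif=motif, tag_length=tag_length)


def read_fasta(path) -> list[Transcript]:
    """Load transcripts from a (wrapped or unwrapped) multi-FASTA file."""
    return [Transcript(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def build_from_fasta(path, **kwargs) -> TagReference:
    return build_tag_reference(read_fasta(path), **kwargs)
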