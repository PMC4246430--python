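"""Read trimming and quality filtering.

Tags are position-anchored (the informative 23-mer starts at base 1 of the
read), so adaptor removal reduces to fixed-length truncation.  Quality
filtering keeps a read iff it is full tag length after trimming and its
mean phred score over the retained bases meets a threshold (default 20).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DEFAULT_TAG_LENGTH = 23
DEFAULT_MIN_MEAN_Q = 20.0


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def trim_read(read: Read, target_length: int = DEFAULT_TAG_LENGTH) -> Read:
    """Truncate a read (sequence and qualities in lockstep) to its first
    ``target_length`` bases; shorter reads pass through unchanged."""
    if len(read) <= target_length:
        return read
    return Read(read.id, read.sequence[:target_length], read.qualities[:target_length])


def quality_filter(
    reads: Iterable[Read],
    min_mean_q: float = DEFAULT_MIN_MEAN_Q,
    target_length: int = DEFAULT_TAG_LENGTH,
) -> tuple[list[Read], int]:
    """Keep reads of exactly ``target_length`` whose mean phred score is at
    least ``min_mean_q``.  Returns (kept reads, discarded count)."""
    kept, discarded = [], 0
    for read in reads:
        if len(read) == target_length and _mean(read.qualities) >= min_mean_q:
            kept.append(read)
        else:
            discarded += 1
    return kept, discarded


def preprocess(
    reads: Iterable[Read],
    target_length: int = DEFAULT_TAG_LENGTH,
    min_mean_q: float = DEFAULT_MIN_MEAN_Q,
) -> tuple[list[Read], dict]:
    """Trim then quality-filter; returns kept reads and a summary dict."""
    trimmed = [trim_read(r, target_length) for r in reads]
    kept, discarded = quality_filter(trimmed, min_mean_q, target_length)
    total = len(trimmed)
    stats = {
        "reads_in": total,
        "reads_kept": len(kept),
        "reads_discarded": discarded,
        "pass_fraction": len(kept) / total if total else float("nan"),
    }
    return kept, stats


def _mean(values: Sequence[int]) -> float:
    return sum(values) / len(values) if values else 0.0


def read_fastq(path) -> Iterator[Read]:
    """Iterate reads from a Sanger phred+33 FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield Read(
            rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"])
        )


def write_fastq(reads: Iterable[Read], path) -> int:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    return SeqIO.write(records, str(path), "fastq")
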