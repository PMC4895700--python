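"""Read filtration and collapsing for small-RNA libraries.

A raw small-RNA read is an 18-24 nt insert ligated between a 5' and a 3'
adapter; only the insert plus a stretch of 3' adapter is sequenced. The
filtration cascade keeps reads that carry no ambiguous base, no 5'-adapter
sequence and no poly-A artifact, and that end in a recognisable 3'-adapter
prefix of 6-18 nt. Surviving reads are trimmed and identical inserts are
collapsed into unique tags with counts.

Checks are applied in a fixed order so every read has exactly one primary
drop reason: ambiguous -> 5' adapter -> 3'-adapter match -> poly-A (on the
trimmed insert) -> insert length.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from Bio import SeqIO

# standard Illumina small-RNA chemistry; configurable everywhere below
DEFAULT_ADAPTER_3P = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER_5P = "GTTCAGAGTTCTACAGTCCGACGATC"

DECISIONS = (
    "keep",
    "drop_polyA",
    "drop_ambiguous",
    "drop_5adapter",
    "drop_no3adapter",
    "drop_length",
)


class MalformedReadError(ValueError):
    """Raised for an empty or otherwise unusable read sequence."""


@dataclass(frozen=True)
class QCParams:
    """Tunable thresholds of the filtration cascade.

    Attributes
    ----------
    adapter_3p, adapter_5p : str
        Adapter sequences. The 3' adapter must be at least 18 nt so the
        full 6-18 nt matched-length window is observable.
    min_tail, max_tail : int
        Accepted range of the 3'-adapter matched length (nt).
    min_len, max_len : int
        Insert length bounds after trimming. Wider than the canonical
        18-24 nt mature range to keep a margin for border species.
    polya_run : int
        A trimmed insert ending in at least this many consecutive A is
        called a poly-A artifact.
    polya_frac : float
        ... as is an insert whose overall A fraction reaches this value.
    adapter5_k : int
        A read containing any exact substring of the 5' adapter of this
        length is called an adapter dimer.
    """

    adapter_3p: str = DEFAULT_ADAPTER_3P
    adapter_5p: str = DEFAULT_ADAPTER_5P
    min_tail: int = 6
    max_tail: int = 18
    min_len: int = 16
    max_len: int = 27
    polya_run: int = 6
    polya_frac: float = 0.8
    adapter5_k: int = 10

    def __post_init__(self) -> None:
        if len(self.adapter_3p) < self.max_tail:
            raise ValueError("3' adapter shorter than max_tail")
        if not (1 <= self.min_tail <= self.max_tail):
            raise ValueError("invalid adapter tail range")


@dataclass(frozen=True)
class RawRead:
    read_id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise MalformedReadError(f"empty sequence for read {self.read_id!r}")
        if len(self.seq) != len(self.qual):
            raise MalformedReadError(
                f"sequence/quality length mismatch for read {self.read_id!r}"
            )


@dataclass(frozen=True)
class CleanTag:
    """A unique insert sequence with its collapsed read count."""

    insert_seq: str
    count: int


@dataclass
class QCReport:
    """Per-decision read counters; they sum to the total input reads."""

    counts: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {d: int(self.counts.get(d, 0)) for d in DECISIONS}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"total": self.total, **self.to_dict()}, fh, indent=2)
            fh.write("\n")


def trim_3adapter(
    seq: str, adapter_3p: str = DEFAULT_ADAPTER_3P, min_match: int = 1
) -> tuple[str, int]:
    """Strip the longest 3'-adapter prefix found at the read's 3' end.

    Returns ``(insert, matched_len)`` where ``matched_len`` is the length of
    the longest prefix of ``adapter_3p`` that occurs as a suffix of ``seq``
    (exact match); 0 when no prefix of at least ``min_match`` nt matches, in
    which case the insert is the whole read.
    """
    if not seq:
        raise MalformedReadError("empty sequence")
    for k in range(min(len(adapter_3p), len(seq)), min_match - 1, -1):
        if seq.endswith(adapter_3p[:k]):
            return seq[: len(seq) - k], k
    return seq, 0


def is_polya(insert: str, run: int = 6, frac: float = 0.8) -> bool:
    if not insert:
        return False
    if insert.endswith("A" * run):
        return True
    return insert.count("A") / len(insert) >= frac


def _has_5adapter(seq: str, adapter_5p: str, k: int) -> bool:
    if len(adapter_5p) < k:
        return adapter_5p in seq if adapter_5p else False
    return any(adapter_5p[i : i + k] in seq for i in range(len(adapter_5p) - k + 1))


def classify_read(read: RawRead, params: QCParams = QCParams()) -> tuple[str, str | None]:
    """Assign a read its single primary QC decision.

    Returns ``(decision, insert)``; ``insert`` is the trimmed insert for
    ``keep`` decisions and ``None`` otherwise.
    """
    seq = read.seq
    if "N" in seq:
        return "drop_ambiguous", None
    if _has_5adapter(seq, params.adapter_5p, params.adapter5_k):
        return "drop_5adapter", None
    insert, matched = trim_3adapter(seq, params.adapter_3p)
    if not (params.min_tail <= matched <= params.max_tail):
        return "drop_no3adapter", None
    if is_polya(insert, params.polya_run, params.polya_frac):
        return "drop_polyA", None
    if not (params.min_len <= len(insert) <= params.max_len):
        return "drop_length", None
    return "keep", insert


def collapse(inserts: Iterable[str]) -> list[CleanTag]:
    """Collapse identical insert sequences to unique tags.

    Output is sorted by descending count, ties broken lexicographically;
    counts sum to the number of input inserts.
    """
    counts = Counter(inserts)
    return [
        CleanTag(seq, n)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def process_reads(
    reads: Iterable[RawRead], params: QCParams = QCParams()
) -> tuple[list[CleanTag], QCReport]:
    """Run the full cascade over a library and collapse the survivors."""
    report = QCReport()
    kept: list[str] = []
    for read in reads:
        decision, insert = classify_read(read, params)
        report.counts[decision] += 1
        if decision == "keep":
            kept.append(insert)  # type: ignore[arg-type]
    return collapse(kept), report


def read_fastq(path) -> Iterator[RawRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        yield RawRead(rec.id, str(rec.seq), qual)


def process_fastq(path, params: QCParams = QCParams()) -> tuple[list[CleanTag], QCReport]:
    return process_reads(read_fastq(path), params)


def write_tags_fasta(tags: list[CleanTag], path) -> None:
    """Write collapsed tags in the ``tag{serial}_x{count}`` FASTA dialect."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, start=1):
            fh.write(f">tag{i}_x{tag.count}\n{tag.insert_seq}\n")


def read_tags_fasta(path) -> list[CleanTag]:
    tags = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = int(rec.id.rsplit("_x", 1)[1])
        tags.append(CleanTag(str(rec.seq), count))
    return tags
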