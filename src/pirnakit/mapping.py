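"""Adapter trimming and exact 0/1-mismatch small-RNA read placement.

Small-RNA reads are sequenced past their 3' end into the library adapter, so
the first processing step truncates each read at the adapter junction.  Reads
are then placed on a (desk-scale) reference collection on both strands,
allowing at most one substitution; every placement is reported so that
downstream steps can either drop multi-mappers (the convention for 23-29 nt
piRNA analyses) or weight them 1/n for whole-library size distributions.

Coordinates are 0-based half-open on the forward reference throughout.  A
minus-strand hit is a placement of the reverse complement of the read; its 5'
end is therefore its highest coordinate (``end - 1``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAG"
DEFAULT_MIN_ADAPTER_MATCH = 6


@dataclass(frozen=True)
class SmallRNARead:
    """One sequenced small-RNA molecule."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class AlignmentHit:
    """Placement of a read on a reference (0-based half-open, <=1 mismatch)."""

    read_id: str
    reference: str
    start: int
    end: int
    strand: str
    mismatches: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError("invalid interval")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.mismatches <= 1:
            raise ValueError("mismatches must be 0 or 1")

    @property
    def read_length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """5'-end coordinate: ``start`` on the plus strand, ``end - 1`` on minus."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class MappingResult:
    """All placements plus the count of N-containing reads that were skipped."""

    hits: tuple[AlignmentHit, ...]
    n_reads: int
    n_skipped_with_n: int

    def placements_per_read(self) -> Counter:
        return Counter(h.read_id for h in self.hits)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def trim_adapter(
    read: SmallRNARead,
    adapter: str = DEFAULT_ADAPTER,
    min_match: int = DEFAULT_MIN_ADAPTER_MATCH,
) -> SmallRNARead:
    """Truncate ``read`` at the leftmost adapter match.

    A match at position ``i`` means ``read.seq[i:]`` starts with a prefix of
    ``adapter`` of length >= ``min_match``, or contains the full adapter when
    fewer than ``min_match`` bases remain of it.  If no position matches the
    read is returned unchanged.  Idempotent: the trimmed insert can only match
    again if it genuinely contains an adapter prefix.
    """
    if min_match < 1:
        raise ValueError("min_match must be >= 1")
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.seq
    full = adapter
    for i in range(len(seq)):
        k = min(len(full), len(seq) - i)
        if k >= min_match or k == len(full):
            if seq[i : i + k] == full[:k]:
                return SmallRNARead(read.id, seq[:i]) if i > 0 else _empty_guard(read)
    return read


def _empty_guard(read: SmallRNARead) -> SmallRNARead:
    # An adapter match at position 0 would leave an empty insert; keep a
    # 0-length sentinel illegal and surface it as an error instead.
    raise ValueError(f"read {read.id!r} is adapter-only (no insert)")


def trim_library(
    reads: Iterable[SmallRNARead],
    adapter: str = DEFAULT_ADAPTER,
    min_match: int = DEFAULT_MIN_ADAPTER_MATCH,
) -> list[SmallRNARead]:
    """Trim every read, silently dropping adapter-only reads."""
    out = []
    for r in reads:
        try:
            out.append(trim_adapter(r, adapter, min_match))
        except ValueError:
            continue
    return out


def _hamming_at_most(a: str, b: str, limit: int) -> int:
    """Hamming distance of equal-length strings, or ``limit + 1`` if exceeded."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def _candidate_starts(query: str, ref: str, max_mm: int) -> list[int]:
    """Exact candidate generation by pigeonhole seeding.

    With <= 1 substitution at least one half of the read matches exactly, so
    locating both halves with ``str.find`` enumerates every possible start.
    """
    L = len(query)
    if L > len(ref):
        return []
    if max_mm == 0:
        seeds = [(query, 0)]
    else:
        h = L // 2
        seeds = [(query[:h], 0), (query[h:], h)]
    cands: set[int] = set()
    for seed, offset in seeds:
        i = ref.find(seed)
        while i != -1:
            start = i - offset
            if 0 <= start <= len(ref) - L:
                cands.add(start)
            i = ref.find(seed, i + 1)
    return sorted(cands)


def map_reads(
    reads: Iterable[SmallRNARead],
    references: Mapping[str, str],
    max_mismatches: int = 0,
) -> MappingResult:
    """Report every placement of every read on either strand.

    Substitutions only (no indels), at most ``max_mismatches`` (0 or 1).
    Reads containing N are skipped and counted, never errors.
    """
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    if not references:
        raise ValueError("reference collection is empty")
    hits: list[AlignmentHit] = []
    n_reads = 0
    n_skipped = 0
    for read in reads:
        n_reads += 1
        if "N" in read.seq:
            n_skipped += 1
            continue
        L = len(read.seq)
        for strand, query in (("+", read.seq), ("-", revcomp(read.seq))):
            for ref_name, ref_seq in references.items():
                for start in _candidate_starts(query, ref_seq, max_mismatches):
                    mm = _hamming_at_most(query, ref_seq[start : start + L], max_mismatches)
                    if mm <= max_mismatches:
                        hits.append(
                            AlignmentHit(read.id, ref_name, start, start + L, strand, mm)
                        )
    return MappingResult(tuple(hits), n_reads, n_skipped)


def filter_by_length(
    hits: Iterable[AlignmentHit], min_nt: int, max_nt: int
) -> list[AlignmentHit]:
    """Retain hits whose read length lies in ``[min_nt, max_nt]`` (inclusive)."""
    if min_nt > max_nt:
        raise ValueError("min_nt must be <= max_nt")
    return [h for h in hits if min_nt <= h.read_length <= max_nt]


def unique_mappers(hits: Sequence[AlignmentHit]) -> list[AlignmentHit]:
    """Retain hits of reads with exactly one placement in the reference set.

    Both strands and all references count toward the placement total, so reads
    from a tandem repeat (one hit per copy) are removed entirely.
    """
    n_placements = Counter(h.read_id for h in hits)
    return [h for h in hits if n_placements[h.read_id] == 1]


def multimapper_weights(hits: Sequence[AlignmentHit]) -> dict[str, float]:
    """Per-read weight ``1 / n_placements`` for whole-library distributions."""
    n_placements = Counter(h.read_id for h in hits)
    return {rid: 1.0 / n for rid, n in n_placements.items()}


# ---------------------------------------------------------------------------
# I/O


def read_fastq(path: str | Path) -> list[SmallRNARead]:
    return [SmallRNARead(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: Iterable[SmallRNARead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(references: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in references.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


HIT_COLUMNS = ["read_id", "reference", "start", "end", "strand", "mismatches"]


def hits_to_frame(hits: Sequence[AlignmentHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.read_id, h.reference, h.start, h.end, h.strand, h.mismatches) for h in hits],
        columns=HIT_COLUMNS,
    )


def frame_to_hits(frame: pd.DataFrame) -> list[AlignmentHit]:
    return [
        AlignmentHit(r.read_id, r.reference, int(r.start), int(r.end), r.strand, int(r.mismatches))
        for r in frame.itertuples(index=False)
    ]


def write_hits(hits: Sequence[AlignmentHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits(path: str | Path) -> list[AlignmentHit]:
    return frame_to_hits(pd.read_csv(path, sep="\t"))
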