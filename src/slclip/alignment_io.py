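"""Reference-oriented access to transcriptomic SAM/BAM alignments.

Each primary alignment is exposed as an :class:`AlignedRead` whose sequence
and qualities are in *reference* orientation (pysam already stores SEQ/QUAL
of reverse-strand records reverse-complemented into that orientation), with
the two soft-clips named relative to the reference: ``clip5`` abuts the
alignment start, ``clip3`` the alignment end.  A read that mapped to the
reverse strand of a transcript reference is an *antisense* read (first-strand
cDNA), which is how the strand origin of a direct-cDNA read is determined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pysam

log = logging.getLogger(__name__)

_OP_SOFT = 4
_OP_HARD = 5


@dataclass
class AlignedRead:
    """One reference-oriented primary alignment with its soft-clips."""

    read_id: str
    ref_id: str
    is_antisense: bool
    ref_start: int   # 0-based inclusive
    ref_end: int     # 0-based exclusive
    seq: str         # full read sequence, reference orientation
    quals: np.ndarray  # PHRED array, same length/orientation as seq
    clip5_len: int
    clip3_len: int

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.quals):
            raise ValueError("sequence/quality length mismatch")
        if not self.ref_start < self.ref_end:
            raise ValueError("require ref_start < ref_end")

    @property
    def aligned_len(self) -> int:
        return len(self.seq) - self.clip5_len - self.clip3_len

    def aligned_prefix(self, n: int) -> str:
        """First ``n`` aligned read bases in reference orientation."""
        return self.seq[self.clip5_len : self.clip5_len + min(n, self.aligned_len)]


@dataclass
class FilterPolicy:
    """Which records :func:`load_alignments` emits."""

    primary_only: bool = True
    min_mapq: int = 0  # the source protocol applies no MAPQ filter by default


@dataclass
class LoadStats:
    emitted: int = 0
    skipped_unmapped: int = 0
    skipped_secondary: int = 0
    skipped_supplementary: int = 0
    skipped_no_quality: int = 0
    skipped_hard_clipped: int = 0
    skipped_mapq: int = 0

    @property
    def total(self) -> int:
        return (self.emitted + self.skipped_unmapped + self.skipped_secondary
                + self.skipped_supplementary + self.skipped_no_quality
                + self.skipped_hard_clipped + self.skipped_mapq)


def _clips(cigartuples) -> tuple[int, int]:
    lead = cigartuples[0][1] if cigartuples and cigartuples[0][0] == _OP_SOFT else 0
    trail = cigartuples[-1][1] if cigartuples and cigartuples[-1][0] == _OP_SOFT else 0
    return lead, trail


def record_to_read(rec: pysam.AlignedSegment) -> AlignedRead:
    """Convert a mapped pysam record into a reference-oriented AlignedRead."""
    # SEQ/QUAL in a SAM record are stored in reference orientation, so the
    # leading soft-clip is always the reference-5' clip regardless of strand.
    clip5, clip3 = _clips(rec.cigartuples)
    return AlignedRead(
        read_id=rec.query_name,
        ref_id=rec.reference_name,
        is_antisense=rec.is_reverse,
        ref_start=rec.reference_start,
        ref_end=rec.reference_end,
        seq=rec.query_sequence,
        quals=np.asarray(rec.query_qualities, dtype=np.int16),
        clip5_len=clip5,
        clip3_len=clip3,
    )


def load_alignments(
    path,
    policy: FilterPolicy = FilterPolicy(),
    stats: LoadStats | None = None,
) -> Iterator[AlignedRead]:
    """Stream primary alignments from a SAM/BAM file as AlignedReads.

    Secondary/supplementary and unmapped records are dropped (and counted in
    ``stats``); hard-clipped primaries are rejected with a warning because
    soft-clip mining needs the full sequence; records without a quality
    string are skipped and counted.
    """
    stats = stats if stats is not None else LoadStats()
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                stats.skipped_unmapped += 1
                continue
            if rec.is_secondary:
                stats.skipped_secondary += 1
                continue
            if rec.is_supplementary:
                stats.skipped_supplementary += 1
                continue
            if policy.min_mapq and rec.mapping_quality < policy.min_mapq:
                stats.skipped_mapq += 1
                continue
            if any(op == _OP_HARD for op, _ in rec.cigartuples):
                log.warning("hard-clipped primary %s skipped (full sequence required)",
                            rec.query_name)
                stats.skipped_hard_clipped += 1
                continue
            if rec.query_qualities is None or rec.query_sequence is None:
                stats.skipped_no_quality += 1
                continue
            stats.emitted += 1
            yield record_to_read(rec)


def extract_upstream_window(
    read: AlignedRead, max_len: int = 100
) -> tuple[str, np.ndarray]:
    """Soft-clip bases directly upstream of the alignment start.

    Returns the last ``min(clip5_len, max_len)`` bases of the reference-5'
    soft-clip (and their qualities): the window's final base abuts the
    alignment start, i.e. a match ending at the window end has offset 0 from
    the alignment start.  An empty window is valid.
    """
    n = min(read.clip5_len, max_len)
    if n == 0:
        return "", read.quals[:0]
    start = read.clip5_len - n
    return read.seq[start : read.clip5_len], read.quals[start : read.clip5_len]
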