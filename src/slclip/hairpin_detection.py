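"""Endogenous 5' terminal hairpin calling.

Non-trans-spliced mRNAs can start with a short self-complementary stem that
self-primes second-strand synthesis the same way a spliced leader does.  On
an antisense read with no SL detected, the stem leaves a recognizable
signature: the soft-clip bases just upstream of the alignment start are the
reverse complement of the first aligned bases of the read.

The probe spans positions -13..+2 relative to the alignment start (13
soft-clip bases + 2 aligned bases = 15 nt).  Its reverse complement is
aligned locally (gapped) against the first 30 aligned bases of the read
itself — read-side rather than reference-side, so sequencing errors affect
both sides of the comparison consistently.  The hairpin is called when at
least 12 of the 15 probe positions land on identity columns of the best
local alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._align import local_align_identity
from .alignment_io import AlignedRead
from .sl_detection import ScoringScheme

PROBE_CLIP_NT = 13     # soft-clip bases in the probe (positions -13..-1)
PROBE_ALIGNED_NT = 2   # aligned bases in the probe (positions +1..+2)
PROBE_LEN = PROBE_CLIP_NT + PROBE_ALIGNED_NT
MIN_MATCHED_NT = 12    # >= 12 of 15 identity columns validate the hairpin
TARGET_WINDOW = 30     # aligned 5' bases searched for the stem partner

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class HairpinCall:
    """Outcome of the reverse-complement stem test on one read."""

    is_hairpin: bool
    matched_nt: int                 # identity columns in the best alignment
    probe: str                      # the 15-mer (-13..+2), reference orientation
    stem_target_span: tuple[int, int]  # matched region within the aligned prefix


def extract_stem_probe(read: AlignedRead) -> str | None:
    """The -13..+2 probe of a read, or None if the 5' clip is shorter than 13.

    Caller is expected to apply this only to antisense reads with no SL
    detected, per the classification flow.
    """
    if read.clip5_len < PROBE_CLIP_NT:
        return None
    clip_part = read.seq[read.clip5_len - PROBE_CLIP_NT : read.clip5_len]
    return clip_part + read.aligned_prefix(PROBE_ALIGNED_NT)


def detect_hairpin(
    probe: str,
    read: AlignedRead,
    window_w: int = TARGET_WINDOW,
    scheme: ScoringScheme = ScoringScheme(),
    min_matched: int = MIN_MATCHED_NT,
) -> HairpinCall:
    """Reverse-complement the probe and map it against the read's own
    aligned 5' region; call a hairpin if >= ``min_matched`` of its positions
    are identity columns of the best local alignment.

    An aligned region shorter than the probe is compared as-is (matched_nt is
    bounded by what exists).
    """
    target = read.aligned_prefix(window_w)
    _, matched, j0, j1 = local_align_identity(revcomp(probe), target, scheme)
    return HairpinCall(
        is_hairpin=matched >= min_matched,
        matched_nt=matched,
        probe=probe,
        stem_target_span=(j0, j1),
    )
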