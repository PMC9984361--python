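"""Spliced-leader detection in 5' upstream soft-clip windows.

A trans-spliced read aligns to its transcript from the trans-splice acceptor
site onward, leaving the spliced leader (SL) in the 5' soft-clip.  Detection
therefore searches each SL of a repertoire against the (up to 100 nt) window
directly upstream of the alignment start using a semi-global alignment: the
SL must align end to end, the window flanks are free.

Nanopore quality frequently truncates the 5' end of the SL copy, so each SL
is retried with progressively larger 5' truncations (2 nt per step) until it
either passes the per-length detection threshold or falls below 7 nt.  The
best-scoring detection across the repertoire labels the read; best-score ties
across the SL1/SL2 families yield the ambiguity class ``SL.X`` and ties among
several SL2 variants yield ``SL2.X``.

Downstream quantification additionally requires a *confident* match: score
strictly greater than 9, or a match ending within 2 nt of the alignment
start (where real SLs sit even when badly base-called).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from ._align import semiglobal_align

#: Sentinel read classes (specific SL detections use the SL's own name).
CLASS_SLX = "SL.X"
CLASS_SL2X = "SL2.X"
CLASS_SL1X = "SL1.X"
CLASS_HAIRPIN = "endogenous_hairpin"
CLASS_UNIDENTIFIED = "unidentified"
CLASS_SENSE_UNTESTED = "sense_untested"

MIN_TRUNCATED_LEN = 7   # truncation loop stops below this query length
TRIM_STEP = 2           # nucleotides trimmed from the SL 5' end per retry
CONFIDENT_SCORE = 9     # confident iff score > 9 ...
CONFIDENT_OFFSET = 2    # ... or match ends <= 2 nt from the alignment start


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring scheme (match > 0 > mismatch, gaps <= mismatch)."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open > self.mismatch or self.gap_extend > self.mismatch:
            raise ValueError("gap penalties must be <= mismatch")


def default_threshold(length: int) -> int:
    """Detection threshold T(L) for a (possibly truncated) SL of length L.

    ``L - 4`` tolerates two substitutions at any truncation; the floor of 10
    (the confidence bound ``score > 9``) keeps short truncations from firing
    on random sequence — an unfloored budget of two mismatches on an 8-mer
    would match essentially every 100-nt window somewhere.
    """
    return max(length - 4, 10)


@dataclass(frozen=True)
class SLMatch:
    """A scored, possibly 5'-truncated SL hit in an upstream window."""

    sl_name: str
    family: str            # "SL1" or "SL2"
    score: int
    trunc: int             # nt trimmed from the SL 5' end
    matched_len: int       # SL query length actually used
    end_offset: int        # distance from match 3' end to the alignment start

    @property
    def confident(self) -> bool:
        return is_confident(self)


def is_confident(match: SLMatch) -> bool:
    """Confident-match rule: score > 9, or ends <= 2 nt from alignment start."""
    return match.score > CONFIDENT_SCORE or match.end_offset <= CONFIDENT_OFFSET


def sl_family(name: str) -> str:
    """Family of an SL by conventional naming (``SL2``/``SL2.*`` vs rest)."""
    return "SL2" if name == "SL2" or name.startswith("SL2.") else "SL1"


@dataclass
class Repertoire:
    """An SL repertoire: name -> sequence, with a family for each name."""

    sequences: dict[str, str]
    families: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if len(seq) < MIN_TRUNCATED_LEN:
                raise ValueError(f"SL {name!r} shorter than {MIN_TRUNCATED_LEN} nt")
            self.families.setdefault(name, sl_family(name))

    @classmethod
    def from_fasta(cls, path) -> "Repertoire":
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        if not seqs:
            raise ValueError(f"no SL sequences in {path}")
        if len(seqs) != len(set(seqs)):
            raise ValueError("duplicate SL names")
        return cls(seqs)

    def items(self):
        return self.sequences.items()


def detect_sl(
    window: str,
    repertoire: Repertoire,
    scheme: ScoringScheme = ScoringScheme(),
    threshold: Callable[[int], int] = default_threshold,
    exhaust_truncations: bool = False,
) -> list[SLMatch]:
    """Search every SL (with progressive 5' trimming) in an upstream window.

    For each SL the full-length query is tried first; on failure 2 nt are
    trimmed from its 5' end and the search repeats while the truncated query
    is at least 7 nt long.  By default the loop stops at the first truncation
    passing ``threshold(len)`` (set ``exhaust_truncations`` to keep the best
    passing truncation instead).  Returns the per-SL detection list, sorted
    best-first (score desc, matched_len desc, name); empty window -> [].
    """
    if not window:
        return []
    detections: list[SLMatch] = []
    for name, seq in repertoire.items():
        best: SLMatch | None = None
        trunc = 0
        while len(seq) - trunc >= MIN_TRUNCATED_LEN:
            query = seq[trunc:]
            score, target_end = semiglobal_align(query, window, scheme)
            if score >= threshold(len(query)):
                hit = SLMatch(
                    sl_name=name,
                    family=repertoire.families[name],
                    score=score,
                    trunc=trunc,
                    matched_len=len(query),
                    end_offset=len(window) - target_end,
                )
                if best is None or (hit.score, hit.matched_len) > (best.score, best.matched_len):
                    best = hit
                if not exhaust_truncations:
                    break
            trunc += TRIM_STEP
        if best is not None:
            detections.append(best)
    detections.sort(key=lambda m: (-m.score, -m.matched_len, m.sl_name))
    return detections


def classify_ambiguity(detections: Sequence[SLMatch]) -> tuple[str, SLMatch]:
    """Resolve a non-empty detection set to a read-class label.

    A unique best score names the SL directly; ties are first broken toward
    the larger matched length, and remaining ties are declared ambiguous:
    across families -> ``SL.X``, among SL2 variants -> ``SL2.X`` (and, for
    generality with multi-SL1 repertoires, ``SL1.X``).  Returns the label and
    the representative best match.
    """
    if not detections:
        raise ValueError("no detections to classify")
    best_score = max(d.score for d in detections)
    tied = [d for d in detections if d.score == best_score]
    if len(tied) > 1:
        best_len = max(d.matched_len for d in tied)
        tied = [d for d in tied if d.matched_len == best_len]
    rep = min(tied, key=lambda d: d.sl_name)
    if len(tied) == 1:
        return tied[0].sl_name, tied[0]
    families = {d.family for d in tied}
    if families == {"SL2"}:
        return CLASS_SL2X, rep
    if families == {"SL1"}:
        return CLASS_SL1X, rep
    return CLASS_SLX, rep
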