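"""Per-read 5'-end classification: SL detection, then the hairpin test.

Classification flow per primary alignment:

1. extract the upstream soft-clip window (<= 100 nt) and run SL detection;
   any detection labels the read with its best SL (or an ambiguity class).
2. otherwise, antisense reads undergo the reverse-complement stem test; a
   positive call is ``endogenous_hairpin``, a negative (or an insufficient
   <13 nt clip) is ``unidentified``.
3. SL-negative sense reads are ``sense_untested`` — the hairpin artifact
   only leaves its signature on first-strand (antisense) reads.

With ``sl1_primed=True`` (libraries primed with an SL1 oligo) sense reads
are excluded from SL counting altogether, since heterologous binding of the
primer could fabricate sense SL1 hits.
"""

from __future__ import annotations

from typing import Callable, Iterable

import pandas as pd

from .alignment_io import AlignedRead, extract_upstream_window
from .hairpin_detection import detect_hairpin, extract_stem_probe
from .sl_detection import (
    CLASS_HAIRPIN,
    CLASS_SENSE_UNTESTED,
    CLASS_SL2X,
    CLASS_SLX,
    CLASS_UNIDENTIFIED,
    Repertoire,
    ScoringScheme,
    classify_ambiguity,
    default_threshold,
    detect_sl,
    is_confident,
)

AMBIGUOUS_CLASSES = {CLASS_SLX, CLASS_SL2X, "SL1.X"}

CLASSIFICATION_COLUMNS = [
    "read_id", "ref_id", "start_pos", "is_antisense", "clip5_len",
    "read_class", "sl_name", "sl_family", "sl_score", "sl_trunc",
    "sl_end_offset", "sl_confident", "hp_matched_nt",
]


def is_sl_class(label: str) -> bool:
    return not (label in (CLASS_HAIRPIN, CLASS_UNIDENTIFIED, CLASS_SENSE_UNTESTED))


def classify_read(
    read: AlignedRead,
    repertoire: Repertoire,
    scheme: ScoringScheme = ScoringScheme(),
    threshold: Callable[[int], int] = default_threshold,
    window_len: int = 100,
    hairpin_window: int = 30,
    sl1_primed: bool = False,
) -> dict:
    """Classify one read; returns a flat record (see CLASSIFICATION_COLUMNS)."""
    row = {
        "read_id": read.read_id,
        "ref_id": read.ref_id,
        "start_pos": read.ref_start,
        "is_antisense": read.is_antisense,
        "clip5_len": read.clip5_len,
        "read_class": CLASS_UNIDENTIFIED,
        "sl_name": None, "sl_family": None, "sl_score": None,
        "sl_trunc": None, "sl_end_offset": None, "sl_confident": False,
        "hp_matched_nt": None,
    }
    if sl1_primed and not read.is_antisense:
        row["read_class"] = CLASS_SENSE_UNTESTED
        return row
    window, _ = extract_upstream_window(read, max_len=window_len)
    detections = detect_sl(window, repertoire, scheme, threshold) if window else []
    if detections:
        label, best = classify_ambiguity(detections)
        row.update(
            read_class=label,
            sl_name=best.sl_name if label not in AMBIGUOUS_CLASSES else None,
            sl_family=best.family if label not in (CLASS_SLX,) else None,
            sl_score=best.score,
            sl_trunc=best.trunc,
            sl_end_offset=best.end_offset,
            sl_confident=is_confident(best),
        )
        if label == CLASS_SL2X:
            row["sl_family"] = "SL2"
        return row
    if not read.is_antisense:
        row["read_class"] = CLASS_SENSE_UNTESTED
        return row
    probe = extract_stem_probe(read)
    if probe is None:
        return row  # unidentified: clip too short for the stem probe
    call = detect_hairpin(probe, read, window_w=hairpin_window, scheme=scheme)
    row["hp_matched_nt"] = call.matched_nt
    if call.is_hairpin:
        row["read_class"] = CLASS_HAIRPIN
    return row


def classify_reads(
    reads: Iterable[AlignedRead],
    repertoire: Repertoire,
    scheme: ScoringScheme = ScoringScheme(),
    threshold: Callable[[int], int] = default_threshold,
    window_len: int = 100,
    hairpin_window: int = 30,
    sl1_primed: bool = False,
) -> pd.DataFrame:
    """Classify a stream of reads into the per-read classification table."""
    rows = [
        classify_read(r, repertoire, scheme, threshold, window_len,
                      hairpin_window, sl1_primed)
        for r in reads
    ]
    df = pd.DataFrame(rows, columns=CLASSIFICATION_COLUMNS)
    return df
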