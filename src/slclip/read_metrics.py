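"""Per-experiment read metrics: strand bias, soft-clip sizes, quality profile.

The quality profile follows the positional-average recipe: every base of a
read gets an offset relative to the alignment start (soft-clip bases are
negative, the first aligned base is offset 0) and the mean PHRED is taken
per offset over a (seeded) sample of reads.  On hairpin-cDNA libraries this
shows the characteristic step: low-quality second-strand soft-clip on the
left, higher-quality aligned first strand on the right.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alignment_io import AlignedRead


@dataclass(frozen=True)
class StrandBias:
    n_sense: int
    n_antisense: int

    @property
    def n(self) -> int:
        return self.n_sense + self.n_antisense

    @property
    def sense_frac(self) -> float:
        return self.n_sense / self.n if self.n else float("nan")

    @property
    def antisense_frac(self) -> float:
        return self.n_antisense / self.n if self.n else float("nan")


def strand_bias(reads: Iterable[AlignedRead]) -> StrandBias:
    """Count sense vs antisense (reverse-mapped) primary alignments."""
    n_anti = n_sense = 0
    for r in reads:
        if r.is_antisense:
            n_anti += 1
        else:
            n_sense += 1
    return StrandBias(n_sense=n_sense, n_antisense=n_anti)


@dataclass(frozen=True)
class SoftclipStats:
    n: int
    median: float
    q1: float
    q3: float
    mean: float
    histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin_edges)


def softclip_stats(reads: Iterable[AlignedRead], which: str = "5",
                   bins: int = 50) -> SoftclipStats:
    """Order statistics of 5' (or 3') soft-clip lengths."""
    if which not in ("5", "3"):
        raise ValueError("which must be '5' or '3'")
    lengths = np.array([r.clip5_len if which == "5" else r.clip3_len
                        for r in reads], dtype=float)
    if lengths.size == 0:
        nan = float("nan")
        return SoftclipStats(0, nan, nan, nan, nan,
                             (np.zeros(0), np.zeros(0)))
    counts, edges = np.histogram(lengths, bins=bins)
    return SoftclipStats(
        n=int(lengths.size),
        median=float(np.median(lengths)),
        q1=float(np.percentile(lengths, 25)),
        q3=float(np.percentile(lengths, 75)),
        mean=float(lengths.mean()),
        histogram=(counts, edges),
    )


@dataclass
class QualityProfile:
    offsets: np.ndarray  # positions relative to the alignment start
    mean_q: np.ndarray   # NaN where n == 0
    n: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.offsets, "mean_q": self.mean_q,
                             "n": self.n})


def quality_profile(
    reads: Sequence[AlignedRead],
    offset_range: tuple[int, int] = (-600, 600),
    sample_n: int | None = None,
    seed: int = 0,
    antisense_only: bool = False,
) -> QualityProfile:
    """Mean base quality per position relative to the alignment start.

    Offsets run over ``offset_range`` inclusive; base offset = reference-
    oriented index - clip5_len.  When more than ``sample_n`` reads are given
    a seeded uniform subsample is profiled.
    """
    lo, hi = offset_range
    if lo > hi:
        raise ValueError("bad offset range")
    pool = [r for r in reads if not antisense_only or r.is_antisense]
    if sample_n is not None and len(pool) > sample_n:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pool), size=sample_n, replace=False)
        pool = [pool[i] for i in sorted(idx)]
    size = hi - lo + 1
    sums = np.zeros(size, dtype=float)
    counts = np.zeros(size, dtype=np.int64)
    for r in pool:
        offs = np.arange(len(r.quals)) - r.clip5_len
        ok = (offs >= lo) & (offs <= hi)
        np.add.at(sums, offs[ok] - lo, r.quals[ok])
        np.add.at(counts, offs[ok] - lo, 1)
    mean_q = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return QualityProfile(offsets=np.arange(lo, hi + 1), mean_q=mean_q,
                          n=counts)
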