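"""Pairwise alignment kernels used by SL and hairpin detection.

Two small dynamic programs, compiled with numba:

* :func:`semiglobal_align` — "glocal" alignment: the query (an SL sequence or
  a 5'-truncation of it) must be aligned end to end, while unaligned target
  flanks are free.  Used to search for spliced leaders inside the upstream
  soft-clip window.
* :func:`local_align_identity` — Smith-Waterman that additionally reports the
  number of identity columns on the best-scoring path (ties resolved toward
  more identities, then the leftmost start).  Used for the reverse-complement
  stem test of the endogenous-hairpin caller.

Gap costs are affine: a gap of length k scores ``gap_open + (k-1)*gap_extend``.
With the default scheme (+1/-1/-2/-2) this degenerates to -2 per gap base, so
detection thresholds read as mismatch budgets.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = np.int32(-(10**9))

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lowercase


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 (A,C,G,T -> 0..3, other -> 4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _semiglobal(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m, n = q.shape[0], t.shape[0]
    H = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)  # gap in query
    F = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)  # gap in target
    for j in range(n + 1):
        H[0, j] = 0  # free target prefix
    for i in range(1, m + 1):
        F[i, 0] = gap_open + (i - 1) * gap_extend
        for j in range(1, n + 1):
            s = match if (q[i - 1] == t[j - 1] and q[i - 1] < 4) else mismatch
            diag = max(H[i - 1, j - 1], E[i - 1, j - 1], F[i - 1, j - 1])
            if diag > NEG_INF:
                H[i, j] = diag + s
            e = H[i, j - 1] + gap_open
            if E[i, j - 1] + gap_extend > e:
                e = E[i, j - 1] + gap_extend
            E[i, j] = e
            f = max(H[i - 1, j], E[i - 1, j]) + gap_open
            if F[i - 1, j] + gap_extend > f:
                f = F[i - 1, j] + gap_extend
            F[i, j] = f
    best = NEG_INF
    best_j = 0
    for j in range(n + 1):
        v = max(H[m, j], F[m, j])
        if v > best:  # smallest j on ties
            best = v
            best_j = j
    return best, best_j


def semiglobal_align(query: str, target: str, scheme) -> tuple[int, int]:
    """Align `query` end-to-end against `target` with free target flanks.

    Returns ``(score, target_end)`` where ``target_end`` is the target
    coordinate just past the query's 3' end (smallest such coordinate on
    score ties).  Raises ``ValueError`` on an empty query; an empty target
    yields no alignment and must be handled by the caller.
    """
    if len(query) == 0:
        raise ValueError("empty query")
    if len(target) == 0:
        raise ValueError("empty target")
    score, j = _semiglobal(
        encode(query), encode(target),
        np.int32(scheme.match), np.int32(scheme.mismatch),
        np.int32(scheme.gap_open), np.int32(scheme.gap_extend),
    )
    return int(score), int(j)


@njit(cache=True)
def _local_ident(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m, n = q.shape[0], t.shape[0]
    # per-state (score, identities, start_j); lexicographic preference:
    # higher score, then more identities, then smaller start_j.
    Hs = np.zeros((m + 1, n + 1), dtype=np.int32)
    Hi = np.zeros((m + 1, n + 1), dtype=np.int32)
    Hj = np.zeros((m + 1, n + 1), dtype=np.int32)
    for j in range(n + 1):
        Hj[0, j] = j  # an empty alignment ending at column j starts there
    Es = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    Ei = np.zeros((m + 1, n + 1), dtype=np.int32)
    Ej = np.zeros((m + 1, n + 1), dtype=np.int32)
    Fs = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    Fi = np.zeros((m + 1, n + 1), dtype=np.int32)
    Fj = np.zeros((m + 1, n + 1), dtype=np.int32)
    best_s = np.int32(0)
    best_i = np.int32(0)
    best_j0 = np.int32(0)
    best_j1 = np.int32(0)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            is_match = q[i - 1] == t[j - 1] and q[i - 1] < 4
            s = match if is_match else mismatch
            inc = 1 if is_match else 0
            # H: diagonal from best of three states, or a fresh start
            ds, di, dj = Hs[i - 1, j - 1], Hi[i - 1, j - 1], Hj[i - 1, j - 1]
            if (Es[i - 1, j - 1] > ds or (Es[i - 1, j - 1] == ds and
               (Ei[i - 1, j - 1] > di or (Ei[i - 1, j - 1] == di and Ej[i - 1, j - 1] < dj)))):
                ds, di, dj = Es[i - 1, j - 1], Ei[i - 1, j - 1], Ej[i - 1, j - 1]
            if (Fs[i - 1, j - 1] > ds or (Fs[i - 1, j - 1] == ds and
               (Fi[i - 1, j - 1] > di or (Fi[i - 1, j - 1] == di and Fj[i - 1, j - 1] < dj)))):
                ds, di, dj = Fs[i - 1, j - 1], Fi[i - 1, j - 1], Fj[i - 1, j - 1]
            hs = ds + s
            hi = di + inc
            hj = dj
            # fresh start at (i-1, j-1)
            fs = s
            if fs > hs or (fs == hs and (inc > hi or (inc == hi and j - 1 < hj))):
                hs, hi, hj = fs, inc, j - 1
            if hs < 0:
                hs, hi, hj = 0, 0, j  # local reset
            Hs[i, j], Hi[i, j], Hj[i, j] = hs, hi, hj
            # E: gap in query (consume target)
            es = Hs[i, j - 1] + gap_open
            ei, ej = Hi[i, j - 1], Hj[i, j - 1]
            if Es[i, j - 1] > NEG_INF:
                alt = Es[i, j - 1] + gap_extend
                if alt > es or (alt == es and (Ei[i, j - 1] > ei or
                   (Ei[i, j - 1] == ei and Ej[i, j - 1] < ej))):
                    es, ei, ej = alt, Ei[i, j - 1], Ej[i, j - 1]
            Es[i, j], Ei[i, j], Ej[i, j] = es, ei, ej
            # F: gap in target (consume query)
            fs2 = Hs[i - 1, j] + gap_open
            fi, fj = Hi[i - 1, j], Hj[i - 1, j]
            if Fs[i - 1, j] > NEG_INF:
                alt = Fs[i - 1, j] + gap_extend
                if alt > fs2 or (alt == fs2 and (Fi[i - 1, j] > fi or
                   (Fi[i - 1, j] == fi and Fj[i - 1, j] < fj))):
                    fs2, fi, fj = alt, Fi[i - 1, j], Fj[i - 1, j]
            Fs[i, j], Fi[i, j], Fj[i, j] = fs2, fi, fj
            if (Hs[i, j] > best_s or (Hs[i, j] == best_s and
               (Hi[i, j] > best_i or (Hi[i, j] == best_i and Hj[i, j] < best_j0)))):
                best_s, best_i = Hs[i, j], Hi[i, j]
                best_j0, best_j1 = Hj[i, j], j
    return best_s, best_i, best_j0, best_j1


def local_align_identity(query: str, target: str, scheme):
    """Best local alignment of `query` vs `target`.

    Returns ``(score, identities, target_start, target_end)``.  ``identities``
    is the maximum number of identity columns among all maximum-score local
    alignments (ties then resolved toward the smallest target start).  Empty
    inputs yield ``(0, 0, 0, 0)``.
    """
    if len(query) == 0 or len(target) == 0:
        return 0, 0, 0, 0
    s, ident, j0, j1 = _local_ident(
        encode(query), encode(target),
        np.int32(scheme.match), np.int32(scheme.mismatch),
        np.int32(scheme.gap_open), np.int32(scheme.gap_extend),
    )
    return int(s), int(ident), int(j0), int(j1)
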