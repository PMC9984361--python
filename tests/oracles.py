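"""Independent brute-force (memoized recursion) alignment oracles.

Written top-down over (query index, target index, last op) so they share no
code or formulation with the iterative production kernels; used to verify
score (and identity-count) agreement on small random instances.
"""

from functools import lru_cache

NEG = float("-inf")


def semiglobal_score_oracle(q: str, t: str, scheme) -> int:
    """Best score aligning all of `q` against `t` with free target flanks."""
    m, n = len(q), len(t)

    @lru_cache(maxsize=None)
    def rec(i, j, last):
        if i == m:
            return 0  # trailing target is free
        best = NEG
        if j < n:
            s = scheme.match if q[i] == t[j] else scheme.mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
            cost = scheme.gap_extend if last == "E" else scheme.gap_open
            best = max(best, cost + rec(i, j + 1, "E"))
        cost = scheme.gap_extend if last == "F" else scheme.gap_open
        best = max(best, cost + rec(i + 1, j, "F"))
        return best

    return int(max(rec(0, j0, "0") for j0 in range(n + 1)))


def local_score_ident_oracle(q: str, t: str, scheme) -> tuple[int, int]:
    """Max (score, identities) lexicographically over all local alignments
    of `q` vs `t` (the empty alignment scores (0, 0))."""
    m, n = len(q), len(t)

    @lru_cache(maxsize=None)
    def rec(i, j, last):
        best = (0, 0)  # stop here
        if i < m and j < n:
            s = scheme.match if q[i] == t[j] else scheme.mismatch
            inc = 1 if q[i] == t[j] else 0
            ds, di = rec(i + 1, j + 1, "M")
            best = max(best, (s + ds, inc + di))
        if j < n:
            cost = scheme.gap_extend if last == "E" else scheme.gap_open
            es, ei = rec(i, j + 1, "E")
            best = max(best, (cost + es, ei))
        if i < m:
            cost = scheme.gap_extend if last == "F" else scheme.gap_open
            fs, fi = rec(i + 1, j, "F")
            best = max(best, (cost + fs, fi))
        return best

    best = (0, 0)
    for i0 in range(m + 1):
        for j0 in range(n + 1):
            best = max(best, rec(i0, j0, "0"))
    return best
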