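"""Brute-force dynamic-programming alignment oracle.

A deliberately naive, pure-Python Gotoh implementation used to
cross-check the production aligner.  It builds full score matrices with
explicit per-cell max() calls and performs a state-machine traceback
under the documented tie-break conventions (diagonal > subject-consuming
gap > query-consuming gap; gaps closed as early as possible; end cell =
first maximum in scan order).  Kept independent of ampliref.alignment:
no code is shared beyond the scoring parameters.
"""

from __future__ import annotations

NEG = -(10 ** 9)


def _score(a: str, b: str, match: int, mismatch: int) -> int:
    if a == b and a in "ACGT":
        return match
    return mismatch


def _fill(q, s, match, mismatch, go, ge, local):
    m, n = len(q), len(s)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = max(H[i][j - 1] - go - ge, E[i][j - 1] - ge)
            f = max(H[i - 1][j] - go - ge, F[i - 1][j] - ge)
            h = H[i - 1][j - 1] + _score(q[i - 1], s[j - 1], match, mismatch)
            v = max(h, e, f)
            if local:
                v = max(v, 0)
            E[i][j] = e
            F[i][j] = f
            H[i][j] = v
    return H, E, F


def _traceback(q, s, H, E, F, match, mismatch, go, ge, bi, bj, local):
    i, j = bi, bj
    matches = 0
    columns = 0
    q_end = bi
    state = "H"
    while True:
        if local:
            if state == "H" and H[i][j] == 0:
                break
        elif i == 0 or j == 0:
            break
        if state == "H":
            diag = H[i - 1][j - 1] + _score(q[i - 1], s[j - 1], match, mismatch)
            if H[i][j] == diag:
                columns += 1
                if q[i - 1] == s[j - 1] and q[i - 1] in "ACGT":
                    matches += 1
                i -= 1
                j -= 1
            elif H[i][j] == E[i][j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            opened = H[i][j - 1] - go - ge
            came_from_open = E[i][j] == opened
            j -= 1
            if came_from_open:
                state = "H"
        else:
            columns += 1
            opened = H[i - 1][j] - go - ge
            came_from_open = F[i][j] == opened
            i -= 1
            if came_from_open:
                state = "H"
    return matches, columns, q_end - i


def naive_local(q: str, s: str, match=2, mismatch=-3, go=5, ge=2):
    """Return (score, matches, alignment_length, q_span) of the best local
    alignment, computed by exhaustive DP."""
    q = q.upper()
    s = s.upper()
    H, E, F = _fill(q, s, match, mismatch, go, ge, local=True)
    best, bi, bj = 0, 0, 0
    for i in range(1, len(q) + 1):
        for j in range(1, len(s) + 1):
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    if best <= 0:
        return 0, 0, 0, 0
    matches, columns, span = _traceback(q, s, H, E, F, match, mismatch, go, ge, bi, bj, local=True)
    return best, matches, columns, span


def naive_semiglobal(q: str, s: str, match=2, mismatch=-3, go=5, ge=2):
    """Return (score, matches, alignment_length, q_span) of the global
    end-gap-free alignment, computed by exhaustive DP."""
    q = q.upper()
    s = s.upper()
    m, n = len(q), len(s)
    H, E, F = _fill(q, s, match, mismatch, go, ge, local=False)
    best, bi, bj = NEG, m, 0
    for j in range(n + 1):
        if H[m][j] > best:
            best, bi, bj = H[m][j], m, j
    for i in range(m + 1):
        if H[i][n] > best:
            best, bi, bj = H[i][n], i, n
    matches, columns, span = _traceback(q, s, H, E, F, match, mismatch, go, ge, bi, bj, local=False)
    return best, matches, columns, span
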