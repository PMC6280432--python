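"""Pairwise DNA alignment with blastn-style identity/coverage semantics.

Two engines share one scoring model:

* :func:`align` — maximum-score *local* (Smith-Waterman-Gotoh) alignment,
  used for query-vs-reference classification.  Identity is computed over
  aligned columns including internal gaps; coverage is the fraction of the
  *query* spanned by the alignment.
* :func:`align_semiglobal` — *global* alignment with free terminal gaps
  (end-gap-free), used for comparing homologous amplicon regions of
  near-equal length.

Both are deterministic.  Where co-optimal alignments exist the traceback
follows a fixed convention that is part of the engine's contract:

* the end cell is the first maximal cell in row-major scan order;
* at each column, a diagonal step is preferred over a gap consuming the
  subject, which is preferred over a gap consuming the query;
* a gap is closed (re-opened from the match state) as early as possible,
  i.e. shorter gaps are preferred over longer ones at equal score.

Scoring: a gap of length L costs ``gap_open + L * gap_extend``.  ``N``
never counts as a match and scores as a mismatch against every base,
including another ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "Scoring",
    "AlignmentStats",
    "align",
    "align_semiglobal",
    "encode",
    "reverse_complement",
]

# Base encoding: A=0 C=1 G=2 T=3 N=4 (anything non-ACGT maps to N).
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
# IUPAC complements for primer handling.
_COMPLEMENT.update(
    {"R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
     "B": "V", "V": "B", "D": "H", "H": "D"}
)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0, C=1, G=2, T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC-aware (used for reverse-primer sites)."""
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass(frozen=True)
class Scoring:
    """blastn-task-style scoring parameters.

    Defaults reproduce the ranking behaviour of blastn's default task:
    match +2, mismatch -3, gap open -5, gap extend -2.  A gap of length L
    costs ``gap_open + L * gap_extend``.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2

    def matrix(self) -> np.ndarray:
        m = np.full((5, 5), self.mismatch, dtype=np.int32)
        for i in range(4):
            m[i, i] = self.match
        # N is never a match, even against N.
        m[4, :] = self.mismatch
        m[:, 4] = self.mismatch
        return m


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class AlignmentStats:
    """Summary of one pairwise alignment.

    ``identity`` is 100 * matches / alignment_length where
    ``alignment_length`` counts aligned columns including internal gaps and
    excluding terminal overhangs.  ``coverage`` is 100 * q_span /
    query_length, i.e. query coverage.
    """

    matches: int
    alignment_length: int
    q_span: int
    query_length: int
    score: int

    @property
    def identity(self) -> float:
        if self.alignment_length == 0:
            return 0.0
        return 100.0 * self.matches / self.alignment_length

    @property
    def coverage(self) -> float:
        if self.query_length == 0:
            return 0.0
        return 100.0 * self.q_span / self.query_length


_NEG = np.int32(-(10 ** 9))


@njit(cache=True)
def _fill_local(q, s, mat, go, ge):  # pragma: no cover - exercised via align()
    m, n = len(q), len(s)
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), _NEG, np.int32)
    F = np.full((m + 1, n + 1), _NEG, np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        matq = mat[q[i - 1]]
        Hp = H[i - 1]
        Hc = H[i]
        Ec = E[i]
        Fp = F[i - 1]
        Fc = F[i]
        hleft = np.int32(0)
        eleft = _NEG
        for j in range(1, n + 1):
            e = max(hleft - go - ge, eleft - ge)
            f = max(Hp[j] - go - ge, Fp[j] - ge)
            v = Hp[j - 1] + matq[s[j - 1]]
            if e > v:
                v = e
            if f > v:
                v = f
            if v < 0:
                v = np.int32(0)
            Ec[j] = e
            Fc[j] = f
            Hc[j] = v
            hleft = v
            eleft = e
            if v > best:
                best = v
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def _trace_local(q, s, mat, go, ge, H, E, F, bi, bj):  # pragma: no cover
    # Returns (matches, columns, q_span). States: 0=H, 1=E (gap in query,
    # consumes subject), 2=F (gap in subject, consumes query).
    i, j = bi, bj
    matches = 0
    columns = 0
    q_end = bi
    state = 0
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            diag = H[i - 1, j - 1] + mat[q[i - 1], s[j - 1]]
            if H[i, j] == diag:
                columns += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4 and s[j - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            opened = H[i, j - 1] - go - ge
            j -= 1
            if E[i, j + 1] == opened:
                state = 0  # close gap as early as possible
        else:
            columns += 1
            opened = H[i - 1, j] - go - ge
            i -= 1
            if F[i + 1, j] == opened:
                state = 0
    return matches, columns, q_end - i


def align(query: str, subject: str, scoring: Scoring = DEFAULT_SCORING) -> AlignmentStats:
    """Maximum-score local alignment of ``query`` against ``subject``.

    Raises ``ValueError`` on empty input.  Deterministic for fixed inputs
    and scoring (see module docstring for tie-break conventions).
    """
    if not query or not subject:
        raise ValueError("align() requires two non-empty sequences")
    q = encode(query)
    s = encode(subject)
    mat = scoring.matrix()
    go = np.int32(scoring.gap_open)
    ge = np.int32(scoring.gap_extend)
    H, E, F, best, bi, bj = _fill_local(q, s, mat, go, ge)
    if best <= 0:
        return AlignmentStats(0, 0, 0, len(q), int(best))
    matches, columns, q_span = _trace_local(q, s, mat, go, ge, H, E, F, bi, bj)
    return AlignmentStats(int(matches), int(columns), int(q_span), len(q), int(best))


@njit(cache=True)
def _fill_semiglobal(q, s, mat, go, ge):  # pragma: no cover
    m, n = len(q), len(s)
    H = np.zeros((m + 1, n + 1), np.int32)
    E = np.full((m + 1, n + 1), _NEG, np.int32)
    F = np.full((m + 1, n + 1), _NEG, np.int32)
    for i in range(1, m + 1):
        matq = mat[q[i - 1]]
        Hp = H[i - 1]
        Hc = H[i]
        Ec = E[i]
        Fp = F[i - 1]
        Fc = F[i]
        hleft = np.int32(0)
        eleft = _NEG
        for j in range(1, n + 1):
            e = max(hleft - go - ge, eleft - ge)
            f = max(Hp[j] - go - ge, Fp[j] - ge)
            v = Hp[j - 1] + matq[s[j - 1]]
            if e > v:
                v = e
            if f > v:
                v = f
            Ec[j] = e
            Fc[j] = f
            Hc[j] = v
            hleft = v
            eleft = e
    # Best end over the last row then the last column, first maximum wins.
    best = _NEG
    bi = m
    bj = 0
    for j in range(n + 1):
        if H[m, j] > best:
            best = H[m, j]
            bi = m
            bj = j
    for i in range(m + 1):
        if H[i, n] > best:
            best = H[i, n]
            bi = i
            bj = n
    return H, E, F, best, bi, bj


@njit(cache=True)
def _trace_semiglobal(q, s, mat, go, ge, H, E, F, bi, bj):  # pragma: no cover
    i, j = bi, bj
    matches = 0
    columns = 0
    q_end = bi
    state = 0
    while i > 0 and j > 0:
        if state == 0:
            diag = H[i - 1, j - 1] + mat[q[i - 1], s[j - 1]]
            if H[i, j] == diag:
                columns += 1
                if q[i - 1] == s[j - 1] and q[i - 1] < 4 and s[j - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            columns += 1
            opened = H[i, j - 1] - go - ge
            j -= 1
            if E[i, j + 1] == opened:
                state = 0
        else:
            columns += 1
            opened = H[i - 1, j] - go - ge
            i -= 1
            if F[i + 1, j] == opened:
                state = 0
    return matches, columns, q_end - i


def align_semiglobal(query: str, subject: str, scoring: Scoring = DEFAULT_SCORING) -> AlignmentStats:
    """Global alignment with free (unpenalised, uncounted) terminal gaps.

    Terminal overhangs contribute neither to ``alignment_length`` nor to
    ``matches``; identity is therefore computed over the aligned core only.
    Appropriate for homologous regions of near-equal length.
    """
    if not query or not subject:
        raise ValueError("align_semiglobal() requires two non-empty sequences")
    q = encode(query)
    s = encode(subject)
    mat = scoring.matrix()
    go = np.int32(scoring.gap_open)
    ge = np.int32(scoring.gap_extend)
    H, E, F, best, bi, bj = _fill_semiglobal(q, s, mat, go, ge)
    matches, columns, q_span = _trace_semiglobal(q, s, mat, go, ge, H, E, F, bi, bj)
    return AlignmentStats(int(matches), int(columns), int(q_span), len(q), int(best))
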