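"""Dynamic-programming alignment kernels shared across the pipeline.

All kernels operate on sequences encoded as IUPAC bitmasks (A=1, C=2, G=4,
T=8; degenerate codes are unions), so degenerate letters match any compatible
concrete base. Gap scoring convention: a gap of length L costs
``gap_open + (L - 1) * gap_extend`` (the first gapped position pays the open
penalty), which is the convention of Biopython's PairwiseAligner with
``open_gap_score = gap_open`` and ``extend_gap_score = gap_extend``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .core_io import IUPAC_BITS

_NEG = -(10 ** 9)

_ENCODE = np.zeros(256, dtype=np.uint8)
for _code, _bits in IUPAC_BITS.items():
    _ENCODE[ord(_code)] = _bits
    _ENCODE[ord(_code.lower())] = _bits


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as an array of IUPAC bitmasks."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    enc = _ENCODE[arr]
    if len(seq) and not enc.all():
        bad = seq[int(np.argmin(enc != 0))]
        raise ValueError(f"non-IUPAC character {bad!r}")
    return enc


@njit(cache=True)
def _fill_local(q, s, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m, n = len(q), len(s)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            sub = match if (qi & s[j - 1]) != 0 else mismatch
            e = H[i - 1, j] + gap_open
            if E[i - 1, j] + gap_extend > e:
                e = E[i - 1, j] + gap_extend
            E[i, j] = e
            f = H[i, j - 1] + gap_open
            if F[i, j - 1] + gap_extend > f:
                f = F[i, j - 1] + gap_extend
            F[i, j] = f
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def _fill_global(q, s, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    m, n = len(q), len(s)
    H = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    E = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int32)
    H[0, 0] = 0
    for i in range(1, m + 1):
        E[i, 0] = gap_open + (i - 1) * gap_extend
        H[i, 0] = E[i, 0]
    for j in range(1, n + 1):
        F[0, j] = gap_open + (j - 1) * gap_extend
        H[0, j] = F[0, j]
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            sub = match if (qi & s[j - 1]) != 0 else mismatch
            e = H[i - 1, j] + gap_open
            if E[i - 1, j] + gap_extend > e:
                e = E[i - 1, j] + gap_extend
            E[i, j] = e
            f = H[i, j - 1] + gap_open
            if F[i, j - 1] + gap_extend > f:
                f = F[i, j - 1] + gap_extend
            F[i, j] = f
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def _sellers_last_row(p, s):  # pragma: no cover
    """Min edit distance of the full pattern vs a substring ending at each
    position of the subject (free start). Returns the last DP row."""
    m, n = len(p), len(s)
    prev = np.empty(n + 1, dtype=np.int32)
    cur = np.empty(n + 1, dtype=np.int32)
    for j in range(n + 1):
        prev[j] = 0
    for i in range(1, m + 1):
        cur[0] = i
        pi = p[i - 1]
        for j in range(1, n + 1):
            cost = 0 if (pi & s[j - 1]) != 0 else 1
            best = prev[j - 1] + cost
            if prev[j] + 1 < best:
                best = prev[j] + 1
            if cur[j - 1] + 1 < best:
                best = cur[j - 1] + 1
            cur[j] = best
        prev, cur = cur, prev
    return prev


def _traceback(H, E, F, q, s, i, j, match, mismatch, gap_open, gap_extend,
               local: bool):
    """Walk the three-state DP back from (i, j); returns (qs, ss, stats).

    stats = (n_match_columns, n_alignment_columns). Ties prefer diagonal,
    then vertical (gap in subject), then horizontal — deterministic.
    """
    n_match = 0
    n_cols = 0
    state = "H"
    while i > 0 or j > 0:
        if local and state == "H" and H[i, j] == 0:
            break
        if state == "H":
            if i > 0 and j > 0:
                sub = match if (q[i - 1] & s[j - 1]) else mismatch
                if H[i, j] == H[i - 1, j - 1] + sub:
                    n_cols += 1
                    if q[i - 1] & s[j - 1]:
                        n_match += 1
                    i -= 1
                    j -= 1
                    continue
            if i > 0 and H[i, j] == E[i, j]:
                state = "E"
                continue
            if j > 0 and H[i, j] == F[i, j]:
                state = "F"
                continue
            raise AssertionError("traceback dead end")
        if state == "E":
            n_cols += 1
            if H[i - 1, j] + gap_open == E[i, j]:
                state = "H"
            elif E[i - 1, j] + gap_extend == E[i, j]:
                state = "E"
            else:  # boundary initialisation in global mode
                state = "E" if i > 1 else "H"
            i -= 1
            continue
        # state == "F"
        n_cols += 1
        if H[i, j - 1] + gap_open == F[i, j]:
            state = "H"
        elif F[i, j - 1] + gap_extend == F[i, j]:
            state = "F"
        else:
            state = "F" if j > 1 else "H"
        j -= 1
    return i, j, n_match, n_cols


def best_local_alignment(query: str, subject: str, match: int = 1,
                         mismatch: int = -2, gap_open: int = -5,
                         gap_extend: int = -2):
    """Best Smith-Waterman local alignment of query vs subject.

    Returns ``(score, (q_start, q_end), (s_start, s_end), identity)`` with
    identity computed over alignment columns, gaps counted as mismatches, or
    ``None`` when the best score is 0. The maximum-scoring cell is chosen with
    the smallest (subject end, query end) on ties.
    """
    q, s = encode(query), encode(subject)
    if len(q) == 0 or len(s) == 0:
        return None
    H, E, F = _fill_local(q, s, match, mismatch, gap_open, gap_extend)
    score = int(H.max())
    if score <= 0:
        return None
    cells = np.argwhere(H == score)
    # smallest subject end, then query end
    order = np.lexsort((cells[:, 0], cells[:, 1]))
    i_end, j_end = (int(v) for v in cells[order[0]])
    i0, j0, n_match, n_cols = _traceback(
        H, E, F, q, s, i_end, j_end, match, mismatch, gap_open, gap_extend,
        local=True)
    identity = n_match / n_cols if n_cols else 0.0
    return score, (i0, i_end), (j0, j_end), identity


def global_alignment(query: str, subject: str, match: int = 1,
                     mismatch: int = -1, gap_open: int = -4,
                     gap_extend: int = -1) -> tuple[int, str, str]:
    """Needleman-Wunsch global alignment; returns (score, gapped_q, gapped_s)."""
    q, s = encode(query), encode(subject)
    if len(q) == 0:
        return (gap_open + (len(s) - 1) * gap_extend if len(s) else 0,
                "-" * len(s), subject)
    if len(s) == 0:
        return gap_open + (len(q) - 1) * gap_extend, query, "-" * len(q)
    H, E, F = _fill_global(q, s, match, mismatch, gap_open, gap_extend)
    score = int(H[len(q), len(s)])
    # replay the traceback, emitting gapped strings
    i, j = len(q), len(s)
    out_q: list[str] = []
    out_s: list[str] = []
    state = "H"
    while i > 0 or j > 0:
        if state == "H":
            if i > 0 and j > 0:
                sub = match if (q[i - 1] & s[j - 1]) else mismatch
                if H[i, j] == H[i - 1, j - 1] + sub:
                    out_q.append(query[i - 1])
                    out_s.append(subject[j - 1])
                    i -= 1
                    j -= 1
                    continue
            if i > 0 and H[i, j] == E[i, j]:
                state = "E"
                continue
            state = "F"
            continue
        if state == "E":
            out_q.append(query[i - 1])
            out_s.append("-")
            if j == 0:
                state = "E"
            elif H[i - 1, j] + gap_open == E[i, j]:
                state = "H"
            else:
                state = "E"
            i -= 1
            continue
        out_q.append("-")
        out_s.append(subject[j - 1])
        if i == 0:
            state = "F"
        elif H[i, j - 1] + gap_open == F[i, j]:
            state = "H"
        else:
            state = "F"
        j -= 1
    return score, "".join(reversed(out_q)), "".join(reversed(out_s))


def semiglobal_end_distances(pattern: str, subject: str) -> np.ndarray:
    """For each subject position j, the minimum edit distance of the whole
    pattern against any substring of the subject ending at j (length n+1;
    entry 0 is the empty prefix). IUPAC-compatible letters match at cost 0."""
    p, s = encode(pattern), encode(subject)
    return _sellers_last_row(p, s)
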