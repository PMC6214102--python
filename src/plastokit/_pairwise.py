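"""Global affine-gap pairwise alignment (Gotoh), plus anchored alignment
for genome-scale sequences.

Scoring convention: a gap of length g costs ``gap_open + g * gap_extend``
(both negative).  Tie-breaking during traceback is deterministic and
prefers, at equal score, a diagonal step (match or mismatch) over a
vertical step (gap in the second sequence, i.e. a deletion relative to
the first) over a horizontal step (insertion).
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

NEG = np.float32(-1e8)


class AlignmentError(ValueError):
    pass


def _sub_matrix_dna(match: float, mismatch: float) -> tuple[dict[str, int], np.ndarray]:
    alphabet = "ACGTN"
    idx = {c: i for i, c in enumerate(alphabet)}
    m = np.full((5, 5), mismatch, dtype=np.float32)
    np.fill_diagonal(m, match)
    # N scores as mismatch against everything, including itself
    m[4, :] = mismatch
    m[:, 4] = mismatch
    return idx, m


def _encode(seq: str, idx: dict[str, int]) -> np.ndarray:
    return np.fromiter((idx.get(c, idx.get("X", 0)) for c in seq), dtype=np.int64)


def gotoh_align(
    a: str,
    b: str,
    sub: np.ndarray,
    index: dict[str, int],
    gap_open: float,
    gap_extend: float,
) -> tuple[str, str, float]:
    """Optimal global alignment of ``a`` (rows) and ``b`` (columns).

    Returns (aligned_a, aligned_b, score).  All scores are kept in exact
    small-integer float arithmetic, so equality tests in the traceback are
    safe.
    """
    n, m = len(a), len(b)
    go = np.float32(gap_open)
    ge = np.float32(gap_extend)
    if n == 0 and m == 0:
        return "", "", 0.0
    if n * m > 16_000_000:
        raise AlignmentError(
            f"alignment problem too large ({n} x {m}); supply an external alignment"
        )
    ea = _encode(a, index)
    eb = _encode(b, index)

    M = np.full((n + 1, m + 1), NEG, dtype=np.float32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.float32)  # gap in a (horizontal)
    F = np.full((n + 1, m + 1), NEG, dtype=np.float32)  # gap in b (vertical)
    M[0, 0] = 0.0
    if m:
        E[0, 1:] = go + ge * np.arange(1, m + 1, dtype=np.float32)
    if n:
        F[1:, 0] = go + ge * np.arange(1, n + 1, dtype=np.float32)

    jcol = np.arange(m, dtype=np.float32)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], E[i - 1]), F[i - 1])
        M[i, 1:] = prev_best[:-1] + sub[ea[i - 1], eb]
        # vertical: open from best non-F state above, or extend F
        open_v = np.maximum(M[i - 1, 1:], E[i - 1, 1:]) + go + ge
        F[i, 1:] = np.maximum(open_v, F[i - 1, 1:] + ge)
        # horizontal: E[i,j] = ge*j + max_{k<j}(maxMF[i,k] + go - ge*k)
        mf = np.maximum(M[i, :-1], F[i, :-1])
        h = mf + go - ge * jcol
        E[i, 1:] = ge * np.arange(1, m + 1, dtype=np.float32) + np.maximum.accumulate(h)

    # traceback; preference: M (diagonal) > F (vertical/deletion) > E
    i, j = n, m
    best = max(M[i, j], F[i, j], E[i, j])
    if M[i, j] == best:
        state = "M"
    elif F[i, j] == best:
        state = "F"
    else:
        state = "E"
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = sub[ea[i - 1], eb[j - 1]]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            target = M[i, j] - s
            i, j = i - 1, j - 1
            if M[i, j] == target:
                state = "M"
            elif F[i, j] == target:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            out_a.append(a[i - 1])
            out_b.append("-")
            val = F[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + go + ge == val:
                state = "M"
            elif E[i, j] + go + ge == val:
                state = "E"
            else:
                state = "F"
        else:  # E
            out_a.append("-")
            out_b.append(b[j - 1])
            val = E[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + go + ge == val:
                state = "M"
            elif F[i, j] + go + ge == val:
                state = "F"
            else:
                state = "E"
        if i == 0 and j == 0:
            break
        if i == 0:
            state = "E"
        elif j == 0:
            state = "F"
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(best)


_DNA_INDEX, _DNA_SUB = _sub_matrix_dna(2.0, -3.0)


def align_dna(
    a: str, b: str, gap_open: float = -5.0, gap_extend: float = -2.0
) -> tuple[str, str, float]:
    """Affine DNA alignment: match +2, mismatch -3, gap open -5, extend -2."""
    return gotoh_align(a, b, _DNA_SUB, _DNA_INDEX, gap_open, gap_extend)


_PROT_CACHE: Optional[tuple[dict[str, int], np.ndarray]] = None


def _blosum62() -> tuple[dict[str, int], np.ndarray]:
    global _PROT_CACHE
    if _PROT_CACHE is None:
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        alphabet = str(blosum.alphabet)
        idx = {c: i for i, c in enumerate(alphabet)}
        m = np.array(blosum, dtype=np.float32)
        _PROT_CACHE = (idx, m)
    return _PROT_CACHE


def align_protein(
    a: str, b: str, gap_open: float = -10.0, gap_extend: float = -1.0
) -> tuple[str, str, float]:
    """Affine protein alignment with BLOSUM62, gap open -10, extend -1."""
    idx, m = _blosum62()
    a = "".join(c if c in idx else "X" for c in a.upper())
    b = "".join(c if c in idx else "X" for c in b.upper())
    return gotoh_align(a, b, m, idx, gap_open, gap_extend)


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if kmer in dup:
            continue
        if kmer in seen:
            del seen[kmer]
            dup.add(kmer)
        else:
            seen[kmer] = i
    return seen


def _chain_anchors(pairs: list[tuple[int, int]], k: int) -> list[tuple[int, int, int]]:
    """Longest chain of co-linear, non-overlapping anchors.

    ``pairs`` are (a_pos, b_pos) seed matches sorted by a_pos; returns
    merged anchors (a_pos, b_pos, length).
    """
    import bisect

    if not pairs:
        return []
    # patience LIS on b positions (strictly increasing)
    tails: list[int] = []
    tails_idx: list[int] = []
    prev = [-1] * len(pairs)
    for i, (_, bpos) in enumerate(pairs):
        pos = bisect.bisect_left(tails, bpos)
        if pos == len(tails):
            tails.append(bpos)
            tails_idx.append(i)
        else:
            tails[pos] = bpos
            tails_idx[pos] = i
        prev[i] = tails_idx[pos - 1] if pos > 0 else -1
    chain: list[tuple[int, int]] = []
    i = tails_idx[-1]
    while i != -1:
        chain.append(pairs[i])
        i = prev[i]
    chain.reverse()
    # drop anchors overlapping their predecessor, merge same-diagonal runs
    anchors: list[list[int]] = []
    for apos, bpos in chain:
        if anchors:
            pa, pb, plen = anchors[-1]
            if apos - pa == bpos - pb and apos <= pa + plen:
                anchors[-1][2] = apos + k - pa
                continue
            if apos < pa + plen or bpos < pb + plen:
                continue
        anchors.append([apos, bpos, k])
    return [tuple(x) for x in anchors]  # type: ignore[misc]


def anchored_align_dna(
    a: str,
    b: str,
    k: int = 31,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> tuple[str, str]:
    """Genome-scale DNA alignment via unique k-mer anchoring.

    Shared unique k-mers are chained co-linearly; inter-anchor segments are
    aligned with the full affine DP.  Intended for high-identity sequences
    (the synthetic cohorts); no score is reported.
    """
    ka = _unique_kmers(a, k)
    kb = _unique_kmers(b, k)
    pairs = sorted((pa, kb[m]) for m, pa in ka.items() if m in kb)
    anchors = _chain_anchors(pairs, k)
    if not anchors:
        aa, bb, _ = align_dna(a, b, gap_open, gap_extend)
        return aa, bb
    out_a: list[str] = []
    out_b: list[str] = []
    ca = cb = 0
    for apos, bpos, length in anchors:
        seg_a, seg_b = a[ca:apos], b[cb:bpos]
        if seg_a or seg_b:
            if not seg_a:
                out_a.append("-" * len(seg_b))
                out_b.append(seg_b)
            elif not seg_b:
                out_a.append(seg_a)
                out_b.append("-" * len(seg_a))
            else:
                aa, bb, _ = align_dna(seg_a, seg_b, gap_open, gap_extend)
                out_a.append(aa)
                out_b.append(bb)
        out_a.append(a[apos : apos + length])
        out_b.append(b[bpos : bpos + length])
        ca, cb = apos + length, bpos + length
    seg_a, seg_b = a[ca:], b[cb:]
    if seg_a or seg_b:
        if not seg_a:
            out_a.append("-" * len(seg_b))
            out_b.append(seg_b)
        elif not seg_b:
            out_a.append(seg_a)
            out_b.append("-" * len(seg_a))
        else:
            aa, bb, _ = align_dna(seg_a, seg_b, gap_open, gap_extend)
            out_a.append(aa)
            out_b.append(bb)
    return "".join(out_a), "".join(out_b)
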