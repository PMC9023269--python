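"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: a plain three-state
dynamic program for semiglobal affine alignment scores, a string-equality
scan for deletion equivalence/microhomology, and a naive Hamming scan.
"""

from __future__ import annotations

NEG = float("-inf")


def semiglobal_score_oracle(
    ref: str,
    read: str,
    match: float = 2,
    mismatch: float = -4,
    gap_open: float = -10,
    gap_extend: float = -1,
) -> float:
    """Optimal semiglobal affine score (free end gaps on the reference)."""
    n, m = len(ref), len(read)
    V = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in read (ref base unmatched)
    I = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in ref (read base unmatched)
    for i in range(n + 1):
        V[i][0] = 0.0  # leading reference overhang is free
    for j in range(1, m + 1):
        I[0][j] = max(V[0][j - 1] + gap_open, I[0][j - 1] + gap_extend)
        V[0][j] = I[0][j]
    for i in range(1, n + 1):
        ri = ref[i - 1]
        for j in range(1, m + 1):
            diag = V[i - 1][j - 1] + (match if ri == read[j - 1] else mismatch)
            D[i][j] = max(V[i - 1][j] + gap_open, D[i - 1][j] + gap_extend)
            I[i][j] = max(V[i][j - 1] + gap_open, I[i][j - 1] + gap_extend)
            V[i][j] = max(diag, D[i][j], I[i][j])
    return max(V[i][m] for i in range(n + 1))  # trailing overhang free


def deletion_placements_oracle(ref: str, start: int, length: int) -> list[int]:
    """All placements of a deletion yielding the identical edited sequence."""
    edited = ref[:start] + ref[start + length :]
    return [
        s
        for s in range(len(ref) - length + 1)
        if ref[:s] + ref[s + length :] == edited
    ]


def mh_len_oracle(ref: str, start: int, length: int) -> int:
    """Flanking-repeat length of a deletion: its sliding ambiguity, capped at L-1.

    A k-nt flanking repeat lets the deletion slide over k placements; the
    size of the placement set minus one therefore equals the maximal
    microhomology length, independent of any suffix/prefix bookkeeping.
    """
    placements = deletion_placements_oracle(ref, start, length)
    return min(max(placements) - min(placements), length - 1)


def hamming_scan_oracle(read: str, anchor: str) -> list[int]:
    """Hamming distance of ``anchor`` at every offset of ``read``."""
    k = len(anchor)
    return [
        sum(a != b for a, b in zip(read[i : i + k], anchor))
        for i in range(len(read) - k + 1)
    ]
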