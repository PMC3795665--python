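"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: the alignment oracle
enumerates every global alignment recursively, and the mapping oracle slides
a read across every offset by direct string comparison.
"""

from __future__ import annotations


def brute_force_alignment_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
) -> float:
    """Best global alignment score by exhaustive recursion (no DP tables).

    A gap of length k costs gap_open + (k-1) * gap_extend.  Only feasible for
    short sequences (the number of alignments grows like the Delannoy
    numbers); tests keep len <= 8.
    """
    best = [float("-inf")]

    def rec(i: int, j: int, score: float, prev: str) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, "M")
        if i < len(a):
            rec(i + 1, j, score + (gap_extend if prev == "X" else gap_open), "X")
        if j < len(b):
            rec(i, j + 1, score + (gap_extend if prev == "Y" else gap_open), "Y")

    rec(0, 0, 0.0, "S")
    return best[0]


def sliding_mismatches(read: str, reference: str, circular: bool = True) -> tuple[int, int]:
    """(best offset 0-based, mismatch count) by direct comparison at every offset."""
    L = len(reference)
    ext = reference + (reference[: len(read) - 1] if circular else "")
    best_off, best_mm = 0, len(read) + 1
    for off in range(L if circular else L - len(read) + 1):
        mm = sum(1 for x, y in zip(read, ext[off : off + len(read)]) if x != y)
        if mm < best_mm:
            best_off, best_mm = off, mm
    return best_off, best_mm


def alignment_score_from_strings(
    aligned_a: str,
    aligned_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
) -> float:
    """Re-score an alignment directly from its gapped strings."""
    score = 0.0
    prev = None
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            state = "Y" if ca == "-" else "X"
            score += gap_extend if prev == state else gap_open
            prev = state
        else:
            score += match if ca == cb else mismatch
            prev = "M"
    return score
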