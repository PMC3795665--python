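"""Interspecific divergence between consensus repeat units.

Two species' consensus units are globally aligned and every divergent column
is classified as a transition (A<->G, C<->T), a transversion (purine <->
pyrimidine) or part of a *complex* event — any insertion, deletion or
inversion.  Gene regions, under purifying selection for rRNA function, show
mostly transitions; spacers and expansion segments accumulate transversions
and complex events.

Alignment is Needleman-Wunsch with affine gaps (Gotoh): match +1, mismatch
-1, and a gap of length k costs -2 - 0.5*(k-1) (open -2, extend -0.5, the
same convention as Biopython's PairwiseAligner).  Scores are computed in
doubled integers so ties are exact, and the traceback is deterministic:
diagonal, then up (gap in the second sequence), then left.  To make event
totals exactly symmetric in the input order, the pair is canonicalised
lexicographically before the DP and the alignment is transposed back.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pileup import revcomp
from .reference import Region

__all__ = [
    "AlignmentScoring",
    "PairwiseAlignment",
    "DivergenceEvent",
    "align_pair",
    "classify_events",
    "region_divergence",
    "events_to_tsv",
]

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})

NEG_INF = np.int64(-(10**15))


@dataclass(frozen=True)
class AlignmentScoring:
    """Alignment scores; a gap of length k costs open + (k-1)*extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5

    def doubled(self) -> tuple[int, int, int, int]:
        vals = (self.match, self.mismatch, self.gap_open, self.gap_extend)
        doubled = tuple(2 * v for v in vals)
        if any(abs(v - round(v)) > 1e-9 for v in doubled):
            raise ValueError("scores must be multiples of 0.5 for exact tie handling")
        return tuple(int(round(v)) for v in doubled)  # type: ignore[return-value]


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences, gaps as '-'."""

    aligned_a: str
    aligned_b: str
    score: float

    def columns(self) -> list[tuple[str, str]]:
        return list(zip(self.aligned_a, self.aligned_b))

    def coordinate_map(self) -> list[tuple[int, int]]:
        """(posA, posB) for every column where both sequences have a base."""
        out = []
        pa = pb = 0
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca != "-":
                pa += 1
            if cb != "-":
                pb += 1
            if ca != "-" and cb != "-":
                out.append((pa, pb))
        return out


@dataclass(frozen=True)
class DivergenceEvent:
    """One divergence event, positioned on the first sequence (1-based)."""

    position: int
    cls: str  # 'transition' | 'transversion' | 'complex'
    detail: str


def _gotoh(a: str, b: str, scoring: AlignmentScoring) -> tuple[str, str, int]:
    """Affine-gap global alignment; returns aligned strings and doubled score."""
    match2, mismatch2, open2, ext2 = scoring.doubled()
    n, m = len(a), len(b)
    # state matrices, doubled-integer scores; M: a[i] ~ b[j], X: gap in b
    # (consumes a, "up"), Y: gap in a (consumes b, "left")
    M = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    X = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    Y = np.full((n + 1, m + 1), NEG_INF, dtype=np.int64)
    M[0, 0] = 0
    for i in range(1, n + 1):
        X[i, 0] = open2 + (i - 1) * ext2
    for j in range(1, m + 1):
        Y[0, j] = open2 + (j - 1) * ext2

    a_codes = np.frombuffer(a.encode(), dtype=np.uint8)
    b_codes = np.frombuffer(b.encode(), dtype=np.uint8)
    sub_row = np.empty(m, dtype=np.int64)
    for i in range(1, n + 1):
        np.copyto(sub_row, mismatch2)
        sub_row[b_codes == a_codes[i - 1]] = match2
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + sub_row
        X[i, 1:] = np.maximum(
            np.maximum(M[i - 1, 1:] + open2, X[i - 1, 1:] + ext2),
            Y[i - 1, 1:] + open2,
        )
        # Y depends on the current row to the left: running scan via cummax of
        # (best non-Y entry at k) - k*ext, since a switch into Y always costs open2
        # Y[i,j] = open2 + (j-1-k)*ext2 + w[k], maximised over k <= j-1
        w = np.maximum(M[i, :-1], X[i, :-1]).astype(np.float64)
        shift = np.arange(m, dtype=np.float64) * ext2
        scan = np.maximum.accumulate(w - shift)
        Y[i, 1:] = np.where(
            scan > float(NEG_INF) / 2,
            np.round(scan + shift + open2).astype(np.int64),
            NEG_INF,
        )

    # traceback: preference diagonal (M), then up (X), then left (Y)
    i, j = n, m
    finals = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax(finals))  # argmax returns first max: M > X > Y
    score2 = int(finals[state])
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:  # M: consumed a[i-1] and b[j-1]
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = match2 if a[i - 1] == b[j - 1] else mismatch2
            target = M[i, j] - s
            i, j = i - 1, j - 1
            state = _pick_state(M[i, j], X[i, j], Y[i, j], target)
        elif state == 1:  # X: gap in b, consumed a[i-1]
            out_a.append(a[i - 1])
            out_b.append("-")
            here = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + open2 == here:
                state = 0
            elif X[i, j] + ext2 == here:
                state = 1
            else:
                state = 2
        else:  # Y: gap in a, consumed b[j-1]
            out_a.append("-")
            out_b.append(b[j - 1])
            here = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if M[i, j] + open2 == here:
                state = 0
            elif X[i, j] + open2 == here:
                state = 1
            else:
                state = 2
    return "".join(reversed(out_a)), "".join(reversed(out_b)), score2


def _pick_state(m: int, x: int, y: int, target: int) -> int:
    if m == target:
        return 0
    if x == target:
        return 1
    if y == target:
        return 2
    raise AssertionError("traceback lost the optimal path")


def align_pair(
    seq_a: str,
    seq_b: str,
    scoring: AlignmentScoring = AlignmentScoring(),
) -> PairwiseAlignment:
    """Optimal global alignment of two nucleotide sequences.

    The pair is canonicalised by lexicographic order before the DP and the
    result transposed back, so that the alignment — and hence all event
    class totals — is exactly symmetric in the argument order.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    seq_a = seq_a.upper()
    seq_b = seq_b.upper()
    if seq_a <= seq_b:
        aa, ab, score2 = _gotoh(seq_a, seq_b, scoring)
    else:
        ab, aa, score2 = _gotoh(seq_b, seq_a, scoring)
    return PairwiseAlignment(aligned_a=aa, aligned_b=ab, score=score2 / 2.0)


def classify_events(
    alignment: PairwiseAlignment,
    *,
    merge_distance: int = 3,
    min_inversion_length: int = 4,
) -> tuple[list[DivergenceEvent], dict[str, int]]:
    """Classify every divergent alignment column into event classes.

    Substitution columns are transitions or transversions.  Each maximal gap
    run is one complex event; gap runs separated by fewer than
    ``merge_distance`` aligned columns merge into a single complex event.  A
    gapless mismatch run of length >= ``min_inversion_length`` whose reverse
    complement matches the partner sequence is re-labelled as one complex
    (inversion) event.  Positions are 1-based on the first sequence; events
    inside a gap of the first sequence take the position of the preceding
    base (minimum 1).
    """
    cols = alignment.columns()
    pos_a = []  # seqA coordinate for every column (position of preceding base within gaps)
    pa = 0
    for ca, _ in cols:
        if ca != "-":
            pa += 1
        pos_a.append(max(pa, 1))

    is_gap = [ca == "-" or cb == "-" for ca, cb in cols]
    # maximal gap runs
    gap_runs: list[tuple[int, int]] = []
    k = 0
    while k < len(cols):
        if is_gap[k]:
            start = k
            while k < len(cols) and is_gap[k]:
                k += 1
            gap_runs.append((start, k - 1))
        else:
            k += 1
    # merge runs separated by < merge_distance aligned columns
    merged: list[tuple[int, int]] = []
    for run in gap_runs:
        if merged and run[0] - merged[-1][1] - 1 < merge_distance:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)

    complex_cols = set()
    events: list[DivergenceEvent] = []
    for start, end in merged:
        complex_cols.update(range(start, end + 1))
        n_ins = sum(1 for k in range(start, end + 1) if cols[k][0] == "-")
        n_del = sum(1 for k in range(start, end + 1) if cols[k][1] == "-")
        parts = []
        if n_del:
            parts.append(f"{n_del}bp deletion in B")
        if n_ins:
            parts.append(f"{n_ins}bp insertion in B")
        events.append(
            DivergenceEvent(
                position=pos_a[start],
                cls="complex",
                detail="indel: " + ", ".join(parts),
            )
        )

    # mismatch runs outside complex spans
    k = 0
    while k < len(cols):
        ca, cb = cols[k]
        if k in complex_cols or is_gap[k] or ca == cb:
            k += 1
            continue
        start = k
        while (
            k < len(cols)
            and k not in complex_cols
            and not is_gap[k]
            and cols[k][0] != cols[k][1]
        ):
            k += 1
        run_a = "".join(cols[t][0] for t in range(start, k))
        run_b = "".join(cols[t][1] for t in range(start, k))
        if len(run_a) >= min_inversion_length and run_a == revcomp(run_b):
            events.append(
                DivergenceEvent(
                    position=pos_a[start],
                    cls="complex",
                    detail=f"inversion {len(run_a)}bp",
                )
            )
            continue
        for t in range(start, k):
            ca, cb = cols[t]
            if (ca, cb) in _TRANSITIONS:
                cls = "transition"
            else:
                cls = "transversion"
            events.append(
                DivergenceEvent(position=pos_a[t], cls=cls, detail=f"{ca}>{cb}")
            )

    events.sort(key=lambda e: (e.position, e.cls, e.detail))
    totals = {"transition": 0, "transversion": 0, "complex": 0}
    for e in events:
        totals[e.cls] += 1
    return events, totals


def region_divergence(
    events: Sequence[DivergenceEvent],
    regions: Iterable[Region],
) -> pd.DataFrame:
    """Counts and per-base densities of each event class per region."""
    rows = []
    for reg in regions:
        counts = {"transition": 0, "transversion": 0, "complex": 0}
        for e in events:
            if reg.start <= e.position <= reg.end:
                counts[e.cls] += 1
        row = {"region": reg.name, "length": len(reg)}
        row.update(counts)
        for cls, n in counts.items():
            row[f"{cls}_density"] = n / len(reg)
        rows.append(row)
    return pd.DataFrame(rows)


def events_to_tsv(events: Sequence[DivergenceEvent], path: str | Path) -> None:
    lines = ["# position on first sequence (1-based)\tclass\tdetail"]
    lines += [f"{e.position}\t{e.cls}\t{e.detail}" for e in events]
    Path(path).write_text("\n".join(lines) + "\n")
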