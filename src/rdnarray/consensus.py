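"""Majority-rule consensus of the repeat unit from a pileup.

Concerted evolution keeps the copies of an rDNA array nearly identical, so
the most frequent base call at each position recovers the dominant repeat
variant.  Ties are broken deterministically (A < C < G < T < del) and
recorded; zero-depth positions emit N; positions where deletion wins the
majority are dropped from the emitted nucleotide sequence (a consensus must
remain a valid sequence) but are retained, as '-', in the per-position call
string so that downstream per-position bookkeeping stays aligned with the
pileup.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pileup import ALLELES, Pileup

__all__ = ["ConsensusResult", "build_consensus", "gap_report"]

_CALL_CHARS = np.array(list("ACGT-"))


@dataclass(frozen=True)
class ConsensusResult:
    """Per-position majority calls over a pileup.

    ``calls`` has one character per pileup position over {A,C,G,T,N,-};
    ``sequence`` is the same with majority-deletion ('-') positions removed.
    """

    reference_id: str
    calls: str
    winning_fraction: np.ndarray
    tie_positions: frozenset[int]
    dropped_positions: frozenset[int]

    @property
    def sequence(self) -> str:
        return self.calls.replace("-", "")

    def __len__(self) -> int:
        return len(self.calls)

    def base_at(self, position: int) -> str:
        return self.calls[position - 1]

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.reference_id}_consensus\n")
            seq = self.sequence
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    def write_reports(self, path: str | Path) -> None:
        """Tie and gap report as TSV (positions 1-based inclusive)."""
        lines = ["# kind\tstart\tend\tdetail"]
        for pos in sorted(self.tie_positions):
            lines.append(f"tie\t{pos}\t{pos}\tbroken alphabetically")
        for pos in sorted(self.dropped_positions):
            lines.append(f"majority_deletion\t{pos}\t{pos}\tdropped from sequence")
        for start, end in gap_report(self):
            lines.append(f"gap\t{start}\t{end}\tzero coverage (N)")
        Path(path).write_text("\n".join(lines) + "\n")


def build_consensus(pileup: Pileup) -> ConsensusResult:
    """Emit the most frequent base call at every position of the pileup."""
    if pileup.length == 0:
        raise ValueError("cannot build a consensus from an empty pileup")
    counts = pileup.counts
    depth = counts.sum(axis=1)
    winner = counts.argmax(axis=1)  # first max = alphabetical tie-break
    best = counts.max(axis=1)
    covered = depth > 0
    n_max = (counts == best[:, None]).sum(axis=1)
    ties = np.nonzero(covered & (n_max > 1))[0]

    calls = np.full(pileup.length, "N")
    calls[covered] = _CALL_CHARS[winner[covered]]
    frac = np.zeros(pileup.length, dtype=float)
    frac[covered] = best[covered] / depth[covered]

    dropped = np.nonzero(covered & (winner == ALLELES.index("del")))[0]
    return ConsensusResult(
        reference_id=pileup.reference_id,
        calls="".join(calls),
        winning_fraction=frac,
        tie_positions=frozenset(int(p) + 1 for p in ties),
        dropped_positions=frozenset(int(p) + 1 for p in dropped),
    )


def gap_report(consensus: ConsensusResult) -> list[tuple[int, int]]:
    """Maximal runs of N in the consensus as 1-based inclusive intervals.

    These are the stretches that saw no aligned reads and would need patching
    from external homologs before the consensus could be used as a complete
    reference; the report replaces any such gap-filling step.
    """
    runs: list[tuple[int, int]] = []
    start = None
    for i, c in enumerate(consensus.calls, 1):
        if c == "N":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(consensus.calls)))
    return runs
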