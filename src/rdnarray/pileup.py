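"""Per-position base-call tallies (pileups) over the repeat reference.

Two routes produce a pileup:

* :func:`pileup_from_sam` ingests standard SAM alignments (any external
  aligner) against the repeat unit, with an identity filter implementing the
  dual-stringency idea of mapping at 95% and then 85% maximal divergence.
* :func:`naive_map` + :func:`build_pileup` is an internal ungapped mapper,
  sufficient for simulated shotgun reads, so that end-to-end tests need no
  external aligner.  Reads are placed at the offset minimising mismatches
  under sliding comparison of both strands against the repeat unit treated as
  circular (a read spanning the junction between two tandem copies maps onto
  the unit modulo its length L, which is also where ties between copies are
  canonicalised).

The pileup is a 5-allele tally per position: A, C, G, T and deletion.
Insertions relative to the reference are kept in a side table keyed by the
preceding reference position; they contribute neither to column depth nor to
polymorphism calling, because the per-position base-call model has no
insertion slot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam
from Bio import SeqIO

from .reference import RepeatReference

__all__ = [
    "ALLELES",
    "AlignedRead",
    "PileupColumn",
    "Pileup",
    "naive_map",
    "build_pileup",
    "pileup_from_reads",
    "dual_stringency_pileup",
    "pileup_from_sam",
    "load_reads",
]

logger = logging.getLogger(__name__)

ALLELES = ("A", "C", "G", "T", "del")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3, anything else -> 4 (never matches)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        out[arr == ord(base)] = code
    return out


def _one_hot(codes: np.ndarray) -> np.ndarray:
    """(n,) int codes -> (n, 4) float32 one-hot; code 4 (N) is all-zero."""
    oh = np.zeros((codes.size, 4), dtype=np.float32)
    valid = codes < 4
    oh[np.nonzero(valid)[0], codes[valid]] = 1.0
    return oh


@dataclass(frozen=True)
class AlignedRead:
    """An ungapped placement of a read on the repeat unit.

    ``start`` is 1-based on the unit; positions wrap modulo the unit length
    for reads spanning the tandem junction.  ``bases`` is the read sequence
    oriented to the reference strand.
    """

    read_id: str
    start: int
    strand: str
    bases: str
    identity: float
    ref_length: int

    @property
    def aligned_pairs(self) -> list[tuple[int, str]]:
        L = self.ref_length
        return [
            ((self.start - 1 + k) % L + 1, b) for k, b in enumerate(self.bases)
        ]

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class PileupColumn:
    position: int
    counts: dict

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


class Pileup:
    """Base-call tallies for every position of a repeat reference.

    ``counts`` is an (L, 5) integer array in allele order A, C, G, T, del.
    """

    def __init__(self, reference_id: str, length: int):
        self.reference_id = reference_id
        self.counts = np.zeros((length, 5), dtype=np.int64)
        self.insertions: dict[int, dict[str, int]] = {}
        self.n_reads = 0
        self.n_skipped = 0

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def __len__(self) -> int:
        return self.length

    @property
    def depth(self) -> np.ndarray:
        """Per-position depth (sum of the five allele counts)."""
        return self.counts.sum(axis=1)

    @property
    def total_aligned_bases(self) -> int:
        return int(self.counts.sum())

    def column(self, position: int) -> PileupColumn:
        row = self.counts[position - 1]
        return PileupColumn(position, {a: int(c) for a, c in zip(ALLELES, row)})

    def add_base(self, position: int, base: str) -> None:
        idx = _BASE_INDEX.get(base.upper())
        if idx is not None:
            self.counts[position - 1, idx] += 1

    def add_deletion(self, position: int) -> None:
        self.counts[position - 1, 4] += 1

    def add_insertion(self, after_position: int, inserted: str) -> None:
        tab = self.insertions.setdefault(after_position, {})
        tab[inserted] = tab.get(inserted, 0) + 1

    def merged_with(self, other: "Pileup") -> "Pileup":
        if other.length != self.length or other.reference_id != self.reference_id:
            raise ValueError("cannot merge pileups over different references")
        out = Pileup(self.reference_id, self.length)
        out.counts = self.counts + other.counts
        out.insertions = {k: dict(v) for k, v in self.insertions.items()}
        for pos, tab in other.insertions.items():
            dest = out.insertions.setdefault(pos, {})
            for ins, n in tab.items():
                dest[ins] = dest.get(ins, 0) + n
        out.n_reads = self.n_reads + other.n_reads
        out.n_skipped = self.n_skipped + other.n_skipped
        return out

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# position (1-based)\tA\tC\tG\tT\tdel\tdepth\n")
            depth = self.depth
            for i in range(self.length):
                row = "\t".join(str(int(c)) for c in self.counts[i])
                fh.write(f"{i + 1}\t{row}\t{int(depth[i])}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, reference_id: str = "ref") -> "Pileup":
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            rows.append([int(x) for x in parts[1:6]])
        pl = cls(reference_id, len(rows))
        pl.counts = np.asarray(rows, dtype=np.int64)
        return pl


def load_reads(path: str | Path, fmt: str | None = None) -> list[tuple[str, str]]:
    """Read FASTA/FASTQ into (id, sequence) tuples; format sniffed from suffix."""
    p = Path(path)
    if fmt is None:
        fmt = "fastq" if p.suffix.lower() in {".fq", ".fastq"} else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(p), fmt)]


def naive_map(
    reads: Iterable[tuple[str, str]],
    ref: RepeatReference,
    max_divergence: float = 0.05,
    *,
    chunk: int = 512,
) -> list[AlignedRead]:
    """Place reads on the repeat unit by exhaustive ungapped sliding comparison.

    Each read (and its reverse complement) is compared at every offset of the
    circularised unit; the best placement wins, ties going to the smallest
    offset and the forward strand.  Reads whose best identity falls below
    ``1 - max_divergence`` are dropped.  Match counting is done as a one-hot
    matrix product so the all-offsets scan stays in BLAS.
    """
    if not 0 <= max_divergence <= 0.5:
        raise ValueError(f"max_divergence must be in [0, 0.5], got {max_divergence}")
    reads = list(reads)
    if not reads:
        return []
    L = ref.length
    max_len = max(len(s) for _, s in reads)
    if max_len >= 2 * L:
        raise ValueError(f"reads must be shorter than 2x the unit length ({2 * L})")
    # circular extension so junction-spanning reads compare contiguously
    ext = ref.sequence + ref.sequence[: max_len - 1]
    ext_oh = _one_hot(_encode(ext))  # (L + max_len - 1, 4)

    by_len: dict[int, list[int]] = {}
    for i, (_, s) in enumerate(reads):
        by_len.setdefault(len(s), []).append(i)

    results: list[AlignedRead | None] = [None] * len(reads)
    for rlen, idxs in by_len.items():
        # windows over the circularised unit: offsets 0..L-1
        win = np.lib.stride_tricks.sliding_window_view(ext_oh, rlen, axis=0)[:L]
        # win: (L, 4, rlen) -> flatten to (L, 4*rlen) with read layout (rlen, 4)
        win_flat = np.ascontiguousarray(win.transpose(0, 2, 1)).reshape(L, 4 * rlen)
        for lo in range(0, len(idxs), chunk):
            batch = idxs[lo : lo + chunk]
            fwd = np.stack([_one_hot(_encode(reads[i][1])) for i in batch])
            rev = np.stack([_one_hot(_encode(revcomp(reads[i][1]))) for i in batch])
            n = len(batch)
            fwd_m = fwd.reshape(n, 4 * rlen) @ win_flat.T  # (n, L) match counts
            rev_m = rev.reshape(n, 4 * rlen) @ win_flat.T
            fwd_best = fwd_m.argmax(axis=1)
            rev_best = rev_m.argmax(axis=1)
            for j, i in enumerate(batch):
                fb, rb = int(fwd_m[j, fwd_best[j]]), int(rev_m[j, rev_best[j]])
                if fb >= rb:
                    matches, offset, strand = fb, int(fwd_best[j]), "+"
                    bases = reads[i][1]
                else:
                    matches, offset, strand = rb, int(rev_best[j]), "-"
                    bases = revcomp(reads[i][1])
                identity = matches / rlen
                if identity >= 1.0 - max_divergence:
                    results[i] = AlignedRead(
                        read_id=reads[i][0],
                        start=offset + 1,
                        strand=strand,
                        bases=bases,
                        identity=identity,
                        ref_length=L,
                    )
    return [r for r in results if r is not None]


def build_pileup(alignments: Sequence[AlignedRead], ref: RepeatReference) -> Pileup:
    """Tally ungapped alignments into a pileup (positions wrap modulo L)."""
    pl = Pileup(ref.id, ref.length)
    L = ref.length
    for aln in alignments:
        codes = _encode(aln.bases)
        pos = (np.arange(len(codes)) + (aln.start - 1)) % L
        valid = codes < 4  # N calls are skipped
        np.add.at(pl.counts, (pos[valid], codes[valid]), 1)
        pl.n_reads += 1
    return pl


def pileup_from_reads(
    reads: Iterable[tuple[str, str]],
    ref: RepeatReference,
    max_divergence: float = 0.05,
) -> Pileup:
    """Map reads with :func:`naive_map` and tally them in one call."""
    reads = list(reads)
    alns = naive_map(reads, ref, max_divergence)
    pl = build_pileup(alns, ref)
    pl.n_skipped = len(reads) - len(alns)
    return pl


def dual_stringency_pileup(
    reads: Iterable[tuple[str, str]],
    ref: RepeatReference,
    strict: float = 0.05,
    relaxed: float = 0.15,
    *,
    residual_only: bool = True,
) -> Pileup:
    """Two-pass mapping: strict divergence first, then a relaxed pass.

    By default only the reads left unmapped by the strict pass are retried at
    the relaxed stringency (residual-first); with ``residual_only=False`` all
    reads are remapped relaxed and the strict pass is ignored, which is the
    single-pass behaviour at the relaxed threshold.
    """
    reads = list(reads)
    if not residual_only:
        return pileup_from_reads(reads, ref, relaxed)
    strict_alns = naive_map(reads, ref, strict)
    mapped_ids = {a.read_id for a in strict_alns}
    residual = [r for r in reads if r[0] not in mapped_ids]
    relaxed_alns = naive_map(residual, ref, relaxed)
    pl = build_pileup(list(strict_alns) + list(relaxed_alns), ref)
    pl.n_skipped = len(reads) - pl.n_reads
    return pl


def pileup_from_sam(
    path: str | Path,
    ref: RepeatReference,
    min_identity: float = 0.95,
) -> Pileup:
    """Tally a SAM file of alignments against the repeat unit.

    Identity is matches / aligned columns, where aligned columns are the
    match/mismatch and deletion columns of the CIGAR (insertions and clips are
    excluded from the denominator).  Reads below ``min_identity`` and unmapped
    records are skipped (counted in ``n_skipped``).  Raises if the SAM header
    names or sizes a reference that contradicts ``ref``.
    """
    pl = Pileup(ref.id, ref.length)
    refseq = ref.sequence
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        names = list(sam.references or ())
        if names:
            if ref.id not in names:
                raise ValueError(
                    f"SAM references {names} do not include reference {ref.id!r}"
                )
            declared = sam.lengths[names.index(ref.id)]
            if declared != ref.length:
                raise ValueError(
                    f"SAM declares {ref.id!r} length {declared}, reference has {ref.length}"
                )
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                pl.n_skipped += 1
                continue
            if rec.reference_name != ref.id:
                raise ValueError(
                    f"alignment of {rec.query_name!r} references {rec.reference_name!r}, "
                    f"expected {ref.id!r}"
                )
            seq = (rec.query_sequence or "").upper()
            events: list[tuple[str, int, str]] = []  # (kind, refpos0, payload)
            matches = 0
            aligned_cols = 0
            qpos = 0
            rpos = rec.reference_start  # 0-based
            for op, ln in rec.cigartuples or ():
                if op in (0, 7, 8):  # M, =, X
                    for k in range(ln):
                        base = seq[qpos + k]
                        events.append(("base", rpos + k, base))
                        if 0 <= rpos + k < len(refseq) and base == refseq[rpos + k]:
                            matches += 1
                    aligned_cols += ln
                    qpos += ln
                    rpos += ln
                elif op == 1:  # I
                    events.append(("ins", rpos - 1, seq[qpos : qpos + ln]))
                    qpos += ln
                elif op == 2:  # D
                    for k in range(ln):
                        events.append(("del", rpos + k, ""))
                    aligned_cols += ln
                    rpos += ln
                elif op == 4:  # S
                    qpos += ln
                # H (5) and P (6): nothing to consume
            if aligned_cols == 0:
                pl.n_skipped += 1
                continue
            identity = matches / aligned_cols
            if identity < min_identity:
                pl.n_skipped += 1
                continue
            for kind, rp, payload in events:
                if not 0 <= rp < ref.length:
                    continue
                if kind == "base":
                    pl.add_base(rp + 1, payload)
                elif kind == "del":
                    pl.add_deletion(rp + 1)
                else:
                    pl.add_insertion(rp + 1, payload)
            pl.n_reads += 1
    if pl.n_skipped:
        logger.info("pileup_from_sam: skipped %d records", pl.n_skipped)
    return pl
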