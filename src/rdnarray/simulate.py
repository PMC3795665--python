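"""Synthetic genomes with tandem rDNA arrays, shotgun reads, and MA series.

The generator emulates the structure the pipeline is built for: a genome
containing a tandem array of C near-identical repeat copies — one dominant
unit sequence plus low-frequency site variants carried independently by a
binomial share of copies — embedded in single-copy background, sampled by
uniformly placed shotgun reads with platform-like substitution error rates
(defaults: 4% for long-read 454-like data, 1% for short-read Illumina-like
data).  Background sequence is i.i.d. uniform with a guard that no 20-mer of
the repeat unit occurs in it, so single-copy depth is unambiguous.

Everything is reproducible: identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "ArraySpec",
    "ReadSpec",
    "GenomeTruth",
    "ReadTruth",
    "LONG_READ_ERROR_RATE",
    "SHORT_READ_ERROR_RATE",
    "simulate_genome",
    "simulate_reads",
    "simulate_ma_series",
    "write_reads_fastq",
    "write_genome_fasta",
]

LONG_READ_ERROR_RATE = 0.04   # 454-like
SHORT_READ_ERROR_RATE = 0.01  # Illumina-like

_BASES = np.array(list("ACGT"))
_GUARD_K = 20


@dataclass(frozen=True)
class ArraySpec:
    """Specification of a tandem repeat array inside a synthetic genome.

    ``variant_sites`` rows are (1-based unit position, variant base,
    frequency across copies); each copy carries each variant independently
    with its stated frequency, giving the low-frequency site variants that
    ride along with the dominant unit sequence.
    """

    copies: int
    unit_length: int
    variant_sites: tuple[tuple[int, str, float], ...] = ()
    background_length: int = 10_000
    seed: int = 0
    unit_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError(f"copy number must be >= 1, got {self.copies}")
        for pos, base, freq in self.variant_sites:
            if not 1 <= pos <= self.unit_length:
                raise ValueError(f"variant position {pos} outside unit [1, {self.unit_length}]")
            if base not in "ACGT":
                raise ValueError(f"variant base must be one of ACGT, got {base!r}")
            if not 0.0 < freq < 1.0:
                raise ValueError(f"variant frequency must be in (0, 1), got {freq}")
        if self.unit_sequence is not None and len(self.unit_sequence) != self.unit_length:
            raise ValueError("unit_sequence length does not match unit_length")


@dataclass(frozen=True)
class ReadSpec:
    read_length: int
    depth: float
    error_rate: float = SHORT_READ_ERROR_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.25:
            raise ValueError(f"error rate must be in [0, 0.25), got {self.error_rate}")
        if self.depth <= 0:
            raise ValueError(f"target depth must be positive, got {self.depth}")


@dataclass(frozen=True)
class GenomeTruth:
    """Ground truth for a simulated genome."""

    copies: int
    unit_sequence: str
    array_start: int  # 1-based position of the first array base in the genome
    variant_sites: tuple[tuple[int, str, float], ...]
    carriers: dict  # unit position -> list of copy indices carrying the variant

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["carriers"] = {str(k): v for k, v in self.carriers.items()}
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


@dataclass(frozen=True)
class ReadTruth:
    """Per-read origin coordinates (0-based genome start) and error counts."""

    starts: tuple[int, ...]
    strands: tuple[str, ...]
    n_errors: tuple[int, ...]
    total_bases: int


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _background_without_unit_kmers(
    rng: np.random.Generator, n: int, unit: str
) -> str:
    """i.i.d. background guaranteed to share no 20-mer with the repeat unit."""
    if n < _GUARD_K:
        return _random_seq(rng, n)
    kmers = {unit[i : i + _GUARD_K] for i in range(len(unit) - _GUARD_K + 1)}
    kmers |= {_revcomp(k) for k in kmers}
    for _ in range(100):  # collision probability is astronomically small
        bg = _random_seq(rng, n)
        if not any(bg[i : i + _GUARD_K] in kmers for i in range(n - _GUARD_K + 1)):
            return bg
    raise RuntimeError("could not draw a background free of unit 20-mers")


def simulate_genome(spec: ArraySpec) -> tuple[str, GenomeTruth]:
    """Background + C concatenated unit copies + background, with truth.

    The background is split evenly around the array.  If a requested variant
    base coincides with the dominant base at its position, the dominant unit
    is changed at that position so the variant is a genuine alternative.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.unit_sequence is not None:
        unit = list(spec.unit_sequence.upper())
    else:
        unit = list(_random_seq(rng, spec.unit_length))
    for pos, base, _ in spec.variant_sites:
        if unit[pos - 1] == base:
            unit[pos - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
    unit_str = "".join(unit)

    carriers: dict[int, list[int]] = {}
    copies = [unit[:] for _ in range(spec.copies)]
    for pos, base, freq in spec.variant_sites:
        carry = np.nonzero(rng.random(spec.copies) < freq)[0]
        carriers[pos] = [int(c) for c in carry]
        for c in carry:
            copies[c][pos - 1] = base

    bg_left_n = spec.background_length // 2
    bg_right_n = spec.background_length - bg_left_n
    bg_left = _background_without_unit_kmers(rng, bg_left_n, unit_str)
    bg_right = _background_without_unit_kmers(rng, bg_right_n, unit_str)
    genome = bg_left + "".join("".join(c) for c in copies) + bg_right
    truth = GenomeTruth(
        copies=spec.copies,
        unit_sequence=unit_str,
        array_start=bg_left_n + 1,
        variant_sites=spec.variant_sites,
        carriers=carriers,
    )
    return genome, truth


def simulate_reads(genome: str, spec: ReadSpec) -> tuple[list[tuple[str, str]], ReadTruth]:
    """Uniform shotgun reads with per-base substitution errors.

    The read count is depth * genome length / read length (rounded); starts
    are uniform over valid positions, strands random, and each base is
    substituted (to a uniformly chosen different base) with the spec's error
    rate.  Origins and per-read error counts are recorded as truth.
    """
    G = len(genome)
    if spec.read_length > G:
        raise ValueError(f"read length {spec.read_length} exceeds genome length {G}")
    rng = np.random.default_rng(spec.seed)
    n_reads = int(round(spec.depth * G / spec.read_length))
    starts = rng.integers(0, G - spec.read_length + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)  # 0 = '+', 1 = '-'
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    genome_codes = np.array([code[b] for b in genome], dtype=np.int8)

    reads: list[tuple[str, str]] = []
    rec_starts: list[int] = []
    rec_strands: list[str] = []
    rec_errors: list[int] = []
    for i in range(n_reads):
        s = int(starts[i])
        frag = genome_codes[s : s + spec.read_length].copy()
        if spec.error_rate > 0:
            err = rng.random(spec.read_length) < spec.error_rate
            n_err = int(err.sum())
            if n_err:
                # uniform choice among the three other bases
                frag[err] = (frag[err] + rng.integers(1, 4, size=n_err)) % 4
        else:
            n_err = 0
        seq = "".join(_BASES[frag])
        strand = "+" if strands[i] == 0 else "-"
        if strand == "-":
            seq = _revcomp(seq)
        reads.append((f"read{i:07d}", seq))
        rec_starts.append(s)
        rec_strands.append(strand)
        rec_errors.append(n_err)
    truth = ReadTruth(
        starts=tuple(rec_starts),
        strands=tuple(rec_strands),
        n_errors=tuple(rec_errors),
        total_bases=n_reads * spec.read_length,
    )
    return reads, truth


def simulate_ma_series(
    base_spec: ArraySpec,
    rate: float,
    generations: int,
    lines: int,
    *,
    jitter: int = 0,
    seed: int | None = None,
) -> tuple[list[ArraySpec], dict]:
    """Mutation-accumulation line series with a known expansion rate.

    Each line's copy number moves by round(rate * generations) plus, when
    ``jitter`` > 0, a uniform integer perturbation in [-jitter, jitter].  The
    default is noise-free so the realised rate equals the nominal one.
    Returns the per-line specs and a truth dict of realised rates.
    """
    rng = np.random.default_rng(base_spec.seed if seed is None else seed)
    specs: list[ArraySpec] = []
    realised: dict[str, float] = {}
    for k in range(lines):
        delta = int(round(rate * generations))
        if jitter > 0:
            delta += int(rng.integers(-jitter, jitter + 1))
        new_c = base_spec.copies + delta
        if new_c < 1:
            raise ValueError(
                f"line {k}: copy number would fall to {new_c}; "
                "rate * generations must exceed -C"
            )
        line_seed = int(rng.integers(0, 2**31 - 1))
        specs.append(
            ArraySpec(
                copies=new_c,
                unit_length=base_spec.unit_length,
                variant_sites=base_spec.variant_sites,
                background_length=base_spec.background_length,
                seed=line_seed,
                unit_sequence=base_spec.unit_sequence,
            )
        )
        realised[f"line{k}"] = (new_c - base_spec.copies) / generations
    return specs, {"rates": realised, "generations": generations, "base_copies": base_spec.copies}


def true_alignments(
    reads: list[tuple[str, str]],
    read_truth: ReadTruth,
    genome_truth: GenomeTruth,
    unit_length: int,
):
    """Ungapped placements on the repeat unit taken from simulator truth.

    Bypasses the mapper: every read that lies entirely inside the tandem
    array is placed at its true unit offset (genome coordinate modulo the
    unit length).  Useful for calibrating the caller itself, independently of
    mapping behaviour.
    """
    from .pileup import AlignedRead, revcomp as _rc

    L = unit_length
    array_start0 = genome_truth.array_start - 1
    array_end0 = array_start0 + genome_truth.copies * L  # exclusive
    out = []
    for (rid, seq), start, strand in zip(reads, read_truth.starts, read_truth.strands):
        if start < array_start0 or start + len(seq) > array_end0:
            continue
        bases = _rc(seq) if strand == "-" else seq
        unit_pos = (start - array_start0) % L
        out.append(
            AlignedRead(
                read_id=rid,
                start=unit_pos + 1,
                strand=strand,
                bases=bases,
                identity=1.0,
                ref_length=L,
            )
        )
    return out


def write_genome_fasta(genome: str, path: str | Path, name: str = "synthetic_genome") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(genome), 70):
            fh.write(genome[i : i + 70] + "\n")


def write_reads_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    """FASTQ with uniform placeholder qualities (the model is quality-blind)."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
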