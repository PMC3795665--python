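"""Repeat copy number from shotgun coverage ratios.

The estimator is the coverage ratio

    C = (total bases aligned to the repeat / repeat length) / D,

where D is the genome-wide sequencing depth (total sequenced bases divided by
the estimated genome size).  Because reads from every copy of the tandem
array pile onto the single reference unit, the unit's mean coverage is C
times the single-copy depth, so the ratio recovers the copy number as an
average over the whole array.

For mutation-accumulation (MA) lines the per-generation expansion rate is the
difference between the line's and the progenitor's copy estimate divided by
the generations of propagation.  Printed tables round estimates before taking
differences, so rates are computed from rounded estimates by default (the
unrounded value is always retained and the reporting precision is explicit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pileup import AlignedRead, Pileup
from .reference import Region

__all__ = [
    "CopyNumberEstimate",
    "ExpansionRate",
    "genome_depth",
    "mean_repeat_coverage",
    "estimate_copies",
    "expansion_rate",
    "estimate_from_pileup",
    "coverage_uniformity",
    "bootstrap_copy_number",
]


def _round_half_up(x: float, decimals: int = 0) -> float:
    """Round half away from zero, the convention of printed tables."""
    scale = 10.0 ** decimals
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class CopyNumberEstimate:
    """Copy-number estimate with its inputs and reporting precision."""

    mean_repeat_coverage: float
    genome_depth: float
    copies: float  # unrounded
    precision: int = 0

    @property
    def copies_reported(self) -> float:
        return _round_half_up(self.copies, self.precision)

    @property
    def mean_coverage_reported(self) -> float:
        return _round_half_up(self.mean_repeat_coverage, 0)


@dataclass(frozen=True)
class ExpansionRate:
    line_id: str
    generations: int
    rate: float  # copies per generation, sign preserved

    @property
    def rate_reported(self) -> float:
        return _round_half_up(self.rate, 4)


def genome_depth(total_sequenced_bases: float, genome_size: float) -> float:
    """Genome-wide fold coverage D = total sequenced bases / genome size."""
    if genome_size <= 0:
        raise ValueError(f"genome size must be positive, got {genome_size}")
    if total_sequenced_bases <= 0:
        raise ValueError(f"total sequenced bases must be positive, got {total_sequenced_bases}")
    return total_sequenced_bases / genome_size

def mean_repeat_coverage(total_aligned_bases: float, repeat_length: int) -> float:
    """Mean fold coverage of the repeat unit (aligned bases / unit length)."""
    if repeat_length <= 0:
        raise ValueError(f"repeat length must be positive, got {repeat_length}")
    if total_aligned_bases < 0:
        raise ValueError("total aligned bases cannot be negative")
    return total_aligned_bases / repeat_length


def estimate_copies(
    mean_coverage: float,
    depth: float,
    precision: int = 0,
) -> CopyNumberEstimate:
    """Copy number C = mean repeat coverage / genome depth.

    ``precision`` is the number of decimals used for reporting; 0 suits
    low-depth (454-like) data, 1 suits high-depth (Illumina-like) data.
    """
    if depth <= 0:
        raise ValueError(f"genome depth must be positive, got {depth}")
    return CopyNumberEstimate(
        mean_repeat_coverage=mean_coverage,
        genome_depth=depth,
        copies=mean_coverage / depth,
        precision=precision,
    )


def expansion_rate(
    c_line: float,
    c_progenitor: float,
    generations: int,
    line_id: str = "",
) -> ExpansionRate:
    """Per-generation change in copy number; contractions give negative rates."""
    if generations <= 0:
        raise ValueError(f"generations must be positive, got {generations}")
    return ExpansionRate(
        line_id=line_id,
        generations=generations,
        rate=(c_line - c_progenitor) / generations,
    )


def estimate_from_pileup(
    pileup: Pileup,
    depth: float,
    precision: int = 0,
) -> CopyNumberEstimate:
    """Copy number straight from a repeat pileup and a genome depth."""
    return estimate_copies(
        mean_repeat_coverage(pileup.total_aligned_bases, pileup.length),
        depth,
        precision,
    )


def coverage_uniformity(pileup: Pileup, regions: Iterable[Region]) -> pd.DataFrame:
    """Check each region's mean depth against the whole-repeat depth spread.

    Returns one row per region with the region mean, the whole-repeat mean
    and population standard deviation of per-position depth, and a flag set
    when the region mean lies within one standard deviation of the repeat
    mean.  A sub-repeat segment present at extra copies (a partial
    duplication) shows up as a region flagged outside.
    """
    regions = list(regions)
    depth = pileup.depth.astype(float)
    overall_mean = float(depth.mean())
    overall_sd = float(depth.std())  # population SD over positions
    rows = []
    for reg in regions:
        if len(reg) == 0:
            raise ValueError(f"region {reg.name!r} is empty")
        seg = depth[reg.start - 1 : reg.end]
        mean = float(seg.mean())
        rows.append(
            {
                "region": reg.name,
                "start": reg.start,
                "end": reg.end,
                "region_mean_depth": mean,
                "repeat_mean_depth": overall_mean,
                "repeat_sd_depth": overall_sd,
                "within_one_sd": bool(abs(mean - overall_mean) <= overall_sd),
            }
        )
    return pd.DataFrame(rows)


def bootstrap_copy_number(
    alignments: Sequence[AlignedRead],
    n_total_reads: int,
    repeat_length: int,
    depth: float,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Bootstrap CI for the copy estimate by resampling reads.

    Resamples per-read aligned-base contributions with replacement over the
    *whole* read set — reads that did not align to the repeat contribute
    zero, and that is where the sampling variance of the coverage ratio
    lives — and recomputes the estimate; returns (point, lo, hi) at the
    requested confidence level.
    """
    if not alignments:
        raise ValueError("no alignments to resample")
    if n_total_reads < len(alignments):
        raise ValueError("n_total_reads smaller than the number of alignments")
    contrib = np.zeros(n_total_reads, dtype=float)
    contrib[: len(alignments)] = [len(a) for a in alignments]
    point = contrib.sum() / repeat_length / depth
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, contrib.size, size=(n_boot, contrib.size))
    totals = contrib[idx].sum(axis=1)
    estimates = totals / repeat_length / depth
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(estimates, [alpha, 1.0 - alpha])
    return float(point), float(lo), float(hi)
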