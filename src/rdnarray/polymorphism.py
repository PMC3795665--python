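"""Intragenomic polymorphism calling with a coverage-scaled error filter.

Every copy of the array contributes reads to each unit position, so a variant
carried by even a single repeat copy is expected to appear in ~D reads, where
D is the genome-wide depth.  Sequencing errors, by contrast, are not expected
to recur at one position as the same allele.  The filter therefore requires a
non-consensus allele to be seen in at least 50% of the 1x coverage depth —
ceil(0.5 * D) identical base calls (at 10x, at least five) — with a floor of
two so that 1x datasets cannot call polymorphisms from single reads.

The threshold is dataset-level by default (scaled to the genome depth, which
is the per-copy depth of the array); a per-site variant scaled to each site's
own pooled depth is available behind ``per_site=True``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .consensus import ConsensusResult
from .pileup import ALLELES, Pileup
from .reference import Region

__all__ = [
    "PolymorphismCall",
    "WindowProfile",
    "polymorphism_threshold",
    "call_polymorphisms",
    "window_profile",
    "region_summary",
    "calls_to_tsv",
    "calls_to_vcf",
]


@dataclass(frozen=True)
class PolymorphismCall:
    position: int
    consensus_base: str
    variant_base: str  # 'A', 'C', 'G', 'T' or 'del'
    variant_count: int
    site_depth: int
    threshold: int
    passed: bool


@dataclass(frozen=True)
class WindowProfile:
    window_start: int
    window_length: int
    polymorphic_fraction: float


def polymorphism_threshold(depth: float) -> int:
    """Minimum identical non-consensus calls: ceil(0.5 * D), floored at 2."""
    if depth <= 0:
        raise ValueError(f"coverage depth must be positive, got {depth}")
    return max(2, math.ceil(0.5 * depth))


def call_polymorphisms(
    pileup: Pileup,
    consensus: ConsensusResult,
    depth: float,
    *,
    per_site: bool = False,
) -> list[PolymorphismCall]:
    """Emit a call for every non-consensus allele observed at least once.

    ``passed`` marks calls meeting the error-filtering threshold.  Positions
    whose consensus is N (no coverage) emit nothing.  With ``per_site=True``
    the threshold is ceil(0.5 * site depth) instead of the dataset-level
    ceil(0.5 * D).
    """
    if len(consensus) != pileup.length:
        raise ValueError(
            f"consensus length {len(consensus)} does not match pileup length {pileup.length}"
        )
    base_threshold = polymorphism_threshold(depth)
    depths = pileup.depth
    calls: list[PolymorphismCall] = []
    for pos0 in np.nonzero(pileup.counts.sum(axis=1) > 0)[0]:
        cons = consensus.calls[pos0]
        if cons == "N":
            continue
        cons_allele = "del" if cons == "-" else cons
        site_depth = int(depths[pos0])
        thr = max(2, math.ceil(0.5 * site_depth)) if per_site else base_threshold
        for a_idx, allele in enumerate(ALLELES):
            count = int(pileup.counts[pos0, a_idx])
            if count == 0 or allele == cons_allele:
                continue
            calls.append(
                PolymorphismCall(
                    position=int(pos0) + 1,
                    consensus_base=cons,
                    variant_base=allele,
                    variant_count=count,
                    site_depth=site_depth,
                    threshold=thr,
                    passed=count >= thr,
                )
            )
    return calls


def _passed_positions(calls: Iterable[PolymorphismCall]) -> set[int]:
    return {c.position for c in calls if c.passed}


def window_profile(
    calls: Sequence[PolymorphismCall],
    length: int,
    window: int = 50,
    step: int = 1,
) -> list[WindowProfile]:
    """Fraction of polymorphic positions in a sliding window along the unit.

    A position counts once however many variant alleles passed there.  One
    profile is produced per start 1..L-window+1.
    """
    if window > length:
        raise ValueError(f"window {window} exceeds reference length {length}")
    flags = np.zeros(length, dtype=float)
    for pos in _passed_positions(calls):
        flags[pos - 1] = 1.0
    csum = np.concatenate([[0.0], np.cumsum(flags)])
    out = []
    for start0 in range(0, length - window + 1, step):
        frac = (csum[start0 + window] - csum[start0]) / window
        out.append(WindowProfile(start0 + 1, window, float(frac)))
    return out


def region_summary(
    calls: Sequence[PolymorphismCall],
    regions: Iterable[Region],
    length: int,
) -> pd.DataFrame:
    """Passed-position count, length and density per region.

    Adds aggregate rows for coding regions (18S/5.8S/26S-28S by name), for
    the remainder of the unit (noncoding spacers), and for the whole unit.
    """
    regions = list(regions)
    passed = _passed_positions(calls)
    rows = []
    coding_positions: set[int] = set()
    region_positions: set[int] = set()
    for reg in regions:
        span = set(range(reg.start, reg.end + 1))
        region_positions |= span
        if reg.coding:
            coding_positions |= span
        hits = len(passed & span)
        rows.append(
            {
                "region": reg.name,
                "length": len(span),
                "polymorphic_positions": hits,
                "density": hits / len(span),
            }
        )
    everything = set(range(1, length + 1))
    noncoding = everything - coding_positions
    for name, span in (
        ("coding", coding_positions),
        ("noncoding", noncoding),
        ("whole_repeat", everything),
    ):
        hits = len(passed & span)
        rows.append(
            {
                "region": name,
                "length": len(span),
                "polymorphic_positions": hits,
                "density": hits / len(span) if span else 0.0,
            }
        )
    return pd.DataFrame(rows)


def calls_to_tsv(calls: Sequence[PolymorphismCall], path: str | Path) -> None:
    lines = ["# position (1-based)\tconsensus\tvariant\tcount\tdepth\tthreshold\tpassed"]
    for c in calls:
        lines.append(
            f"{c.position}\t{c.consensus_base}\t{c.variant_base}\t{c.variant_count}"
            f"\t{c.site_depth}\t{c.threshold}\t{int(c.passed)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def calls_to_vcf(
    calls: Sequence[PolymorphismCall],
    path: str | Path,
    reference_id: str,
    reference_length: int,
    *,
    passed_only: bool = True,
) -> None:
    """Minimal VCF of the calls (CHROM = repeat id, 1-based POS).

    Deletion alleles are written with the symbolic ALT ``<DEL>`` since the
    caller has no anchored-indel representation.  INFO carries the variant
    count, the pooled site depth and the threshold used.
    """
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={reference_id},length={reference_length}>",
        '##INFO=<ID=VC,Number=1,Type=Integer,Description="Variant base-call count">',
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Pooled site depth">',
        '##INFO=<ID=THR,Number=1,Type=Integer,Description="Error-filter threshold">',
        '##FILTER=<ID=lowcount,Description="Below the coverage-scaled threshold">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    lines = list(header)
    for c in calls:
        if passed_only and not c.passed:
            continue
        if c.consensus_base == "-":
            continue  # no anchored representation for a majority-deletion site
        alt = "<DEL>" if c.variant_base == "del" else c.variant_base
        filt = "PASS" if c.passed else "lowcount"
        lines.append(
            f"{reference_id}\t{c.position}\t.\t{c.consensus_base}\t{alt}\t.\t{filt}"
            f"\tVC={c.variant_count};DP={c.site_depth};THR={c.threshold}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
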