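"""The Vg/Vm purifying-selection test on rDNA repeat variation.

Under neutrality in a diploid, the standing per-site genetic variation Vg in
a natural isolate and the per-site per-generation mutational variation Vm
accumulated in mutation-accumulation (MA) lines satisfy Vg/Vm = 4*Ne.  MA
lines are propagated through single-individual bottlenecks, so all but the
most deleterious mutations accumulate free of selection; if the observed
ratio implies an effective population size orders of magnitude below the
independently estimated Ne, standing variation is being removed — purifying
selection.

The per-site variation estimator used here is the Gini-Simpson diversity of
the pooled base calls, h_i = 1 - sum_b (count_b / depth_i)^2; it is isolated
behind :func:`per_site_diversity` so an alternative estimator can be swapped
in without touching the downstream arithmetic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .consensus import ConsensusResult
from .pileup import Pileup

__all__ = [
    "DiversityResult",
    "SelectionStats",
    "per_site_diversity",
    "vm_per_generation",
    "vg_vm_test",
    "selection_verdict",
    "round_sig",
]


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (half away from zero)."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    scale = 10.0 ** (sig - 1 - exponent)
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x > 0 else -1)


@dataclass(frozen=True)
class DiversityResult:
    """Mean per-site Gini-Simpson diversity with its SEM."""

    mean: float
    sem: float
    n_sites: int
    n_zero_depth: int
    per_site: np.ndarray

    def block_bootstrap_ci(
        self,
        block: int = 1000,
        n_boot: int = 1000,
        level: float = 0.95,
        seed: int | None = None,
    ) -> tuple[float, float]:
        """Block-bootstrap CI for the mean, for autocorrelated sites."""
        h = self.per_site
        n_blocks = max(1, h.size // block)
        blocks = [h[k * block : (k + 1) * block] for k in range(n_blocks)]
        rng = np.random.default_rng(seed)
        means = np.empty(n_boot)
        for t in range(n_boot):
            idx = rng.integers(0, n_blocks, size=n_blocks)
            means[t] = np.concatenate([blocks[i] for i in idx]).mean()
        alpha = (1 - level) / 2
        lo, hi = np.quantile(means, [alpha, 1 - alpha])
        return float(lo), float(hi)


@dataclass(frozen=True)
class SelectionStats:
    vg: float
    vm_per_line: tuple[float, ...]
    joint_vm: float
    ratio: float
    ne_implied: float

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["vm_per_line"] = list(d["vm_per_line"])
        Path(path).write_text(json.dumps(d, indent=2) + "\n")


def per_site_diversity(pileup: Pileup, consensus: ConsensusResult | None = None) -> DiversityResult:
    """Per-site Gini-Simpson diversity h_i = 1 - sum_b (count_b/depth)^2.

    Sites with zero depth are excluded from the mean and counted separately.
    The consensus argument is accepted for interface symmetry with the
    calling pipeline but the estimator depends only on the pooled tallies.
    """
    counts = pileup.counts.astype(float)
    depth = counts.sum(axis=1)
    covered = depth > 0
    n_zero = int((~covered).sum())
    if not covered.any():
        raise ValueError("no covered sites: cannot estimate diversity")
    freqs = counts[covered] / depth[covered, None]
    h = 1.0 - (freqs**2).sum(axis=1)
    mean = float(h.mean())
    sem = float(h.std(ddof=1) / math.sqrt(h.size)) if h.size > 1 else 0.0
    return DiversityResult(mean=mean, sem=sem, n_sites=int(h.size), n_zero_depth=n_zero, per_site=h)


def vm_per_generation(diversity_mean: float, generations: int) -> float:
    """Mutational variation per site per generation: accumulated diversity / t."""
    if generations <= 0:
        raise ValueError(f"generations must be positive, got {generations}")
    return diversity_mean / generations


def vg_vm_test(vg: float, vm_list: Sequence[float], rounding: int = 3) -> SelectionStats:
    """Combine Vg with per-line Vm into the ratio and the implied Ne.

    The joint Vm is the unweighted arithmetic mean across lines, rounded to
    ``rounding`` significant figures before the ratio is taken (matching how
    such tables are printed); Ne = (Vg/Vm) / 4 exactly.
    """
    if not vm_list:
        raise ValueError("need at least one per-line Vm")
    if any(v <= 0 for v in vm_list):
        raise ValueError(f"all per-line Vm must be positive, got {list(vm_list)}")
    joint = sum(vm_list) / len(vm_list)
    if rounding is not None:
        joint = round_sig(joint, rounding)
    ratio = vg / joint
    return SelectionStats(
        vg=vg,
        vm_per_line=tuple(vm_list),
        joint_vm=joint,
        ratio=ratio,
        ne_implied=ratio / 4.0,
    )


def selection_verdict(stats: SelectionStats, reference_ne: float) -> dict:
    """Compare the implied Ne against an independent Ne estimate.

    Flags purifying selection when the implied Ne sits at least two orders of
    magnitude below the reference; reports the order-of-magnitude gap.
    """
    if reference_ne <= 0:
        raise ValueError(f"reference Ne must be positive, got {reference_ne}")
    gap = math.log10(reference_ne / stats.ne_implied) if stats.ne_implied > 0 else math.inf
    return {
        "ne_implied": stats.ne_implied,
        "reference_ne": reference_ne,
        "orders_of_magnitude_gap": round(gap),
        "purifying_selection": gap >= 2.0,
    }
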