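#!/usr/bin/env python
"""Divergence classes between two species' consensus repeats.

Simulates a pair of diverged consensus units — transition-biased substitution
in the gene regions, transversion- and indel-rich divergence in the spacer —
aligns them globally, classifies every divergent column, and tabulates event
classes per region.  Writes results/divergence_events.tsv and
results/divergence_by_region.tsv.
"""

from pathlib import Path

import numpy as np

from rdnarray import Region, align_pair, classify_events, region_divergence
from rdnarray.divergence import events_to_tsv

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 53
L = 800
GENE_A = Region("18S", 1, 300)
SPACER = Region("ITS", 301, 500)
GENE_B = Region("26S", 501, 800)

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSION = {"A": "T", "T": "A", "C": "G", "G": "C"}


def main() -> None:
    rng = np.random.default_rng(SEED)
    unit_a = "".join(rng.choice(list("ACGT"), L))
    other = list(unit_a)
    # gene regions: sparse, transition-biased
    for p in rng.choice(np.arange(0, 300), 6, replace=False):
        other[p] = TRANSITION[other[p]]
    for p in rng.choice(np.arange(500, 800), 8, replace=False):
        other[p] = TRANSITION[other[p]]
    # spacer: dense transversions plus an indel
    for p in rng.choice(np.arange(300, 460), 20, replace=False):
        other[p] = TRANSVERSION[other[p]]
    del other[470:478]  # 8 bp deletion in the spacer
    unit_b = "".join(other)

    aln = align_pair(unit_a, unit_b)
    events, totals = classify_events(aln)
    print(f"alignment score {aln.score}; event totals: {totals}")

    OUT.mkdir(exist_ok=True)
    events_to_tsv(events, OUT / "divergence_events.tsv")
    table = region_divergence(events, [GENE_A, SPACER, GENE_B])
    table.to_csv(OUT / "divergence_by_region.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    gene_len = len(GENE_A) + len(GENE_B)
    gene_tv = table[table.region.isin(["18S", "26S"])].transversion.sum() / gene_len
    spacer_tv = table[table.region == "ITS"].transversion.sum() / len(SPACER)
    print(
        f"\nTransversion density: spacer {spacer_tv:.4f} vs genes {gene_tv:.4f}; "
        f"complex events (indels/inversions) fall in the spacer, matching the "
        f"signature of purifying selection on rRNA coding function."
    )


if __name__ == "__main__":
    main()
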