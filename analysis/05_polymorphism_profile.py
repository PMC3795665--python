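#!/usr/bin/env python
"""Intragenomic polymorphism along a simulated rDNA array.

Builds an array whose low-frequency variants are concentrated in the gene
regions (as observed within Caenorhabditis genomes), sequences it, calls
polymorphisms with the coverage-scaled threshold, and summarises the calls by
region and by 50 bp sliding window.  Writes results/polymorphism_regions.tsv
and results/polymorphism_windows.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rdnarray import (
    ArraySpec,
    ReadSpec,
    Region,
    RepeatReference,
    build_consensus,
    build_pileup,
    call_polymorphisms,
    naive_map,
    region_summary,
    simulate_genome,
    simulate_reads,
    window_profile,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 47
L = 900
REGIONS = [Region("18S", 101, 300), Region("ITS", 301, 420), Region("26S", 421, 820)]
D = 10


def main() -> None:
    rng = np.random.default_rng(SEED)
    coding_pos = np.concatenate(
        [rng.choice(np.arange(101, 301), 18, replace=False),
         rng.choice(np.arange(421, 821), 18, replace=False)]
    )
    spacer_pos = rng.choice(np.arange(301, 421), 9, replace=False)
    bases = rng.choice(list("ACGT"), coding_pos.size + spacer_pos.size)
    freqs = rng.uniform(0.05, 0.45, coding_pos.size + spacer_pos.size)
    variants = tuple(
        (int(p), str(b), float(f))
        for p, b, f in zip(np.concatenate([coding_pos, spacer_pos]), bases, freqs)
    )
    spec = ArraySpec(copies=150, unit_length=L, background_length=12_000, seed=SEED,
                     variant_sites=variants)
    genome, truth = simulate_genome(spec)
    reads, rt = simulate_reads(
        genome, ReadSpec(read_length=80, depth=D, error_rate=0.0, seed=SEED + 1)
    )
    ref = RepeatReference("unit", truth.unit_sequence, regions=tuple(REGIONS))
    pl = build_pileup(naive_map(reads, ref, 0.15), ref)
    cons = build_consensus(pl)
    calls = call_polymorphisms(pl, cons, D)
    n_passed = len({c.position for c in calls if c.passed})
    print(f"{n_passed} polymorphic positions called over a {L} bp unit "
          f"({len(variants)} variants planted)")

    OUT.mkdir(exist_ok=True)
    regions_table = region_summary(calls, REGIONS, L)
    regions_table.to_csv(OUT / "polymorphism_regions.tsv", sep="\t", index=False)
    print(regions_table.to_string(index=False))

    profiles = window_profile(calls, L, window=50)
    win = pd.DataFrame(
        {"window_start": [p.window_start for p in profiles],
         "polymorphic_fraction": [p.polymorphic_fraction for p in profiles]}
    )
    win.to_csv(OUT / "polymorphism_windows.tsv", sep="\t", index=False)
    peak = win.loc[win.polymorphic_fraction.idxmax()]
    print(
        f"\nPeak window: start {int(peak.window_start)}, "
        f"{peak.polymorphic_fraction:.0%} polymorphic positions "
        f"(cf. the >20% windows seen in the most variable genomes)."
    )


if __name__ == "__main__":
    main()
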