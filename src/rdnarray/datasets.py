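"""Published whole-genome-shotgun summary inputs used as worked examples.

These are the printed per-dataset summaries for the six-nematode rDNA survey
and the C. elegans mutation-accumulation (MA) experiment: total bases aligned
to the repeat, repeat unit length, genome-wide coverage depth, generations of
propagation, and the Vg/Vm inputs measured on the natural isolate CB4856 and
three 454-sequenced MA lines.  They are data, not tuning knobs: the analysis
scripts and the acceptance run recompute every derived quantity (mean repeat
coverage, copy estimates, expansion rates, the Vg/Vm ratio and the implied
Ne) from these inputs.

Note: Coverage Depth and rDNA Coverage for MA lines 523 and 526 are printed
rounded; recomputing their one-decimal repeat estimates from them lands 0.1
above the printed values (132.5 vs 132.4, 165.9 vs 165.8).  The recomputed
values are what this package reports.
"""

from __future__ import annotations

__all__ = [
    "SPECIES_WGS",
    "MA_LINES",
    "MA_PROGENITOR",
    "VG_CB4856",
    "VG_CB4856_SEM",
    "VM_PER_LINE",
    "VM_PER_LINE_SEM",
    "REFERENCE_NE",
]

#: Six-species survey: total bases aligned to the rDNA unit, unit length (bp),
#: genome-wide coverage depth (x), and approximate genome size (Mb).
SPECIES_WGS: dict[str, dict] = {
    "C. brenneri": dict(total_bases=21_261_492, repeat_length=6_929, coverage_depth=9.5, genome_size_mb=150),
    "C. remanei": dict(total_bases=11_679_749, repeat_length=6_921, coverage_depth=9.2, genome_size_mb=135),
    "C. briggsae": dict(total_bases=3_853_734, repeat_length=6_830, coverage_depth=10.0, genome_size_mb=104),
    "C. japonica": dict(total_bases=4_943_716, repeat_length=6_825, coverage_depth=6.3, genome_size_mb=135),
    "B. malayi": dict(total_bases=9_773_484, repeat_length=7_330, coverage_depth=8.9, genome_size_mb=90),
    "P. pacificus": dict(total_bases=11_396_247, repeat_length=6_261, coverage_depth=8.9, genome_size_mb=169),
}

#: C. elegans N2 progenitor: mean rDNA coverage (x), genome depth (x), and the
#: reporting precision used for its Illumina-depth estimate (one decimal).
MA_PROGENITOR: dict = dict(line="N2", rdna_coverage=1_295, coverage_depth=11.50, precision=1)

#: MA lines: generations of single-individual bottleneck propagation,
#: genome depth, mean rDNA coverage, sequencing technology, and the reporting
#: precision (integer for the low-depth 454 lines, one decimal for Illumina).
MA_LINES: dict[str, dict] = {
    "MA41": dict(generations=400, coverage_depth=1.9, rdna_coverage=392, technology="454", precision=0),
    "MA83": dict(generations=373, coverage_depth=3.1, rdna_coverage=387, technology="454", precision=0),
    "MA99": dict(generations=420, coverage_depth=2.8, rdna_coverage=716, technology="454", precision=0),
    "MA523": dict(generations=250, coverage_depth=9.55, rdna_coverage=1_265, technology="Illumina", precision=1),
    "MA526": dict(generations=250, coverage_depth=7.38, rdna_coverage=1_224, technology="Illumina", precision=1),
    "MA529": dict(generations=250, coverage_depth=12.41, rdna_coverage=1_727, technology="Illumina", precision=1),
    "MA538": dict(generations=250, coverage_depth=12.38, rdna_coverage=1_866, technology="Illumina", precision=1),
    "MA545": dict(generations=250, coverage_depth=7.01, rdna_coverage=839, technology="Illumina", precision=1),
    "MA553": dict(generations=250, coverage_depth=10.08, rdna_coverage=1_228, technology="Illumina", precision=1),
    "MA574": dict(generations=250, coverage_depth=17.47, rdna_coverage=2_532, technology="Illumina", precision=1),
}

#: Standing per-site variation in the natural isolate CB4856.
VG_CB4856: float = 0.0009
VG_CB4856_SEM: float = 3.9e-5

#: Per-site per-generation mutational variation in the three 454 MA lines.
VM_PER_LINE: dict[str, float] = {"MA41": 2.99e-5, "MA83": 1.36e-5, "MA99": 1.82e-5}
VM_PER_LINE_SEM: dict[str, float] = {"MA41": 1.11e-6, "MA83": 7.36e-7, "MA99": 5.90e-7}

#: Independent C. elegans effective population size (from mutation rate and
#: silent-site diversity), the null against which the implied Ne is judged.
REFERENCE_NE: float = 1e6
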