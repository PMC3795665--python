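# Methods

## Model and coordinate conventions

The object of study is one rDNA repeat unit of length *L* (≈6.3–7.3 kb in
the nematode datasets), tandemly repeated *C* times in a genome otherwise
treated as single-copy. All coordinates are 1-based inclusive on the unit;
file outputs state this in their headers. The pileup model is 4-allele
(A/C/G/T) plus a fifth deletion allele; IUPAC ambiguity codes other than N
are rejected at reference load rather than folded, because every downstream
tally assumes an unambiguous allele space.

The default region annotation ships the printed gene boundaries of the
*C. elegans* unit — 18S 2694–3157, 5.8S 3311–3694, 26S 3695–7203 — and is
fully user-overridable. The printed 18S interval is anomalously short for an
18S gene (~1.7 kb is typical); it is shipped verbatim as published, and
nothing in the package depends on its biological plausibility.

## Copy-number estimator

With genome-wide depth `D = total sequenced bases / genome size`, the unit's
mean coverage is `C·D` in expectation, so

&nbsp;&nbsp;&nbsp;&nbsp;`C = (bases aligned to the unit / L) / D`.

The estimate is an average over the whole array; no per-unit deconvolution
is attempted (none is possible from pooled depth alone). Unrounded values
are kept internally; the *reporting* precision is explicit per dataset —
integer for low-depth (454-like, 2–3×) datasets, one decimal for high-depth
(Illumina-like) ones — and rounding is half-away-from-zero. MA-line
expansion rates `(C_line − C_progenitor)/t` are computed from the *rounded*
estimates by default, because that is how the published table was assembled;
an unrounded mode is available. Two published MA lines (523, 526) have
inputs printed at a precision too coarse to reproduce their printed
estimates exactly; recomputation lands 0.1 above, and the recomputed values
are what this package reports.

Coverage uniformity across regions is tested against the population
standard deviation of per-position depth over the whole unit; a region is
flagged when its mean depth leaves the ±1 SD band. A sub-repeat duplication
(one region at extra copy depth) is the alternative this detects.

Sampling uncertainty comes from a read-resampling bootstrap: per-read
aligned-base contributions — zero for reads that did not align to the unit,
which is where the variance of the coverage ratio lives — are resampled with
replacement and the estimator recomputed (default 1000 replicates,
percentile 95% CI).

## Mapping

The published pipeline used external assemblers/aligners; the contribution
being downstream of alignment, this package (a) ingests standard SAM against
the unit, with identity = matches/aligned columns and a dual-stringency
convention (95%, then 85% on the residue — the residual-first reading of the
two-pass idea; a single-pass mode exists), and (b) provides an internal
exhaustive ungapped mapper for synthetic data: each read and its reverse
complement is compared at every offset of the unit treated as circular, so
junction-spanning reads place correctly modulo *L*; the best placement wins,
ties canonicalised to the smallest offset (all analyses are per-unit, so any
offset congruent modulo *L* is equivalent). Reads below the identity floor
are dropped. Match counting is a one-hot matrix product, which keeps the
all-offsets scan in BLAS. Reads straddling the array/background boundary are
dropped by the identity filter; at 10× and 80 bp reads this biases total
aligned bases down by <0.2% for the smallest surveyed array, well inside the
bootstrap CI. Deletions tally as the fifth allele; insertions go to a side
table keyed by the preceding reference position and contribute to neither
depth nor polymorphism calling, since the per-position base-call model has
no insertion slot.

## Consensus

Majority base call per position; zero-depth positions emit N; ties are
broken deterministically (A < C < G < T < del) and recorded. If deletion
wins a position it is dropped from the emitted sequence (a consensus must
be a valid nucleotide string) but kept as '-' in the per-position call
string, so per-position bookkeeping stays aligned with the pileup. Gap
reporting (maximal N runs) replaces any homolog-based gap filling, which
would require external databases.

## Polymorphism calling

Threshold: a non-consensus allele passes when its count reaches
`max(2, ⌈D/2⌉)` — 50% of 1× coverage depth, so five identical calls at 10×.
The floor of 2 prevents single-read calls in ~1× datasets. The threshold is
*dataset-level* (scaled to the genome depth, which is the per-copy depth of
the array); the per-site variant `⌈site depth/2⌉` sits behind a flag. The
"identical calls" are required to be the variant allele, not just any allele
(the alternative is trivially satisfied by the consensus).

Why this works, and when it stops working: a variant carried by a fraction
*f* of *C* copies is supported by ~`f·C·D` reads against a threshold of
`⌈D/2⌉`, so detection power for *f* ≥ 0.5 is ≈1 at any surveyed *C*, and
power is monotone in *f* when measured against the ancestral dominant unit.
Conversely the threshold bounds sequencing-error false calls only while the
expected per-allele error count `(C·D)·e/3` stays below `⌈D/2⌉`, i.e. while
`C < 3/(2e)` (≈37 copies at 4% error, ≈150 at 1%). Beyond that regime,
error alleles recur often enough to pass, and region-level contrasts should
be read as variant-plus-error densities. The false-positive calibration is
therefore run at pooled site depth equal to *D* (identical copies collapse
to a single copy sequenced at the pooled depth), where the per-allele pass
rate is bounded by the binomial tail `P[Bin(D, e) ≥ threshold]` — the bound
holds with ~3× margin because errors split over three alternative alleles.

Window profiles use a 50 bp window at step 1 (sliding, with no stated step,
is read as step 1); a position counts once regardless of how many alleles
passed there. Region summaries add coding (18S/5.8S/26S-28S by name) versus
noncoding aggregates.

## Divergence classification

Global Needleman–Wunsch/Gotoh alignment: match +1, mismatch −1, gap of
length *k* costing −2 − 0.5(*k*−1) (the open-plus-extend convention of
Biopython's `PairwiseAligner`, against which scores are cross-checked in
tests; short pairs are checked against exhaustive enumeration of all
alignments). Scores are computed in doubled integers so ties are exact, and
traceback preference is diagonal, then up, then left. The input pair is
canonicalised lexicographically before the DP and transposed back, which
makes event class totals exactly symmetric in argument order even at
traceback ties.

Event rules: each mismatch column is a transition (A↔G, C↔T) or
transversion; each maximal gap run is one complex event; gap runs separated
by fewer than 3 aligned columns merge into one complex event; a gapless
mismatch run of length ≥ 4 equal to the reverse complement of its partner is
one complex (inversion) event. The merge distance (3) and minimum inversion
length (4) are pragmatic constants with no published operational definition
behind them; both are parameters. Multi-base indels count as one event, not
per base. Events are reported in first-sequence coordinates with a
coordinate map to the second.

## Selection test

Per-site variation is the Gini–Simpson diversity of pooled base calls,
`h_i = 1 − Σ_b (count_b/depth_i)²`; Vg is its mean over covered sites with
SEM from site-level dispersion (a 1 kb block bootstrap is available for
autocorrelation). The estimator is isolated behind one function so an
alternative can be substituted — the published numbers cite an external
estimator without formulas, so only the downstream arithmetic is reproduced
from the published inputs. Vm is accumulated diversity divided by
generations. The joint Vm is the unweighted mean across lines, rounded to 3
significant figures before the ratio (this reproduces the printed chain
2.06×10⁻⁵ → 43.69 → 10.9 exactly); Ne = (Vg/Vm)/4 identically. The verdict
flags purifying selection at ≥ 2 orders of magnitude between implied and
reference Ne.

## Synthetic data

The generator emulates the study conditions: a dominant unit with site
variants carried independently by a Binomial(*C*, *f*) share of copies
(*f* ∈ (0,1); *f* = 1 is rejected — a fixed difference is not a variant);
i.i.d. uniform background split around the array, with a guard that no
20-mer of the unit (either strand) occurs in it, so single-copy depth is
unambiguous; uniformly placed reads at a target depth with per-base
substitution errors (defaults 4% long-read-like, 1% short-read-like; indel
errors are off by default, switchable). Read placement has no
fragment-length structure — the analyses consume only depth. MA series move
each line's copy number by `round(rate·t)`; integer jitter is optional and
off by default so the nominal rate is realised exactly. Identical seeds give
byte-identical outputs.

What the simulations do *not* emulate: platform-specific error profiles
(454 homopolymer indels, quality-correlated Illumina errors), GC or
mappability bias in depth, gene conversion/recombination within arrays, and
divergence among array loci. Passing recovery tests therefore validate the
estimators under uniform sampling, not robustness to those real-data
artefacts; the published uniformity-of-coverage check is the empirical
control for the depth-uniformity assumption.

## Problem sizes and numerical choices

Validation runs use 300 bp units (900–2000 bp where region structure
matters), arrays of 56–323 copies, 15 kb background, 80–100 bp reads at
10–30×, five replicates per copy-number point; at these sizes the full
suite runs in about a minute and recovery CIs are a few copies wide, which
is the same relative scale as the real datasets' sampling error. Bootstrap
CIs are percentile with 500–1000 replicates. CI-coverage assertions test the
*frequency* of coverage across replicates against a pre-set binomial bound
(e.g. ≥25/30 successes for a 95% interval), not a single draw. All
simulation seeds are fixed or derived from a single CLI seed.
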