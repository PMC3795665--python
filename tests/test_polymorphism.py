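import itertools
import math

import numpy as np
import pytest
from scipy.stats import binom

from rdnarray import (
    ArraySpec,
    ReadSpec,
    Region,
    RepeatReference,
    build_consensus,
    build_pileup,
    call_polymorphisms,
    polymorphism_threshold,
    region_summary,
    simulate_genome,
    simulate_reads,
    window_profile,
)
from rdnarray.consensus import ConsensusResult
from rdnarray.simulate import true_alignments


def ancestral_consensus(unit: str) -> ConsensusResult:
    return ConsensusResult("unit", unit, np.ones(len(unit)), frozenset(), frozenset())


class TestThreshold:
    @pytest.mark.parametrize("depth,expected", [(10, 5), (9.5, 5), (2, 2), (1, 2), (6.3, 4)])
    def test_half_depth_rounded_up_with_floor_two(self, depth, expected):
        assert polymorphism_threshold(depth) == expected

    def test_nonpositive_depth_raises(self):
        with pytest.raises(ValueError):
            polymorphism_threshold(0)


class TestCallPolymorphisms:
    def test_variant_at_half_depth_passes_the_ten_x_rule(self, pileup_factory):
        pl = pileup_factory({1: {"A": 5, "G": 5}}, 1)
        cons = build_consensus(pl)  # tie -> A
        (call,) = call_polymorphisms(pl, cons, 10)
        assert call.variant_base == "G"
        assert call.passed  # 5 >= 5

    def test_single_error_like_call_fails(self, pileup_factory):
        pl = pileup_factory({1: {"A": 9, "G": 1}}, 1)
        (call,) = call_polymorphisms(pl, build_consensus(pl), 10)
        assert not call.passed

    def test_consensus_n_positions_emit_nothing(self, pileup_factory):
        pl = pileup_factory({2: {"A": 3, "G": 2}}, 2)
        calls = call_polymorphisms(pl, build_consensus(pl), 4)
        assert [c.position for c in calls] == [2]

    def test_deletion_allele_reported_as_del(self, pileup_factory):
        pl = pileup_factory({1: {"A": 6, "del": 5}}, 1)
        (call,) = call_polymorphisms(pl, build_consensus(pl), 10)
        assert call.variant_base == "del"
        assert call.passed

    def test_per_site_mode_scales_to_site_depth(self, pileup_factory):
        # pooled site depth 100 -> per-site threshold 50, dataset-level 5
        pl = pileup_factory({1: {"A": 80, "G": 20}}, 1)
        cons = build_consensus(pl)
        (dataset,) = call_polymorphisms(pl, cons, 10)
        (per_site,) = call_polymorphisms(pl, cons, 10, per_site=True)
        assert dataset.passed and dataset.threshold == 5
        assert not per_site.passed and per_site.threshold == 50

    def test_length_mismatch_raises(self, pileup_factory):
        pl = pileup_factory({1: {"A": 1}}, 2)
        with pytest.raises(ValueError, match="length"):
            call_polymorphisms(pl, ancestral_consensus("ACG"), 10)

    def test_error_free_identical_copies_yield_zero_passed_calls(self):
        spec = ArraySpec(copies=10, unit_length=300, background_length=0, seed=17)
        genome, truth = simulate_genome(spec)
        reads, rt = simulate_reads(genome, ReadSpec(read_length=60, depth=10, error_rate=0.0, seed=18))
        ref = RepeatReference("unit", truth.unit_sequence)
        pl = build_pileup(true_alignments(reads, rt, truth, 300), ref)
        calls = call_polymorphisms(pl, build_consensus(pl), 10)
        assert calls == []


class TestWindowProfile:
    def test_fraction_arithmetic(self, pileup_factory):
        pl = pileup_factory({i: {"A": 5, "G": 5} for i in range(1, 11)}, 50)
        calls = call_polymorphisms(pl, ancestral_consensus("A" * 50), 10)
        (profile,) = window_profile(calls, 50, window=50)
        assert profile.polymorphic_fraction == pytest.approx(0.20)

    def test_no_calls_gives_all_zero(self):
        profiles = window_profile([], 60, window=50)
        assert len(profiles) == 11
        assert all(p.polymorphic_fraction == 0 for p in profiles)

    def test_every_position_polymorphic_gives_one(self, pileup_factory):
        pl = pileup_factory({i: {"A": 5, "G": 5} for i in range(1, 8)}, 7)
        calls = call_polymorphisms(pl, ancestral_consensus("A" * 7), 10)
        assert all(p.polymorphic_fraction == 1.0 for p in window_profile(calls, 7, window=3))

    def test_window_larger_than_reference_raises(self):
        with pytest.raises(ValueError):
            window_profile([], 10, window=50)

    def test_window_sum_identity_by_brute_force(self, pileup_factory):
        # sum over step-1 windows == window * passed - edge corrections,
        # verified against direct enumeration on a small unit
        L, w = 23, 5
        polymorphic = {3, 4, 11, 20, 23}
        pl = pileup_factory({p: {"A": 5, "G": 5} for p in polymorphic}, L)
        calls = call_polymorphisms(pl, ancestral_consensus("A" * L), 10)
        profiles = window_profile(calls, L, window=w)
        total = sum(p.polymorphic_fraction * w for p in profiles)
        brute = sum(
            sum(1 for p in polymorphic if s <= p <= s + w - 1)
            for s in range(1, L - w + 2)
        )
        assert total == pytest.approx(brute)

    def test_profile_invariant_to_call_ordering(self, pileup_factory):
        pl = pileup_factory({p: {"A": 5, "G": 5} for p in (2, 9, 4)}, 12)
        calls = call_polymorphisms(pl, ancestral_consensus("A" * 12), 10)
        fwd = window_profile(calls, 12, window=4)
        rev = window_profile(list(reversed(calls)), 12, window=4)
        assert fwd == rev


class TestRegionSummary:
    def test_calls_inside_one_region_only(self, pileup_factory):
        pl = pileup_factory({p: {"A": 5, "G": 5} for p in (4, 5)}, 20)
        calls = call_polymorphisms(pl, ancestral_consensus("A" * 20), 10)
        regions = [Region("18S", 3, 8), Region("ITS", 9, 14)]
        table = region_summary(calls, regions, 20).set_index("region")
        assert table.loc["18S", "polymorphic_positions"] == 2
        assert table.loc["ITS", "polymorphic_positions"] == 0
        assert table.loc["coding", "density"] > table.loc["noncoding", "density"]

    def test_empty_call_list_gives_zero_densities(self):
        table = region_summary([], [Region("18S", 1, 10)], 20)
        assert (table["density"] == 0).all()

    def test_coding_enrichment_recovered_from_simulator_truth(self):
        # variants placed 80% inside the coding region: recovered density gap
        L = 500
        coding = Region("18S", 1, 250)
        rng = np.random.default_rng(23)
        coding_pos = rng.choice(np.arange(1, 251), size=16, replace=False)
        noncoding_pos = rng.choice(np.arange(251, 501), size=4, replace=False)
        variants = tuple((int(p), "A", 0.3) for p in np.concatenate([coding_pos, noncoding_pos]))
        # error-free reads isolate placement recovery from error control: at
        # pooled site depth C*D the dataset-level threshold does not bound
        # sequencing-error alleles (see the false-positive test for that regime)
        spec = ArraySpec(copies=60, unit_length=L, background_length=5000, seed=24,
                         variant_sites=variants)
        genome, truth = simulate_genome(spec)
        reads, rt = simulate_reads(genome, ReadSpec(read_length=80, depth=10, error_rate=0.0, seed=25))
        ref = RepeatReference("unit", truth.unit_sequence)
        pl = build_pileup(true_alignments(reads, rt, truth, L), ref)
        calls = call_polymorphisms(pl, build_consensus(pl), 10)
        table = region_summary(calls, [coding, Region("ITS", 251, 500)], L).set_index("region")
        assert table.loc["coding", "density"] > table.loc["noncoding", "density"]


class TestErrorControlAndPower:
    def test_false_positive_rate_below_binomial_bound(self):
        # identical copies, pooled site depth equal to the dataset depth
        D, e, L = 10, 0.04, 10_000
        spec = ArraySpec(copies=1, unit_length=L, background_length=0, seed=11)
        genome, truth = simulate_genome(spec)
        reads, rt = simulate_reads(genome, ReadSpec(read_length=100, depth=D, error_rate=e, seed=12))
        ref = RepeatReference("unit", truth.unit_sequence)
        pl = build_pileup(true_alignments(reads, rt, truth, L), ref)
        calls = call_polymorphisms(pl, build_consensus(pl), D)
        n_passed = sum(c.passed for c in calls)
        bound = binom.sf(polymorphism_threshold(D) - 1, D, e)
        assert n_passed / (3 * L) < bound

    def test_power_at_least_95_percent_for_f_above_half_and_monotone(self):
        # a variant in fraction f of the C copies is supported by ~f*C*D reads
        # against a threshold of ceil(D/2): power ~1 for f >= 0.5
        L, C, D = 2000, 100, 10
        fgrid = (0.5, 0.6, 0.7, 0.8, 0.9)
        per_f = 20
        variants, truth_f = [], {}
        pos = 50
        for f in fgrid:
            for _ in range(per_f):
                variants.append((pos, "A", f))
                truth_f[pos] = f
                pos += 19
        spec = ArraySpec(copies=C, unit_length=L, background_length=10_000, seed=21,
                         variant_sites=tuple(variants))
        genome, truth = simulate_genome(spec)
        reads, rt = simulate_reads(genome, ReadSpec(read_length=100, depth=D, error_rate=0.04, seed=22))
        ref = RepeatReference("unit", truth.unit_sequence)
        pl = build_pileup(true_alignments(reads, rt, truth, L), ref)
        calls = call_polymorphisms(pl, ancestral_consensus(truth.unit_sequence), D)
        passed = {(c.position, c.variant_base) for c in calls if c.passed}
        power = {
            f: sum((p, "A") in passed for p, pf in truth_f.items() if pf == f) / per_f
            for f in fgrid
        }
        assert all(power[f] >= 0.95 for f in fgrid)
        assert all(power[a] <= power[b] + 1e-12 for a, b in itertools.pairwise(fgrid))
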