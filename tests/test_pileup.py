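import numpy as np
import pytest

from rdnarray import (
    ArraySpec,
    ReadSpec,
    RepeatReference,
    build_pileup,
    dual_stringency_pileup,
    naive_map,
    pileup_from_reads,
    pileup_from_sam,
    simulate_genome,
    simulate_reads,
)
from rdnarray.pileup import revcomp

from oracles import sliding_mismatches


def mutate(seq: str, positions: list[int], rng=None) -> str:
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = swap[out[p]]
    return "".join(out)


class TestNaiveMap:
    def test_exact_substring_recovers_offset(self, small_ref):
        read = small_ref.sequence[4:14]
        (aln,) = naive_map([("r", read)], small_ref, 0.05)
        assert (aln.start, aln.strand, aln.identity) == (5, "+", 1.0)

    def test_reverse_complement_maps_to_same_offset(self, small_ref):
        read = revcomp(small_ref.sequence[4:14])
        (aln,) = naive_map([("r", read)], small_ref, 0.05)
        assert (aln.start, aln.strand) == (5, "-")
        assert aln.bases == small_ref.sequence[4:14]

    def test_divergent_read_dropped_and_decision_matches_oracle(self):
        # 10% mismatches vs a 5% ceiling: brute-force check at every offset
        ref = RepeatReference("u", "ACGTTGCAGGCTAACGGTTACGATCCAGTGCAATTGCCGG")
        read = mutate(ref.sequence[5:25], [3, 11])  # 2/20 = 10%
        _, best_mm = sliding_mismatches(read, ref.sequence)
        assert best_mm / len(read) > 0.05
        assert naive_map([("r", read)], ref, 0.05) == []
        kept = naive_map([("r", read)], ref, 0.15)
        assert kept and kept[0].identity == 1 - best_mm / len(read)

    def test_junction_spanning_read_wraps_modulo_unit(self, small_ref):
        L = small_ref.length
        read = small_ref.sequence[L - 5 :] + small_ref.sequence[:5]
        (aln,) = naive_map([("r", read)], small_ref, 0.05)
        assert aln.start == L - 4
        positions = [p for p, _ in aln.aligned_pairs]
        assert positions == [16, 17, 18, 19, 20, 1, 2, 3, 4, 5]

    def test_empty_read_set_is_empty_result(self, small_ref):
        assert naive_map([], small_ref, 0.05) == []

    def test_error_free_reads_recover_origin_modulo_unit_length(self):
        spec = ArraySpec(copies=8, unit_length=120, background_length=400, seed=5)
        genome, truth = simulate_genome(spec)
        reads, rt = simulate_reads(genome, ReadSpec(read_length=40, depth=4, error_rate=0.0, seed=6))
        ref = RepeatReference("unit", truth.unit_sequence)
        alns = {a.read_id: a for a in naive_map(reads, ref, 0.0)}
        array_start0 = truth.array_start - 1
        checked = 0
        for (rid, _), start in zip(reads, rt.starts):
            if array_start0 <= start and start + 40 <= array_start0 + 8 * 120:
                true_unit_pos = (start - array_start0) % 120 + 1
                assert alns[rid].start == true_unit_pos
                checked += 1
        assert checked > 20


class TestPileupFromReads:
    def test_single_perfect_read_gives_depth_one_columns(self, small_ref):
        pl = pileup_from_reads([("r", small_ref.sequence[:10])], small_ref, 0.05)
        assert pl.total_aligned_bases == 10
        assert list(pl.depth[:10]) == [1] * 10
        assert list(pl.depth[10:]) == [0] * 10

    def test_staggered_reads_overlap_depth(self, small_ref):
        reads = [("a", small_ref.sequence[0:10]), ("b", small_ref.sequence[5:15])]
        pl = pileup_from_reads(reads, small_ref, 0.05)
        assert list(pl.depth[5:10]) == [2] * 5
        assert pl.total_aligned_bases == 20

    def test_total_aligned_bases_equals_sum_of_read_lengths(self, small_ref):
        rng = np.random.default_rng(0)
        reads = []
        for i in range(30):
            s = int(rng.integers(0, 10))
            ln = int(rng.integers(5, 11))
            reads.append((f"r{i}", small_ref.sequence[s : s + ln]))
        alns = naive_map(reads, small_ref, 0.05)
        pl = build_pileup(alns, small_ref)
        assert pl.total_aligned_bases == sum(len(a) for a in alns)

    def test_lowering_min_identity_never_decreases_depth(self):
        spec = ArraySpec(copies=5, unit_length=200, background_length=0, seed=9)
        genome, truth = simulate_genome(spec)
        reads, _ = simulate_reads(genome, ReadSpec(read_length=50, depth=6, error_rate=0.04, seed=10))
        ref = RepeatReference("unit", truth.unit_sequence)
        strict = pileup_from_reads(reads, ref, 0.05)
        relaxed = pileup_from_reads(reads, ref, 0.15)
        assert (relaxed.depth >= strict.depth).all()

    def test_dual_stringency_residual_pass_adds_divergent_reads(self, small_ref):
        clean = small_ref.sequence[:20]
        noisy = mutate(small_ref.sequence[:20], [2, 9])  # 10% divergent
        pl = dual_stringency_pileup([("a", clean), ("b", noisy)], small_ref, 0.05, 0.15)
        assert pl.n_reads == 2
        single = pileup_from_reads([("a", clean), ("b", noisy)], small_ref, 0.05)
        assert single.n_reads == 1


SAM_TEMPLATE = """@HD\tVN:1.6\tSO:unknown
@SQ\tSN:{name}\tLN:{length}
{records}"""


def write_sam(path, ref, records):
    body = "\n".join("\t".join(map(str, r)) for r in records)
    path.write_text(SAM_TEMPLATE.format(name=ref.id, length=ref.length, records=body) + "\n")
    return path


class TestPileupFromSam:
    def test_perfect_read(self, tmp_path, small_ref):
        sam = write_sam(
            tmp_path / "a.sam",
            small_ref,
            [("r1", 0, "unit", 1, 60, "10M", "*", 0, 0, small_ref.sequence[:10], "*")],
        )
        pl = pileup_from_sam(sam, small_ref, 0.95)
        assert pl.total_aligned_bases == 10
        assert list(pl.depth[:10]) == [1] * 10

    def test_identity_filter_excludes_divergent_read(self, tmp_path, small_ref):
        noisy = mutate(small_ref.sequence[:20], [1, 5, 9])  # 85% identity
        sam = write_sam(
            tmp_path / "b.sam",
            small_ref,
            [("r1", 0, "unit", 1, 60, "20M", "*", 0, 0, noisy, "*")],
        )
        assert pileup_from_sam(sam, small_ref, 0.95).n_reads == 0
        assert pileup_from_sam(sam, small_ref, 0.85).n_reads == 1

    def test_deletion_counts_as_fifth_allele_and_insertion_sidelined(self, tmp_path, small_ref):
        seq = small_ref.sequence
        # 5M 2D 5M: bases 1-5, deletion at 6-7, bases 8-12
        # 4M 3I 4M: insertion recorded after position 4, no depth contribution
        sam = write_sam(
            tmp_path / "c.sam",
            small_ref,
            [
                ("rdel", 0, "unit", 1, 60, "5M2D5M", "*", 0, 0, seq[:5] + seq[7:12], "*"),
                ("rins", 0, "unit", 1, 60, "4M3I4M", "*", 0, 0, seq[:4] + "GGG" + seq[4:8], "*"),
            ],
        )
        pl = pileup_from_sam(sam, small_ref, 0.80)
        assert pl.counts[5, 4] == 1 and pl.counts[6, 4] == 1  # del allele at pos 6, 7
        assert pl.insertions == {4: {"GGG": 1}}
        # insertion bases do not enter depth
        assert pl.total_aligned_bases == 10 + 2 + 8

    def test_unmapped_records_skipped(self, tmp_path, small_ref):
        sam = write_sam(
            tmp_path / "d.sam",
            small_ref,
            [("r1", 4, "*", 0, 0, "*", "*", 0, 0, "ACGT", "*")],
        )
        pl = pileup_from_sam(sam, small_ref, 0.95)
        assert (pl.n_reads, pl.n_skipped) == (0, 1)

    def test_reference_name_mismatch_raises(self, tmp_path, small_ref):
        sam = tmp_path / "e.sam"
        sam.write_text(
            "@SQ\tSN:other\tLN:20\nr1\t0\tother\t1\t60\t4M\t*\t0\t0\tACGT\t*\n"
        )
        with pytest.raises(ValueError, match="do not include"):
            pileup_from_sam(sam, small_ref, 0.95)

    def test_soft_clips_do_not_contribute(self, tmp_path, small_ref):
        seq = "TTT" + small_ref.sequence[:8]
        sam = write_sam(
            tmp_path / "f.sam",
            small_ref,
            [("r1", 0, "unit", 1, 60, "3S8M", "*", 0, 0, seq, "*")],
        )
        pl = pileup_from_sam(sam, small_ref, 0.95)
        assert pl.total_aligned_bases == 8


class TestPileupContainer:
    def test_tsv_round_trip(self, tmp_path, pileup_factory):
        pl = pileup_factory({1: {"A": 3, "G": 1}, 5: {"del": 2}}, 6)
        path = tmp_path / "p.tsv"
        pl.to_tsv(path)
        back = type(pl).from_tsv(path)
        assert (back.counts == pl.counts).all()

    def test_depth_is_sum_of_counts(self, pileup_factory):
        pl = pileup_factory({2: {"A": 3, "C": 2, "del": 1}}, 4)
        assert pl.column(2).depth == 6
        assert pl.total_aligned_bases == 6
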