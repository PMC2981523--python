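"""Window extraction, coordinate compilation and negative sampling."""

import numpy as np
import pytest
from scipy import stats

import tssmask as tm
from tssmask.seq_windows import (
    read_windows_fasta,
    write_windows_fasta,
)

from conftest import random_dna


class TestTssWindow:
    def test_length_and_alphabet_enforced(self):
        with pytest.raises(ValueError):
            tm.TssWindow("ACGT" * 49)  # 196 nt
        with pytest.raises(tm.AmbiguousSequenceError):
            tm.TssWindow("N" * 200)

    def test_softmasked_input_is_uppercased(self):
        w = tm.TssWindow("acgt" * 50)
        assert w.seq == "ACGT" * 50

    def test_halves_split_at_tss(self):
        w = tm.TssWindow("A" * 100 + "C" + "G" * 99)
        assert w.upstream == "A" * 100
        assert w.downstream[0] == "C"  # character 101 is the TSS base


class TestExtractWindow:
    def test_tss_base_lands_at_character_101(self, rng):
        genome = random_dna(rng, 500)
        genome = genome[:250] + "C" + genome[251:]
        w = tm.extract_window(genome, 250, "+")
        assert w.seq[100] == "C"

    def test_minus_strand_is_revcomp_of_mirrored_slice(self, rng):
        genome = random_dna(rng, 500)
        w = tm.extract_window(genome, 250, "-")
        assert w.seq[100] == tm.revcomp(genome[250])
        assert w.seq == tm.revcomp(genome[151:351])

    def test_out_of_bounds_raises(self, rng):
        genome = random_dna(rng, 300)
        with pytest.raises(tm.WindowBoundsError):
            tm.extract_window(genome, 50, "+")
        with pytest.raises(tm.WindowBoundsError):
            tm.extract_window(genome, 250, "-")

    def test_ambiguous_slice_raises(self, rng):
        genome = random_dna(rng, 400)
        genome = genome[:199] + "N" + genome[200:]
        with pytest.raises(tm.AmbiguousSequenceError):
            tm.extract_window(genome, 200, "+")

    def test_reembedding_reproduces_genome_slice(self, rng):
        """500 random (genome, pos, strand) draws round-trip exactly."""
        genome = random_dna(rng, 3000)
        for _ in range(500):
            strand = "+" if rng.integers(2) == 0 else "-"
            pos = int(rng.integers(100, 2900))
            w = tm.extract_window(genome, pos, strand)
            if strand == "+":
                assert w.seq == genome[pos - 100 : pos + 100]
            else:
                assert tm.revcomp(w.seq) == genome[pos - 99 : pos + 101]

    def test_strand_reversal_symmetry(self, rng):
        """Extracting from the reverse complement at the mirrored position
        and flipped strand yields the same window."""
        genome = random_dna(rng, 1000)
        rc = tm.revcomp(genome)
        for _ in range(50):
            pos = int(rng.integers(150, 850))
            for strand, flipped in (("+", "-"), ("-", "+")):
                a = tm.extract_window(genome, pos, strand)
                b = tm.extract_window(rc, len(genome) - 1 - pos, flipped)
                assert a.seq == b.seq


class TestCompileTssSet:
    def test_exact_triple_match(self):
        cage = [tm.CoordinateRecord("c1", 50, "+")]
        assert tm.compile_tss_set(cage, [tm.CoordinateRecord("c1", 50, "+")]) == [
            tm.CoordinateRecord("c1", 50, "+")
        ]

    def test_strand_specific(self):
        cage = [tm.CoordinateRecord("c1", 50, "+")]
        assert tm.compile_tss_set(cage, [tm.CoordinateRecord("c1", 50, "-")]) == []

    def test_duplicates_collapse(self):
        cage = [tm.CoordinateRecord("c1", 50, "+", "a"), tm.CoordinateRecord("c1", 50, "+", "b")]
        out = tm.compile_tss_set(cage, [tm.CoordinateRecord("c1", 50, "+")])
        assert len(out) == 1

    def test_matches_brute_force_intersection(self, rng):
        def rand_records(n):
            return [
                tm.CoordinateRecord(
                    f"c{rng.integers(3)}", int(rng.integers(100)), "+-"[rng.integers(2)]
                )
                for _ in range(n)
            ]

        cage, evidence = rand_records(1000), rand_records(1000)
        got = {r.triple for r in tm.compile_tss_set(cage, evidence)}
        expected = {
            c.triple
            for c in cage
            if any(c.triple == e.triple for e in evidence)
        }
        assert got == expected


class TestNegativeSampling:
    def test_single_window_genome(self):
        seq = "ACGT" * 50
        out = tm.sample_negative_windows([("s", seq)], [], 1, rng_seed=0)
        assert len(out) == 1
        assert out[0].seq in (seq, tm.revcomp(seq))

    def test_reproducible_given_seed(self, rng):
        genome = [("s", random_dna(rng, 2000))]
        a = tm.sample_negative_windows(genome, [], 20, rng_seed=3)
        b = tm.sample_negative_windows(genome, [], 20, rng_seed=3)
        assert [w.seq for w in a] == [w.seq for w in b]

    def test_allocation_proportional_to_length(self, rng):
        """9:1 length ratio gives per-sequence counts inside binomial
        99% bounds."""
        genome = [("big", random_dna(rng, 9000)), ("small", random_dna(rng, 1000))]
        wins = tm.sample_negative_windows(genome, [], 10_000, rng_seed=1)
        n_big = sum(1 for w in wins if w.origin[0] == "big")
        lo, hi = stats.binom.ppf([0.005, 0.995], 10_000, 0.9)
        assert lo <= n_big <= hi

    def test_cage_exclusion_blocks_all_centers(self, rng):
        seq = random_dna(rng, 400)
        cage = [tm.CoordinateRecord("s", p, "+") for p in range(0, 400, 15)]
        with pytest.raises(tm.SamplingExhaustedError):
            tm.sample_negative_windows([("s", seq)], cage, 5, rng_seed=0, max_tries=2000)

    def test_cage_exclusion_ignores_strand(self, rng):
        seq = random_dna(rng, 400)
        cage = [tm.CoordinateRecord("s", p, "-") for p in range(0, 400, 15)]
        with pytest.raises(tm.SamplingExhaustedError):
            tm.sample_negative_windows([("s", seq)], cage, 5, rng_seed=0, max_tries=2000)

    def test_ambiguous_windows_are_redrawn(self, rng):
        seq = random_dna(rng, 300) + "N" * 300 + random_dna(rng, 300)
        wins = tm.sample_negative_windows([("s", seq)], [], 30, rng_seed=2)
        assert all(set(w.seq) <= set("ACGT") for w in wins)


class TestFastaRoundTrip:
    def test_windows_round_trip_byte_identical(self, tmp_path, small_corpus):
        path = tmp_path / "wins.fa"
        wins = small_corpus.positives[:50]
        write_windows_fasta(wins, path)
        back = read_windows_fasta(path)
        assert [w.seq for w in back] == [w.seq for w in wins]
        assert [w.label for w in back] == ["positive"] * 50

    def test_origin_metadata_survives(self, tmp_path, rng):
        genome = random_dna(rng, 500)
        w = tm.extract_window(genome, 250, "-", sequence_id="chrT")
        path = tmp_path / "w.fa"
        write_windows_fasta([w], path)
        (back,) = read_windows_fasta(path)
        assert back.origin == ("chrT", 250, "-")

    def test_gzip_transparent(self, tmp_path, small_corpus):
        path = tmp_path / "wins.fa.gz"
        write_windows_fasta(small_corpus.negatives[:10], path)
        assert len(read_windows_fasta(path)) == 10


class TestCoordinateBed:
    def test_round_trip(self, tmp_path):
        recs = [
            tm.CoordinateRecord("chr1", 100, "+", "CAGE"),
            tm.CoordinateRecord("chr2", 7, "-", "mRNA"),
        ]
        path = tmp_path / "c.bed"
        tm.seq_windows.write_coordinate_bed(recs, path)
        back = tm.seq_windows.read_coordinate_bed(path)
        assert [r.triple for r in back] == [r.triple for r in recs]
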