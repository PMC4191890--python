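"""Read processing, track building, and on-disk format round-trips."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from termscan import (
    AlignedRead,
    CoverageTrack,
    LibraryStats,
    build_track,
    condense_reads,
    filter_excluded,
    read_track,
    trim_adapter,
    write_track,
)
from termscan.coverage_io import (
    ADAPTER_3P,
    read_bedgraph_strand,
    read_wiggle_strand,
    write_bedgraph_strand,
    write_wiggle_strand,
)


def brute_force_trim(read: str, adapter: str, min_overlap: int, rate: float) -> str:
    """Exhaustive suffix-prefix oracle for adapter trimming."""
    for k in range(min(len(read), len(adapter)), min_overlap - 1, -1):
        mismatches = sum(a != b for a, b in zip(read[-k:], adapter[:k]))
        if mismatches <= rate * k:
            return read[:-k]
    return read


class TestTrimAdapter:
    def test_full_adapter_removed(self):
        insert = "ACGTACGTACGT"
        assert trim_adapter(insert + ADAPTER_3P, ADAPTER_3P) == insert

    def test_no_adapter_unchanged(self):
        read = "ACGTACGTCCCC"
        assert trim_adapter(read, "GGGGGGGGGG") == read

    def test_partial_adapter_suffix(self):
        insert = "TTTTACGT"
        read = insert + ADAPTER_3P[:8]
        assert trim_adapter(read, ADAPTER_3P, min_overlap=5, max_mismatch_rate=0.0) == insert

    def test_short_overlap_below_min_kept(self):
        read = "ACGTACGT" + ADAPTER_3P[:3]
        assert trim_adapter(read, ADAPTER_3P, min_overlap=5) == read

    @given(
        insert=st.text(alphabet="ACGT", min_size=0, max_size=30),
        keep=st.integers(min_value=0, max_value=len(ADAPTER_3P)),
        min_overlap=st.integers(min_value=1, max_value=8),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_exhaustive_oracle(self, insert, keep, min_overlap):
        read = insert + ADAPTER_3P[:keep]
        expected = brute_force_trim(read, ADAPTER_3P, min_overlap, 0.1)
        assert trim_adapter(read, ADAPTER_3P, min_overlap=min_overlap) == expected


class TestCondense:
    def test_duplicates_collapsed_order_kept(self):
        assert condense_reads(["AA", "AA", "CC", "AA", "GG"]) == ["AA", "CC", "GG"]

    def test_empty(self):
        assert condense_reads([]) == []

    @given(st.lists(st.text(alphabet="ACGT", min_size=1, max_size=6), max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_idempotent(self, reads):
        once = condense_reads(reads)
        assert condense_reads(once) == once


class TestFilterExcluded:
    TRNA = [("chrI", 100, 200, "+")]

    def test_read_inside_exclusion_removed(self):
        reads = [AlignedRead("chrI", 120, 150, "+")]
        assert filter_excluded(reads, self.TRNA) == []

    def test_zero_overlap_kept(self):
        reads = [AlignedRead("chrI", 200, 230, "+")]  # half-open: no overlap
        assert filter_excluded(reads, self.TRNA) == reads

    def test_one_bp_overlap_removed(self):
        reads = [AlignedRead("chrI", 199, 230, "+")]
        assert filter_excluded(reads, self.TRNA) == []

    def test_opposite_strand_kept_by_default(self):
        reads = [AlignedRead("chrI", 120, 150, "-")]
        assert filter_excluded(reads, self.TRNA) == reads
        assert filter_excluded(reads, self.TRNA, same_strand=False) == []

    def test_malformed_interval_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            filter_excluded([], [("chrI", 50, 50, "+")])

    @given(
        read_start=st.integers(min_value=0, max_value=300),
        read_len=st.integers(min_value=1, max_value=60),
        excl_start=st.integers(min_value=0, max_value=300),
        excl_len=st.integers(min_value=1, max_value=60),
    )
    @settings(max_examples=200, deadline=None)
    def test_overlap_agrees_with_interval_arithmetic(
        self, read_start, read_len, excl_start, excl_len
    ):
        read = AlignedRead("chrI", read_start, read_start + read_len, "+")
        exclusion = [("chrI", excl_start, excl_start + excl_len, "+")]
        overlaps = read.start < excl_start + excl_len and excl_start < read.end
        kept = filter_excluded([read], exclusion)
        assert (kept == []) == overlaps


class TestBuildTrack:
    LENGTHS = {"chrI": 300}

    def test_single_read_unit_coverage(self):
        reads = [AlignedRead("chrI", 10, 40, "+")]
        track = build_track(reads, total_aligned=10**7, chrom_lengths=self.LENGTHS)
        values = track.values("chrI", "+")
        assert np.all(values[10:40] == 1.0)
        assert values.sum() == 30.0

    def test_normalization_scales_inversely_with_depth(self):
        reads = [AlignedRead("chrI", 10, 40, "+")]
        track = build_track(reads, total_aligned=2 * 10**7, chrom_lengths=self.LENGTHS)
        assert np.all(track.values("chrI", "+")[10:40] == 0.5)

    def test_strand_separation(self):
        reads = [AlignedRead("chrI", 10, 40, "-")]
        track = build_track(reads, total_aligned=10**7, chrom_lengths=self.LENGTHS)
        assert track.values("chrI", "+").sum() == 0.0
        assert track.values("chrI", "-").sum() == 30.0

    def test_five_prime_mode_counts_read_ends(self):
        reads = [AlignedRead("chrI", 10, 40, "+"), AlignedRead("chrI", 10, 40, "-")]
        track = build_track(
            reads, total_aligned=10**7, chrom_lengths=self.LENGTHS, five_prime=True
        )
        assert track.values("chrI", "+")[10] == 1.0
        assert track.values("chrI", "-")[39] == 1.0

    def test_invalid_total_aligned(self):
        with pytest.raises(ValueError, match="total_aligned"):
            build_track([], total_aligned=0, chrom_lengths=self.LENGTHS)

    def test_equals_naive_per_base_accumulation(self):
        rng = np.random.default_rng(7)
        reads = [
            AlignedRead(
                "chrI",
                int(start := rng.integers(0, 250)),
                int(start + rng.integers(1, 50)),
                "+" if rng.random() < 0.5 else "-",
            )
            for _ in range(200)
        ]
        total = 5_000_000
        track = build_track(reads, total, self.LENGTHS)
        factor = 1e7 / total
        naive = {s: np.zeros(300) for s in "+-"}
        for read in reads:
            for base in range(read.start, read.end):
                naive[read.strand][base] += factor
        for strand in "+-":
            np.testing.assert_allclose(track.values("chrI", strand), naive[strand])
        expected_total = factor * sum(r.end - r.start for r in reads)
        assert track.total() == pytest.approx(expected_total)


class TestTrackFormats:
    @pytest.fixture()
    def track(self):
        rng = np.random.default_rng(3)
        track = CoverageTrack({"chrI": 200, "chrII": 120})
        for chrom in ("chrI", "chrII"):
            for strand in "+-":
                values = rng.poisson(1.2, track.chrom_lengths[chrom]).astype(float)
                values[rng.random(len(values)) < 0.3] = 0.0
                values *= 1.7  # non-integer normalized values
                track.set_values(chrom, strand, values)
        return track

    @pytest.mark.parametrize("fmt", ["bedgraph", "wiggle"])
    def test_round_trip_value_exact(self, track, fmt, tmp_path):
        prefix = str(tmp_path / "trk")
        paths = write_track(track, prefix, fmt=fmt)
        back = read_track(paths["+"], paths["-"], track.chrom_lengths, fmt=fmt)
        for chrom in track.chromosomes():
            for strand in "+-":
                np.testing.assert_array_equal(
                    back.values(chrom, strand), track.values(chrom, strand)
                )

    def test_bedgraph_interval_expansion(self, tmp_path):
        path = tmp_path / "x.bedgraph"
        path.write_text("chrI\t0\t3\t2.5\n")
        track = read_bedgraph_strand(str(path), {"chrI": 10}, "+")
        np.testing.assert_array_equal(
            track.values("chrI", "+"), [2.5, 2.5, 2.5, 0, 0, 0, 0, 0, 0, 0]
        )

    def test_wiggle_one_based_start(self, tmp_path):
        path = tmp_path / "x.wig"
        path.write_text("fixedStep chrom=chrI start=1 step=1\n4.0\n")
        track = read_wiggle_strand(str(path), {"chrI": 5}, "+")
        assert track.values("chrI", "+")[0] == 4.0

    @pytest.mark.parametrize(
        "content, message",
        [
            ("chrX\t0\t3\t1.0\n", "unknown chromosome"),
            ("chrI\t0\t3\t-1.0\n", "negative"),
            ("chrI\t0\t5\t1.0\nchrI\t4\t8\t2.0\n", "overlapping"),
            ("chrI\t5\t5\t1.0\n", "malformed"),
        ],
    )
    def test_bedgraph_errors_carry_line_numbers(self, tmp_path, content, message):
        path = tmp_path / "bad.bedgraph"
        path.write_text(content)
        with pytest.raises(ValueError, match=message) as err:
            read_bedgraph_strand(str(path), {"chrI": 100}, "+")
        assert ":2:" in str(err.value) or ":1:" in str(err.value)

    def test_wiggle_negative_value_rejected(self, tmp_path):
        path = tmp_path / "bad.wig"
        path.write_text("fixedStep chrom=chrI start=1 step=1\n-2\n")
        with pytest.raises(ValueError, match="negative"):
            read_wiggle_strand(str(path), {"chrI": 10}, "+")


class TestLibraryStats:
    def test_monotone_accepted(self):
        stats = LibraryStats(1000, 900, 800, 700, 650)
        assert stats.post_trna_count == 650

    def test_increase_rejected(self):
        with pytest.raises(ValueError, match="non-increasing"):
            LibraryStats(1000, 1100, 800, 700, 650)
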