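"""Read processing and strand-specific occupancy tracks.

This module turns aligned nascent-RNA crosslinking reads into normalized,
strand-specific per-base occupancy tracks, and reads/writes the on-disk
formats the rest of the pipeline consumes: bedGraph and fixed-step wiggle
for tracks, BED6 for aligned reads and exclusion intervals, FASTA for raw
read sequences.

Coordinates are 0-based half-open internally.  bedGraph shares that
convention; wiggle is converted to/from its own 1-based convention at the
file boundary.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

STRANDS = ("+", "-")

#: 3' sequencing adapter ligated to nascent-RNA fragments (DNA sense, core
#: sequence without the 5' adenylation / 3' dideoxy chemistry markers).
ADAPTER_3P = "AGATCGGAAGAGCACACGTCT"


@dataclass(frozen=True, order=True)
class AlignedRead:
    """A read aligned to the genome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )


class CoverageTrack:
    """Dense per-base occupancy values, one vector per chromosome and strand.

    Values are non-negative reals: raw counts, or counts scaled by the
    library normalization factor ``norm_per / total_aligned`` (reads per
    10^7 aligned by default).
    """

    def __init__(
        self,
        chrom_lengths: dict[str, int],
        total_aligned: int | None = None,
        norm_per: float = 1e7,
    ) -> None:
        if any(length <= 0 for length in chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        self.chrom_lengths = dict(chrom_lengths)
        self.total_aligned = total_aligned
        self.norm_per = norm_per
        self._data: dict[tuple[str, str], np.ndarray] = {
            (chrom, strand): np.zeros(length, dtype=float)
            for chrom, length in self.chrom_lengths.items()
            for strand in STRANDS
        }

    @property
    def normalization_factor(self) -> float:
        if self.total_aligned is None:
            return 1.0
        return self.norm_per / self.total_aligned

    def chromosomes(self) -> list[str]:
        return sorted(self.chrom_lengths)

    def values(self, chrom: str, strand: str) -> np.ndarray:
        if strand not in STRANDS:
            raise ValueError(f"unknown strand {strand!r}")
        try:
            return self._data[(chrom, strand)]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def set_values(self, chrom: str, strand: str, values: np.ndarray) -> None:
        target = self.values(chrom, strand)
        values = np.asarray(values, dtype=float)
        if values.shape != target.shape:
            raise ValueError(
                f"length mismatch on {chrom}{strand}: "
                f"{values.shape[0]} vs {target.shape[0]}"
            )
        self._data[(chrom, strand)] = values

    def total(self) -> float:
        return float(sum(v.sum() for v in self._data.values()))

    def scaled(self, factor: float) -> "CoverageTrack":
        out = CoverageTrack(self.chrom_lengths, self.total_aligned, self.norm_per)
        for key, values in self._data.items():
            out._data[key] = values * factor
        return out

    def same_genome(self, other: "CoverageTrack") -> bool:
        return self.chrom_lengths == other.chrom_lengths

    def allclose(self, other: "CoverageTrack", rtol: float = 0.0, atol: float = 0.0) -> bool:
        if not self.same_genome(other):
            return False
        return all(
            np.allclose(self._data[key], other._data[key], rtol=rtol, atol=atol)
            for key in self._data
        )


@dataclass(frozen=True)
class LibraryStats:
    """Read counts at the successive processing stages of one library."""

    raw_read_count: int
    post_trim_count: int
    condensed_count: int
    aligned_count: int
    post_trna_count: int

    def __post_init__(self) -> None:
        counts = [getattr(self, f.name) for f in fields(self)]
        if any(c < 0 for c in counts):
            raise ValueError("stage counts must be non-negative")
        for earlier, later in zip(counts, counts[1:]):
            if later > earlier:
                raise ValueError(
                    "stage counts must be non-increasing along the pipeline: "
                    f"{counts}"
                )


def trim_adapter(
    read: str,
    adapter: str,
    min_overlap: int = 5,
    max_mismatch_rate: float = 0.1,
) -> str:
    """Remove a 3' adapter from the end of a read sequence.

    The longest suffix of the read matching a prefix of the adapter — at
    least ``min_overlap`` long, with at most ``max_mismatch_rate`` of its
    positions mismatched — is removed.  A read without a qualifying match
    is returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    longest = min(len(read), len(adapter))
    for k in range(longest, min_overlap - 1, -1):
        suffix = read[-k:]
        prefix = adapter[:k]
        mismatches = sum(a != b for a, b in zip(suffix, prefix))
        if mismatches <= max_mismatch_rate * k:
            return read[:-k]
    return read


def condense_reads(reads: Iterable[str]) -> list[str]:
    """Collapse exact duplicate sequences, keeping first-seen order.

    PCR amplification produces identical copies of the same fragment; the
    library is condensed so no sequence appears more than once.
    """
    return list(dict.fromkeys(reads))


def _exclusion_trees(
    exclusion: Iterable[tuple[str, int, int, str]],
) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = collections.defaultdict(IntervalTree)
    for i, item in enumerate(exclusion):
        if hasattr(item, "chrom"):
            chrom, start, end, strand = item.chrom, item.start, item.end, item.strand
        else:
            chrom, start, end, strand = item
        if strand not in STRANDS:
            raise ValueError(f"exclusion interval {i}: bad strand {strand!r}")
        if not 0 <= start < end:
            raise ValueError(
                f"exclusion interval {i}: malformed [{start}, {end}) on {chrom}"
            )
        trees[chrom].addi(start, end, strand)
    return dict(trees)


def filter_excluded(
    reads: Sequence[AlignedRead],
    exclusion: Iterable[tuple[str, int, int, str]],
    same_strand: bool = True,
) -> list[AlignedRead]:
    """Drop reads overlapping an exclusion interval by >= 1 bp.

    Used to remove reads mapping to tRNA genes, which represent artifactual
    carry-over from the affinity purification rather than Pol II occupancy.
    By default only same-strand overlap excludes a read; ``same_strand=False``
    makes the exclusion strand-agnostic.
    """
    trees = _exclusion_trees(exclusion)
    kept = []
    for read in reads:
        tree = trees.get(read.chrom)
        if tree is not None:
            hits = tree.overlap(read.start, read.end)
            if any((not same_strand) or hit.data == read.strand for hit in hits):
                continue
        kept.append(read)
    return kept


def build_track(
    reads: Sequence[AlignedRead],
    total_aligned: int,
    chrom_lengths: dict[str, int],
    norm_per: float = 1e7,
    five_prime: bool = False,
) -> CoverageTrack:
    """Accumulate reads into a normalized strand-specific coverage track.

    Each read contributes ``norm_per / total_aligned`` to every base it
    covers on its own strand (or, with ``five_prime=True``, only at its
    5' end).  ``total_aligned`` is the library size used for depth
    normalization — reads aligned per 10^7 by default.
    """
    if total_aligned <= 0:
        raise ValueError(f"total_aligned must be positive, got {total_aligned}")
    track = CoverageTrack(chrom_lengths, total_aligned=total_aligned, norm_per=norm_per)
    factor = track.normalization_factor
    for read in reads:
        values = track.values(read.chrom, read.strand)
        if read.end > len(values):
            raise ValueError(
                f"read [{read.start}, {read.end}) exceeds {read.chrom} "
                f"length {len(values)}"
            )
        if five_prime:
            pos = read.start if read.strand == "+" else read.end - 1
            values[pos] += factor
        else:
            values[read.start:read.end] += factor
    return track


# ---------------------------------------------------------------------------
# Track file formats


def _format_value(value: float) -> str:
    # repr round-trips float64 exactly; integers print without the mantissa
    if value == int(value):
        return str(int(value))
    return repr(float(value))


def write_bedgraph_strand(track: CoverageTrack, strand: str, path: str) -> None:
    """Write one strand of a track as 0-based half-open bedGraph.

    Runs of equal adjacent values are merged into one interval; zero runs
    are omitted.
    """
    with open(path, "w") as handle:
        for chrom in track.chromosomes():
            values = track.values(chrom, strand)
            if len(values) == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(values)]))
            for start, end in zip(starts, ends):
                value = values[start]
                if value != 0.0:
                    handle.write(f"{chrom}\t{start}\t{end}\t{_format_value(value)}\n")


def read_bedgraph_strand(
    path: str,
    chrom_lengths: dict[str, int],
    strand: str,
    track: CoverageTrack | None = None,
) -> CoverageTrack:
    """Read one strand of a bedGraph file into a track.

    Raises :class:`ValueError` with the offending line number for unknown
    chromosomes, negative values, malformed or overlapping intervals.
    """
    if track is None:
        track = CoverageTrack(chrom_lengths)
    filled = {chrom: np.zeros(length, dtype=bool) for chrom, length in chrom_lengths.items()}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom, start_s, end_s, value_s = parts
            if chrom not in chrom_lengths:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            start, end, value = int(start_s), int(end_s), float(value_s)
            if not 0 <= start < end <= chrom_lengths[chrom]:
                raise ValueError(f"{path}:{lineno}: malformed interval [{start}, {end})")
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative value {value}")
            if filled[chrom][start:end].any():
                raise ValueError(f"{path}:{lineno}: overlapping interval [{start}, {end})")
            filled[chrom][start:end] = True
            track.values(chrom, strand)[start:end] = value
    return track


def write_wiggle_strand(track: CoverageTrack, strand: str, path: str) -> None:
    """Write one strand as fixed-step wiggle (1-based starts, step 1).

    Contiguous nonzero runs become separate ``fixedStep`` blocks; zero
    stretches are omitted.
    """
    with open(path, "w") as handle:
        for chrom in track.chromosomes():
            values = track.values(chrom, strand)
            nonzero = values != 0.0
            if not nonzero.any():
                continue
            boundaries = np.flatnonzero(np.diff(nonzero.astype(np.int8)))
            starts = np.concatenate(([0], boundaries + 1))
            ends = np.concatenate((boundaries + 1, [len(values)]))
            for start, end in zip(starts, ends):
                if not nonzero[start]:
                    continue
                handle.write(f"fixedStep chrom={chrom} start={start + 1} step=1\n")
                for value in values[start:end]:
                    handle.write(_format_value(value) + "\n")


def read_wiggle_strand(
    path: str,
    chrom_lengths: dict[str, int],
    strand: str,
    track: CoverageTrack | None = None,
) -> CoverageTrack:
    """Read one strand of a fixed-step wiggle file (1-based starts)."""
    if track is None:
        track = CoverageTrack(chrom_lengths)
    chrom: str | None = None
    pos = 0
    step = 1
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("fixedStep"):
                attrs = dict(field.split("=", 1) for field in line.split()[1:])
                chrom = attrs["chrom"]
                if chrom not in chrom_lengths:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                pos = int(attrs["start"]) - 1  # wiggle is 1-based
                step = int(attrs.get("step", 1))
                if pos < 0:
                    raise ValueError(f"{path}:{lineno}: start must be >= 1")
                continue
            if line.startswith("variableStep"):
                raise ValueError(f"{path}:{lineno}: variableStep is not supported")
            if chrom is None:
                raise ValueError(f"{path}:{lineno}: value before fixedStep header")
            value = float(line)
            if value < 0:
                raise ValueError(f"{path}:{lineno}: negative value {value}")
            if pos >= chrom_lengths[chrom]:
                raise ValueError(f"{path}:{lineno}: position beyond {chrom} end")
            track.values(chrom, strand)[pos] = value
            pos += step
    return track


_WRITERS = {"bedgraph": write_bedgraph_strand, "wiggle": write_wiggle_strand}
_READERS = {"bedgraph": read_bedgraph_strand, "wiggle": read_wiggle_strand}
_EXTENSIONS = {"bedgraph": "bedgraph", "wiggle": "wig"}


def write_track(track: CoverageTrack, out_prefix: str, fmt: str = "bedgraph") -> dict[str, str]:
    """Write both strands of a track to ``<prefix>_plus/_minus`` files."""
    if fmt not in _WRITERS:
        raise ValueError(f"unknown track format {fmt!r}")
    paths = {}
    for strand, tag in (("+", "plus"), ("-", "minus")):
        path = f"{out_prefix}_{tag}.{_EXTENSIONS[fmt]}"
        _WRITERS[fmt](track, strand, path)
        paths[strand] = path
    return paths


def read_track(
    plus_path: str,
    minus_path: str,
    chrom_lengths: dict[str, int],
    fmt: str = "bedgraph",
    total_aligned: int | None = None,
    norm_per: float = 1e7,
) -> CoverageTrack:
    """Read a pair of per-strand track files into one CoverageTrack."""
    if fmt not in _READERS:
        raise ValueError(f"unknown track format {fmt!r}")
    track = CoverageTrack(chrom_lengths, total_aligned=total_aligned, norm_per=norm_per)
    _READERS[fmt](plus_path, chrom_lengths, "+", track)
    _READERS[fmt](minus_path, chrom_lengths, "-", track)
    return track


# ---------------------------------------------------------------------------
# BED helpers


def read_bed_intervals(path: str) -> list[tuple[str, int, int, str]]:
    """Read BED6 (or BED3, strand defaulting to '+') into interval tuples."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if frame.shape[1] < 3:
        raise ValueError(f"{path}: expected at least 3 BED columns")
    out = []
    for row in frame.itertuples(index=False):
        strand = row[5] if len(row) >= 6 else "+"
        out.append((str(row[0]), int(row[1]), int(row[2]), str(strand)))
    return out


def read_bed_reads(path: str) -> list[AlignedRead]:
    """Read aligned reads from a BED file."""
    return [AlignedRead(*fields) for fields in read_bed_intervals(path)]


def write_bed_reads(reads: Sequence[AlignedRead], path: str) -> None:
    with open(path, "w") as handle:
        for i, read in enumerate(reads):
            handle.write(
                f"{read.chrom}\t{read.start}\t{read.end}\tread_{i}\t0\t{read.strand}\n"
            )
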