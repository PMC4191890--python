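"""Genome-wide Readthrough Index scan.

At each genomic position, occupancy is tallied in 500-bp windows upstream
and downstream of the position on each strand.  The readthrough fraction is
downstream / (downstream + upstream); the Readthrough Index is that fraction
in the depleted (treated) sample minus the control sample.  Positions where
the index clears a minimum, the windows hold enough signal, and the treated
sample gained occupancy are candidate termination regions; a greedy
non-overlap pass keeps the strongest candidate per region.

Window convention: the downstream window includes the focal position and the
upstream window excludes it, so together they partition a 2x window span.
On the minus strand downstream runs toward decreasing coordinates, so the
two windows swap roles.
"""

from __future__ import annotations

import bisect
import collections
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coverage_io import STRANDS, CoverageTrack


@dataclass(frozen=True)
class ReadthroughPoint:
    """Per-position readthrough statistics for control and treated tracks."""

    chrom: str
    pos: int
    strand: str
    up_control: float
    down_control: float
    up_treated: float
    down_treated: float
    frac_control: float
    frac_treated: float
    index: float

    @property
    def total_control(self) -> float:
        return self.up_control + self.down_control

    @property
    def total_treated(self) -> float:
        return self.up_treated + self.down_treated


@dataclass(frozen=True)
class ScanThresholds:
    """Filters applied to every scanned position.

    window
        flanking window size in nt (upstream and downstream each).
    min_index
        minimum Readthrough Index (treated minus control fraction).
    min_reads
        minimum summed track value over the combined 2x-window span,
        required in either sample.  Applies to the normalized values by
        default; see ``global_scan(raw_counts=...)`` for raw-count mode.
    require_treated_gt_control
        require more total signal over the span in treated than control.
    min_separation
        minimum distance between selected candidates on one strand.
    """

    window: int = 500
    min_index: float = 0.10
    min_reads: float = 1000.0
    require_treated_gt_control: bool = True
    min_separation: int = 1000

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if not 0 <= self.min_index <= 1:
            raise ValueError("min_index must be in [0, 1]")
        if self.min_reads < 0:
            raise ValueError("min_reads must be non-negative")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")


def window_sums(
    track: CoverageTrack,
    chrom: str,
    pos: int,
    strand: str,
    window: int = 500,
) -> tuple[float, float] | None:
    """Summed track values in the upstream/downstream windows at ``pos``.

    Returns ``(up_sum, down_sum)`` oriented by transcription direction, or
    ``None`` when the position is too close to a chromosome end for both
    windows to fit.
    """
    values = track.values(chrom, strand)
    if pos < window or pos > len(values) - window:
        return None
    left = float(values[pos - window:pos].sum())
    right = float(values[pos:pos + window].sum())
    if strand == "+":
        return left, right
    return right, left


def readthrough_fraction(up: float, down: float) -> float | None:
    """Fraction of windowed signal downstream: down / (up + down).

    ``None`` marks the undefined case of an empty span.
    """
    if up < 0 or down < 0:
        raise ValueError(f"window sums must be non-negative, got ({up}, {down})")
    total = up + down
    if total == 0:
        return None
    return down / total


def readthrough_index(
    frac_treated: float | None, frac_control: float | None
) -> float | None:
    """Readthrough Index: treated fraction minus control fraction."""
    if frac_treated is None or frac_control is None:
        return None
    return frac_treated - frac_control


def _strand_window_sums(
    values: np.ndarray, positions: np.ndarray, window: int, strand: str
) -> tuple[np.ndarray, np.ndarray]:
    cumulative = np.concatenate(([0.0], np.cumsum(values)))
    left = cumulative[positions] - cumulative[positions - window]
    right = cumulative[positions + window] - cumulative[positions]
    if strand == "+":
        return left, right
    return right, left


def global_scan(
    control: CoverageTrack,
    treated: CoverageTrack,
    thresholds: ScanThresholds | None = None,
    stride: int = 1,
    raw_counts: tuple[float, float] | None = None,
) -> list[ReadthroughPoint]:
    """Score every genomic position on both strands and apply the filters.

    A position passes when its Readthrough Index exceeds ``min_index``, the
    combined window span holds at least ``min_reads`` in either sample, and
    (by default) the treated span total exceeds the control span total.
    Passing points are returned sorted by index descending, ties broken by
    (chrom, pos, strand).

    ``raw_counts``, if given as ``(control_factor, treated_factor)``, applies
    the ``min_reads`` filter to raw counts by dividing each sample's span
    total by its normalization factor first.
    """
    thresholds = thresholds or ScanThresholds()
    if control.chrom_lengths != treated.chrom_lengths:
        raise ValueError("control and treated tracks cover different genomes")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    window = thresholds.window
    control_div, treated_div = raw_counts if raw_counts is not None else (1.0, 1.0)

    points: list[ReadthroughPoint] = []
    for chrom in control.chromosomes():
        length = control.chrom_lengths[chrom]
        if length < 2 * window:
            continue
        positions = np.arange(window, length - window + 1, stride)
        for strand in STRANDS:
            up_c, down_c = _strand_window_sums(
                control.values(chrom, strand), positions, window, strand
            )
            up_t, down_t = _strand_window_sums(
                treated.values(chrom, strand), positions, window, strand
            )
            total_c = up_c + down_c
            total_t = up_t + down_t
            with np.errstate(invalid="ignore", divide="ignore"):
                frac_c = np.where(total_c > 0, down_c / total_c, np.nan)
                frac_t = np.where(total_t > 0, down_t / total_t, np.nan)
            index = frac_t - frac_c
            passing = (
                ~np.isnan(index)
                & (index > thresholds.min_index)
                & (
                    (total_c / control_div >= thresholds.min_reads)
                    | (total_t / treated_div >= thresholds.min_reads)
                )
            )
            if thresholds.require_treated_gt_control:
                passing &= total_t > total_c
            for i in np.flatnonzero(passing):
                points.append(
                    ReadthroughPoint(
                        chrom=chrom,
                        pos=int(positions[i]),
                        strand=strand,
                        up_control=float(up_c[i]),
                        down_control=float(down_c[i]),
                        up_treated=float(up_t[i]),
                        down_treated=float(down_t[i]),
                        frac_control=float(frac_c[i]),
                        frac_treated=float(frac_t[i]),
                        index=float(index[i]),
                    )
                )
    points.sort(key=lambda p: (-p.index, p.chrom, p.pos, p.strand))
    return points


def select_candidates(
    points: Sequence[ReadthroughPoint], min_separation: int = 1000
) -> list[ReadthroughPoint]:
    """Greedy non-overlapping selection of the strongest candidates.

    Points are visited in order of decreasing index (ties by chrom, pos,
    strand); a point is kept iff no already-kept point on the same
    chromosome and strand lies within ``min_separation`` nt.
    """
    ordered = sorted(points, key=lambda p: (-p.index, p.chrom, p.pos, p.strand))
    kept: list[ReadthroughPoint] = []
    occupied: dict[tuple[str, str], list[int]] = collections.defaultdict(list)
    for point in ordered:
        positions = occupied[(point.chrom, point.strand)]
        i = bisect.bisect_left(positions, point.pos)
        if i > 0 and point.pos - positions[i - 1] < min_separation:
            continue
        if i < len(positions) and positions[i] - point.pos < min_separation:
            continue
        bisect.insort(positions, point.pos)
        kept.append(point)
    return kept
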