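"""Anchor-centered metagene profiles and percent-readthrough rankings.

Metagene matrices average occupancy in fixed-width bins (10 bp by default)
across many anchor-aligned windows, oriented so transcription runs
left→right.  Percent-readthrough rankings score each terminator by
100 × (treated − control) readthrough fraction and order terminators from
highest to lowest, with ranks expressed as fractions of the total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coverage_io import CoverageTrack
from .readthrough_scan import readthrough_fraction, readthrough_index, window_sums

Anchor = tuple[str, int, str, str]  # chrom, pos, strand, id


def _coerce_anchor(anchor) -> Anchor:
    """Accept (chrom, pos, strand[, id]) tuples or site-like objects."""
    if hasattr(anchor, "chrom"):
        aid = getattr(anchor, "source_id", None) or (
            f"{anchor.chrom}:{anchor.pos}:{anchor.strand}"
        )
        return (anchor.chrom, int(anchor.pos), anchor.strand, aid)
    if len(anchor) == 3:
        chrom, pos, strand = anchor
        return (chrom, int(pos), strand, f"{chrom}:{pos}:{strand}")
    chrom, pos, strand, aid = anchor
    return (chrom, int(pos), strand, str(aid))


@dataclass
class MetageneMatrix:
    """Anchors × bins matrix of mean per-base occupancy.

    Rows follow ``anchors`` order; anchors whose window runs off a
    chromosome end are excluded and listed in ``excluded`` with a reason.
    The trailing bin, when the window length is not divisible by the bin
    size, averages over its actual base count.
    """

    anchors: list[Anchor]
    flank: int
    bin_size: int
    values: np.ndarray
    excluded: list[tuple[Anchor, str]] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def bin_offsets(self) -> np.ndarray:
        """Offset of each bin start relative to the anchor, in nt."""
        return np.arange(self.n_bins) * self.bin_size - self.flank


def anchor_matrix(
    track: CoverageTrack,
    anchors: Sequence,
    flank: int = 1000,
    bin_size: int = 10,
) -> MetageneMatrix:
    """Build the anchors × bins occupancy matrix for one track.

    Each row covers ``[pos − flank, pos + flank]`` (length 2·flank + 1),
    reversed for minus-strand anchors so transcription runs left→right,
    then averaged within consecutive ``bin_size`` windows.
    """
    if len(anchors) == 0:
        raise ValueError("anchor list is empty")
    if flank <= 0 or bin_size <= 0:
        raise ValueError("flank and bin_size must be positive")
    span = 2 * flank + 1
    edges = np.arange(0, span, bin_size)
    counts = np.diff(np.concatenate((edges, [span])))

    rows: list[np.ndarray] = []
    kept: list[Anchor] = []
    excluded: list[tuple[Anchor, str]] = []
    for raw in anchors:
        anchor = _coerce_anchor(raw)
        chrom, pos, strand, _ = anchor
        values = track.values(chrom, strand)
        if pos < flank or pos + flank >= len(values):
            excluded.append((anchor, "window_out_of_bounds"))
            continue
        window = values[pos - flank:pos + flank + 1].astype(float)
        if strand == "-":
            window = window[::-1]
        rows.append(np.add.reduceat(window, edges) / counts)
        kept.append(anchor)

    matrix = (
        np.vstack(rows) if rows else np.empty((0, len(edges)), dtype=float)
    )
    return MetageneMatrix(
        anchors=kept, flank=flank, bin_size=bin_size, values=matrix,
        excluded=excluded,
    )


def mean_profile(
    matrix: MetageneMatrix, with_sem: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Unweighted per-bin mean across anchors (optionally with its SEM)."""
    if matrix.values.shape[0] == 0:
        raise ValueError("metagene matrix has no rows")
    means = matrix.values.mean(axis=0)
    if not with_sem:
        return means
    n = matrix.values.shape[0]
    if n > 1:
        sem = matrix.values.std(axis=0, ddof=1) / math.sqrt(n)
    else:
        sem = np.zeros_like(means)
    return means, sem


@dataclass
class ReadthroughRanking:
    """Per-terminator percent readthrough, ordered highest to lowest.

    ``values`` holds 100 × (treated − control) readthrough fractions,
    weakly decreasing; ``rank_fraction`` is (k / N) for k = 1..N.
    """

    ids: list[str]
    values: np.ndarray
    rank_fraction: np.ndarray
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.ids)


def percent_readthrough_ranking(
    terminators: Sequence,
    control: CoverageTrack,
    treated: CoverageTrack,
    window: int = 500,
) -> ReadthroughRanking:
    """Rank terminators by percent readthrough gained on depletion.

    Each terminator is scored with the same windowed machinery as the
    genome scan, evaluated at its (refined) termination point.  Sites too
    close to a chromosome end, or with no signal in either sample, are
    excluded and logged in the result.
    """
    if len(terminators) == 0:
        raise ValueError("terminator list is empty")
    scored: list[tuple[str, float]] = []
    excluded: list[tuple[str, str]] = []
    for raw in terminators:
        chrom, pos, strand, tid = _coerce_anchor(raw)
        sums_control = window_sums(control, chrom, pos, strand, window)
        sums_treated = window_sums(treated, chrom, pos, strand, window)
        if sums_control is None or sums_treated is None:
            excluded.append((tid, "near_chromosome_end"))
            continue
        index = readthrough_index(
            readthrough_fraction(*sums_treated),
            readthrough_fraction(*sums_control),
        )
        if index is None:
            excluded.append((tid, "no_signal"))
            continue
        scored.append((tid, 100.0 * index))

    scored.sort(key=lambda item: (-item[1], item[0]))
    ids = [tid for tid, _ in scored]
    values = np.array([value for _, value in scored], dtype=float)
    n = len(scored)
    rank_fraction = np.arange(1, n + 1, dtype=float) / n if n else np.empty(0)
    return ReadthroughRanking(
        ids=ids, values=values, rank_fraction=rank_fraction, excluded=excluded
    )
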