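"""Sequence analysis of termination regions.

Termination of non-polyadenylated transcripts in yeast is signalled by
short RNA elements in the nascent transcript: the Nrd1 binding site
GUA[A/G], the Nab3 binding sites UCUU/UCUUG, and runs of U residues that
form unstable rU:dA hybrids near the release region.  This module extracts
the RNA-sense window 5' of each termination point, scans it for degenerate
motifs (counting overlapping matches), tallies maximal U-runs, and tests
motif enrichment against dinucleotide-preserving shuffles — a background
that keeps the AT-richness of yeast intergenic sequence intact.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")


def _to_rna(dna: str) -> str:
    return dna.upper().replace("T", "U")


def _validate_rna(seq: str) -> None:
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-RNA characters: {sorted(bad)}")


@dataclass(frozen=True)
class TerminatorSequence:
    """RNA-sense sequence of the window 5' of a termination point."""

    site_id: str
    sequence: str
    clipped: bool = False

    def __post_init__(self) -> None:
        _validate_rna(self.sequence)


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate RNA motif, with bracketed alternatives (e.g. GUA[AG])."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("pattern must be non-empty")
        stripped = self.pattern.replace("[", "").replace("]", "")
        bad = set(stripped) - RNA_ALPHABET
        if bad:
            raise ValueError(f"pattern contains invalid characters: {sorted(bad)}")
        if self.pattern.count("[") != self.pattern.count("]"):
            raise ValueError(f"unbalanced brackets in pattern {self.pattern!r}")

    @classmethod
    def parse(cls, pattern: str, name: str | None = None) -> "MotifPattern":
        return cls(name=name or pattern, pattern=pattern)

    def regex(self) -> re.Pattern:
        # lookahead so overlapping matches are all counted
        return re.compile(f"(?=({self.pattern}))")


@dataclass(frozen=True)
class MotifHits:
    """All (overlapping) matches of one motif in one sequence."""

    count: int
    positions: tuple[int, ...]


@dataclass
class URunStats:
    """Maximal U-runs of length >= min_len, as (start, length) pairs."""

    runs: list[tuple[int, int]]
    min_len: int
    window: tuple[int, int] | None = None

    @property
    def count(self) -> int:
        return len(self.runs)

    @property
    def lengths(self) -> list[int]:
        return [length for _, length in self.runs]


def extract_upstream(
    genome: dict[str, str],
    site,
    length: int = 150,
) -> TerminatorSequence:
    """Extract the RNA-sense window 5' of a termination point.

    Plus strand: bases ``[pos − length, pos)`` read forward; minus strand:
    bases ``(pos, pos + length]`` reverse-complemented.  DNA is
    transliterated to RNA.  Windows clipped at a chromosome end are
    flagged; a site off the genome is an error.
    """
    chrom, pos, strand = site.chrom, site.pos, site.strand
    if chrom not in genome:
        raise ValueError(f"site chromosome {chrom!r} not in genome")
    sequence = genome[chrom]
    if not 0 <= pos < len(sequence):
        raise ValueError(f"site position {chrom}:{pos} is off the genome")
    if strand == "+":
        start = max(0, pos - length)
        window = sequence[start:pos]
        clipped = pos - length < 0
    else:
        end = min(len(sequence), pos + 1 + length)
        window = str(Seq(sequence[pos + 1:end]).reverse_complement())
        clipped = pos + 1 + length > len(sequence)
    site_id = getattr(site, "source_id", None) or f"{chrom}:{pos}:{strand}"
    return TerminatorSequence(
        site_id=site_id, sequence=_to_rna(window), clipped=clipped
    )


def scan_motif(seq: str, pattern: MotifPattern | str) -> MotifHits:
    """Count all matches of a motif in an RNA sequence, overlaps included."""
    if isinstance(pattern, str):
        pattern = MotifPattern.parse(pattern)
    _validate_rna(seq)
    positions = tuple(m.start() for m in pattern.regex().finditer(seq))
    return MotifHits(count=len(positions), positions=positions)


def u_run_stats(
    seq: str,
    min_len: int = 3,
    window: tuple[int, int] | None = None,
) -> URunStats:
    """Maximal U-runs of length >= ``min_len`` overlapping ``window``.

    ``window`` is a half-open (start, end) index range within the
    sequence; ``None`` scans the whole sequence.  Runs are maximal — never
    extendable by an adjacent U.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    _validate_rna(seq)
    runs = []
    for match in re.finditer(f"U{{{min_len},}}", seq):
        start, end = match.start(), match.end()
        if window is not None and not (start < window[1] and end > window[0]):
            continue
        runs.append((start, end - start))
    return URunStats(runs=runs, min_len=min_len, window=window)


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffling and enrichment


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving its exact dinucleotide counts.

    Altschul–Erickson shuffle: the sequence is viewed as an Eulerian walk
    on the digraph whose edges are its dinucleotides; a uniformly random
    walk with the same start and end vertices and the same edge multiset
    is generated by sampling a random arborescence toward the end vertex
    (via rejection) and permuting the remaining out-edges.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    first, last = seq[0], seq[-1]
    vertices = list(edges)

    def reaches_last(last_edge: dict[str, str]) -> bool:
        for vertex in vertices:
            if vertex == last:
                continue
            seen = {vertex}
            current = vertex
            while current != last:
                current = last_edge.get(current)
                if current is None or current in seen:
                    return False
                seen.add(current)
        return True

    while True:  # rejection sampling; <= 4 vertices, accepts quickly
        last_edge = {
            v: targets[rng.integers(len(targets))]
            for v, targets in edges.items()
            if v != last
        }
        if reaches_last(last_edge):
            break

    shuffled: dict[str, list[str]] = {}
    for vertex, targets in edges.items():
        pool = list(targets)
        if vertex != last:
            pool.remove(last_edge[vertex])
        rng.shuffle(pool)
        if vertex != last:
            pool.append(last_edge[vertex])
        shuffled[vertex] = pool

    out = [first]
    current = first
    cursor = {v: 0 for v in shuffled}
    for _ in range(len(seq) - 1):
        nxt = shuffled[current][cursor[current]]
        cursor[current] += 1
        out.append(nxt)
        current = nxt
    return "".join(out)


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed motif count against the dinucleotide-shuffle null."""

    observed: int
    null_mean: float
    fold_enrichment: float
    p_value: float
    n_shuffles: int


def motif_enrichment(
    seqs: Sequence[str],
    pattern: MotifPattern | str,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Empirical enrichment of a motif over dinucleotide-preserving shuffles.

    The observed total match count across sequences is compared with the
    distribution of totals over ``n_shuffles`` per-sequence shuffles;
    p = (1 + #{shuffles >= observed}) / (1 + n_shuffles).  Deterministic
    under a fixed seed.
    """
    if len(seqs) < 2:
        raise ValueError("enrichment needs at least 2 sequences")
    if n_shuffles < 100:
        logger.warning(
            "n_shuffles=%d is low; empirical p-values are coarse", n_shuffles
        )
    if isinstance(pattern, str):
        pattern = MotifPattern.parse(pattern)
    rng = np.random.default_rng(seed)
    observed = sum(scan_motif(s, pattern).count for s in seqs)
    null = np.empty(n_shuffles, dtype=int)
    for k in range(n_shuffles):
        null[k] = sum(
            scan_motif(dinucleotide_shuffle(s, rng), pattern).count for s in seqs
        )
    null_mean = float(null.mean())
    exceed = int((null >= observed).sum())
    p_value = (1 + exceed) / (1 + n_shuffles)
    if observed == 0:
        fold = 0.0
    elif null_mean == 0:
        fold = float("inf")
    else:
        fold = observed / null_mean
    return EnrichmentResult(
        observed=observed, null_mean=null_mean, fold_enrichment=fold,
        p_value=p_value, n_shuffles=n_shuffles,
    )
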