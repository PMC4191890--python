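"""Synthetic genomes, occupancy tracks, pA tables and reads with known truth.

The generator emulates the occupancy structure the termination analysis
assumes: Poisson per-base counts over a gene-body plateau, a Gaussian
pre-termination pause peak in the control, a short exponential decay past
the termination point, and factor-class-specific behaviour under nuclear
depletion — long processive readthrough of non-pA transcripts when the
Nrd1 sensor is lost, a short few-hundred-nt extension when the Sen1
helicase is lost, and a 3' pileup confined within ~200 nt of the pA site
(without extended readthrough) when the Ysh1 endonuclease is lost.
Genomes are AT-rich intergenically with planted Nrd1/Nab3 motifs and
U-runs around non-pA terminators, so sequence analyses have a recoverable
ground truth.

Every simulator takes an explicit seed and is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .coverage_io import ADAPTER_3P, AlignedRead, CoverageTrack

LOCUS_CLASSES = ("mRNA", "snoRNA", "CUT", "antisenseCUT")
NONPA_CLASSES = frozenset({"snoRNA", "CUT", "antisenseCUT"})
FACTOR_CLASSES = ("Nrd1", "Sen1", "Ysh1")
CONDITIONS = ("control", "depleted")

#: Transcript classes whose terminators respond to each factor's depletion:
#: Nrd1/Sen1 act in the non-pA (NNS) pathway, Ysh1 in pA cleavage.
TARGET_CLASSES = {
    "Nrd1": NONPA_CLASSES,
    "Sen1": NONPA_CLASSES,
    "Ysh1": frozenset({"mRNA"}),
}

_CLASS_CODES = {"mRNA": 1, "snoRNA": 2, "CUT": 3, "antisenseCUT": 4}


@dataclass(frozen=True)
class LocusSpec:
    """One transcribed locus with a planted ground-truth termination point."""

    id: str
    chrom: str
    strand: str
    tss: int
    term_point: int
    locus_class: str
    body_rate: float

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-'")
        if self.locus_class not in LOCUS_CLASSES:
            raise ValueError(f"{self.id}: unknown locus_class {self.locus_class!r}")
        if self.body_rate < 0:
            raise ValueError(f"{self.id}: body_rate must be >= 0")
        if self.strand == "+" and not self.tss < self.term_point:
            raise ValueError(f"{self.id}: tss must precede term_point on '+'")
        if self.strand == "-" and not self.tss > self.term_point:
            raise ValueError(f"{self.id}: tss must precede term_point on '-'")

    @property
    def direction(self) -> int:
        return 1 if self.strand == "+" else -1

    @property
    def gene_start(self) -> int:
        return min(self.tss, self.term_point)

    @property
    def gene_end(self) -> int:
        return max(self.tss, self.term_point)


@dataclass(frozen=True)
class OccupancyModel:
    """Rate-function parameters for simulated Pol II occupancy.

    All rates are expected events per base.  The control rate at a locus is
    background + a body plateau on [tss, term_point] + a Gaussian pause
    bump of amplitude ``pause_amp × body_rate`` centered ``pause_offset``
    nt upstream of the termination point (polymerase pauses before it
    terminates) + an exponential tail exp(−d/decay_tau_control) past the
    point.  Under depletion, target-class loci lose the pause and sustain
    ``readthrough_alpha × body_rate`` for ``readthrough_len`` nt before
    decaying (Nrd1/Sen1), or gain an enlarged pileup bump just downstream
    of the pA site with no extension (Ysh1).
    """

    pause_amp: float = 2.0
    pause_sigma: float = 15.0
    pause_offset: float = 30.0
    decay_tau_control: float = 20.0
    readthrough_alpha: float = 0.5
    readthrough_len: float = 1500.0
    background_rate: float = 0.05
    ysh1_pileup_gain: float = 3.0
    ysh1_pileup_offset: float = 80.0
    ysh1_pileup_sigma: float = 40.0

    def __post_init__(self) -> None:
        non_negative = (
            self.pause_amp, self.pause_sigma, self.decay_tau_control,
            self.readthrough_len, self.background_rate,
            self.ysh1_pileup_gain, self.ysh1_pileup_sigma,
        )
        if any(value < 0 for value in non_negative):
            raise ValueError("model rates and scales must be non-negative")
        if not 0 <= self.readthrough_alpha <= 1:
            raise ValueError("readthrough_alpha must be in [0, 1]")
        if self.pause_sigma == 0 or self.decay_tau_control == 0:
            raise ValueError("pause_sigma and decay_tau_control must be positive")

    @classmethod
    def for_factor(cls, factor_class: str, **overrides) -> "OccupancyModel":
        """Preset per factor class.

        Nrd1-like depletion is processive (>= 1 kb readthrough), Sen1-like
        extends only a few hundred nt, Ysh1-like piles up within 200 nt of
        the pA site without extension.
        """
        if factor_class not in FACTOR_CLASSES:
            raise ValueError(f"unknown factor_class {factor_class!r}")
        lengths = {"Nrd1": 1500.0, "Sen1": 250.0, "Ysh1": 0.0}
        overrides.setdefault("readthrough_len", lengths[factor_class])
        return cls(**overrides)


@dataclass(frozen=True)
class SequenceSpec:
    """Composition and planted sequence content of a simulated genome.

    ``motif_inserts`` and ``u_run_inserts`` windows are in transcription
    coordinates relative to the termination point (upstream negative);
    inserts are planted on the transcribed strand of every non-pA locus.
    """

    gc_intergenic: float = 0.30
    gc_genic: float = 0.40
    motif_inserts: tuple[tuple[str, int, tuple[int, int]], ...] = (
        ("GUA[AG]", 3, (-150, 0)),
        ("UCUUG", 3, (-150, 0)),
    )
    u_run_inserts: tuple[tuple[int, int, tuple[int, int]], ...] = (
        (5, 2, (-50, 50)),
    )

    def __post_init__(self) -> None:
        for gc in (self.gc_intergenic, self.gc_genic):
            if not 0 < gc < 1:
                raise ValueError("GC fractions must be in (0, 1)")
        for _, count, (lo, hi) in self.motif_inserts + tuple(
            (f"U{n}", c, w) for n, c, w in self.u_run_inserts
        ):
            if count < 0 or hi <= lo:
                raise ValueError("insert counts must be >= 0 and windows non-empty")


def validate_loci(
    loci: list[LocusSpec],
    chrom_lengths: dict[str, int],
    min_separation: int = 2000,
    min_flank: int = 1000,
) -> None:
    """Check locus placement: in-bounds with flanks, same-strand separated.

    Raises :class:`ValueError` naming the offending locus or pair.
    """
    for locus in loci:
        if locus.chrom not in chrom_lengths:
            raise ValueError(f"{locus.id}: unknown chromosome {locus.chrom!r}")
        length = chrom_lengths[locus.chrom]
        if locus.gene_start < min_flank or locus.gene_end > length - min_flank:
            raise ValueError(
                f"{locus.id}: needs >= {min_flank} nt flanks within "
                f"{locus.chrom} (length {length})"
            )
    grouped: dict[tuple[str, str], list[LocusSpec]] = {}
    for locus in loci:
        grouped.setdefault((locus.chrom, locus.strand), []).append(locus)
    for group in grouped.values():
        group.sort(key=lambda l: l.gene_start)
        for left, right in zip(group, group[1:]):
            gap = right.gene_start - left.gene_end
            if gap < min_separation:
                raise ValueError(
                    f"same-strand loci {left.id} and {right.id} are separated "
                    f"by {gap} nt (< {min_separation})"
                )


# ---------------------------------------------------------------------------
# Occupancy simulation


def _add_locus_rate(
    rate: np.ndarray,
    locus: LocusSpec,
    model: OccupancyModel,
    condition: str,
    factor_class: str,
) -> None:
    """Add one locus's expected rate (minus background) into ``rate``."""
    is_target = locus.locus_class in TARGET_CLASSES[factor_class]
    depleted = condition == "depleted" and is_target
    tau = model.decay_tau_control
    margin = int(model.readthrough_len + 10 * tau + 6 * model.pause_sigma + 200)
    lo = max(0, locus.gene_start - margin)
    hi = min(len(rate), locus.gene_end + margin + 1)
    x = np.arange(lo, hi)
    d = (x - locus.term_point) * locus.direction  # distance past the term point
    t = (x - locus.tss) * locus.direction  # distance from the TSS
    body = locus.body_rate

    segment = np.zeros(hi - lo)
    segment[(t >= 0) & (d <= 0)] += body  # gene-body plateau

    downstream = d > 0
    if depleted and factor_class in ("Nrd1", "Sen1"):
        # pause lost; plateau sustained at alpha for readthrough_len, then decay
        within = downstream & (d <= model.readthrough_len)
        beyond = d > model.readthrough_len
        segment[within] += model.readthrough_alpha * body
        segment[beyond] += (
            model.readthrough_alpha * body
            * np.exp(-(d[beyond] - model.readthrough_len) / tau)
        )
    else:
        segment[downstream] += body * np.exp(-d[downstream] / tau)
        center = -model.pause_offset  # pause precedes the termination point
        segment += (
            model.pause_amp * body
            * np.exp(-((d - center) ** 2) / (2 * model.pause_sigma**2))
        )
        if depleted and factor_class == "Ysh1":
            # uncleaved pA site: enlarged pileup just downstream, no extension
            segment += (
                model.pause_amp * model.ysh1_pileup_gain * body
                * np.exp(
                    -((d - model.ysh1_pileup_offset) ** 2)
                    / (2 * model.ysh1_pileup_sigma**2)
                )
            )
    rate[lo:hi] += segment


def expected_rate_track(
    loci: list[LocusSpec],
    model: OccupancyModel,
    condition: str,
    factor_class: str,
    chrom_lengths: dict[str, int],
) -> CoverageTrack:
    """Deterministic expected-rate track (the Poisson means).

    This is the closed-form rate function: summing it over a window is the
    exact integral used as the analytic oracle for simulated readthrough
    fractions.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if factor_class not in FACTOR_CLASSES:
        raise ValueError(f"unknown factor_class {factor_class!r}")
    validate_loci(loci, chrom_lengths)
    track = CoverageTrack(chrom_lengths)
    for chrom in track.chromosomes():
        for strand in ("+", "-"):
            rate = track.values(chrom, strand)
            rate += model.background_rate
            for locus in loci:
                if locus.chrom == chrom and locus.strand == strand:
                    _add_locus_rate(rate, locus, model, condition, factor_class)
    return track


def simulate_occupancy(
    loci: list[LocusSpec],
    model: OccupancyModel,
    condition: str,
    factor_class: str,
    chrom_lengths: dict[str, int],
    seed: int,
) -> CoverageTrack:
    """Draw per-base counts ~ Poisson(rate) for one condition.

    Counts are independent across bases; the same seed reproduces the
    track exactly.
    """
    rates = expected_rate_track(loci, model, condition, factor_class, chrom_lengths)
    rng = np.random.default_rng(seed)
    track = CoverageTrack(chrom_lengths)
    for chrom in track.chromosomes():
        for strand in ("+", "-"):
            counts = rng.poisson(rates.values(chrom, strand)).astype(float)
            track.set_values(chrom, strand, counts)
    return track


# ---------------------------------------------------------------------------
# Genome simulation

_GC_LETTERS = np.array(["G", "C"])
_AT_LETTERS = np.array(["A", "T"])


def _resolve_degenerate(pattern: str, rng: np.random.Generator) -> str:
    """Instantiate a bracketed RNA pattern to a concrete RNA string."""
    out = []
    i = 0
    while i < len(pattern):
        if pattern[i] == "[":
            j = pattern.index("]", i)
            choices = pattern[i + 1:j]
            out.append(choices[rng.integers(len(choices))])
            i = j + 1
        else:
            out.append(pattern[i])
            i += 1
    return "".join(out)


@dataclass
class Annotation:
    """BED6-style annotation row for a simulated locus."""

    chrom: str
    start: int
    end: int
    name: str
    score: int  # class code
    strand: str


def simulate_genome(
    spec: SequenceSpec,
    loci: list[LocusSpec],
    chrom_lengths: dict[str, int],
    seed: int,
    insert_classes: frozenset[str] = NONPA_CLASSES,
) -> tuple[dict[str, str], list[Annotation]]:
    """Generate a genome with stated GC composition and planted motifs.

    Intergenic sequence is AT-rich (``gc_intergenic``); gene bodies use
    ``gc_genic``.  For every locus whose class is in ``insert_classes``,
    the declared motifs and U-runs are planted on the transcribed strand
    at non-overlapping positions inside their windows relative to the
    termination point.  Deterministic under a fixed seed.
    """
    validate_loci(loci, chrom_lengths)
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    arrays: dict[str, np.ndarray] = {}
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        p_gc = np.full(length, spec.gc_intergenic)
        for locus in loci:
            if locus.chrom == chrom:
                p_gc[locus.gene_start:locus.gene_end + 1] = spec.gc_genic
        is_gc = rng.random(length) < p_gc
        which = rng.integers(0, 2, size=length)
        seq = np.where(is_gc, _GC_LETTERS[which], _AT_LETTERS[which])
        arrays[chrom] = seq

    for locus in sorted(loci, key=lambda l: l.id):
        if locus.locus_class not in insert_classes:
            continue
        seq = arrays[locus.chrom]
        occupied: list[tuple[int, int]] = []  # transcription-offset intervals
        inserts = list(spec.motif_inserts) + [
            ("U" * run_len, count, window)
            for run_len, count, window in spec.u_run_inserts
        ]
        for pattern, count, (win_lo, win_hi) in inserts:
            for _ in range(count):
                rna = _resolve_degenerate(pattern, rng)
                m = len(rna)
                if win_hi - win_lo < m:
                    raise ValueError(
                        f"{locus.id}: window [{win_lo}, {win_hi}) too small "
                        f"for insert {pattern!r}"
                    )
                for _attempt in range(200):
                    offset = int(rng.integers(win_lo, win_hi - m + 1))
                    span = (offset, offset + m)
                    if all(span[1] <= lo or span[0] >= hi for lo, hi in occupied):
                        break
                else:
                    raise ValueError(
                        f"{locus.id}: could not place insert {pattern!r} "
                        f"without overlap in [{win_lo}, {win_hi})"
                    )
                occupied.append(span)
                dna = rna.replace("U", "T")
                if locus.strand == "+":
                    start = locus.term_point + offset
                    seq[start:start + m] = list(dna)
                else:
                    # transcription offsets o..o+m-1 map to descending coords
                    end = locus.term_point - offset  # inclusive genome end
                    start = end - m + 1
                    rc = str(Seq(dna).reverse_complement())
                    seq[start:end + 1] = list(rc)
                if start < 0 or start + m > len(seq):
                    raise ValueError(f"{locus.id}: insert {pattern!r} out of bounds")

    for chrom, seq in arrays.items():
        genome[chrom] = "".join(seq)
    annotations = [
        Annotation(
            chrom=locus.chrom, start=locus.gene_start, end=locus.gene_end + 1,
            name=locus.id, score=_CLASS_CODES[locus.locus_class],
            strand=locus.strand,
        )
        for locus in loci
    ]
    return genome, annotations


# ---------------------------------------------------------------------------
# pA tables and raw reads


def simulate_pa_table(
    loci: list[LocusSpec],
    seed: int,
    noise_sites: int = 0,
    chrom_lengths: dict[str, int] | None = None,
    major_reads_mean: float = 1000.0,
    minor_frac: float | None = None,
    minor_offset: int = 50,
    noise_reads_max: int = 50,
) -> pd.DataFrame:
    """Simulate a pA-site table (chrom, pos, strand, raw_reads).

    Every mRNA locus gets a major site at its termination (pA) point with
    a Poisson-drawn read count; ``minor_frac`` optionally adds a competing
    minor site ``minor_offset`` nt downstream with that fraction of the
    major's reads; ``noise_sites`` adds weakly supported decoys at random
    positions (requires ``chrom_lengths``).
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, int, str, int]] = []
    for locus in loci:
        if locus.locus_class != "mRNA":
            continue
        reads = int(rng.poisson(major_reads_mean))
        rows.append((locus.chrom, locus.term_point, locus.strand, reads))
        if minor_frac is not None:
            pos = locus.term_point + minor_offset * locus.direction
            rows.append((locus.chrom, pos, locus.strand, int(round(reads * minor_frac))))
    if noise_sites > 0:
        if chrom_lengths is None:
            raise ValueError("chrom_lengths is required to place noise sites")
        chroms = sorted(chrom_lengths)
        for _ in range(noise_sites):
            chrom = chroms[rng.integers(len(chroms))]
            pos = int(rng.integers(0, chrom_lengths[chrom]))
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom, pos, strand, int(rng.integers(0, noise_reads_max))))
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "raw_reads"])


def simulate_reads(
    track: CoverageTrack,
    genome: dict[str, str],
    read_len: int = 30,
    adapter: str = ADAPTER_3P,
    n_reads: int = 1000,
    seed: int = 0,
) -> tuple[list[str], list[AlignedRead]]:
    """Sample raw read sequences with start positions ∝ occupancy.

    Each read's 5' end is drawn from the track (multinomial over bases);
    its sequence is the genome substring (reverse-complemented on '−')
    with the 3' adapter appended.  The true alignments are returned
    alongside for oracle tests.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if read_len >= min(track.chrom_lengths.values()):
        raise ValueError("read_len must be shorter than every chromosome")
    keys = [
        (chrom, strand)
        for chrom in track.chromosomes()
        for strand in ("+", "-")
    ]
    weights = []
    for chrom, strand in keys:
        values = track.values(chrom, strand).copy()
        if strand == "+":
            values[len(values) - read_len + 1:] = 0.0  # read must fit
        else:
            values[:read_len - 1] = 0.0
        weights.append(values)
    flat = np.concatenate(weights)
    total = flat.sum()
    if total <= 0:
        raise ValueError("track has no usable signal to sample reads from")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, flat / total)

    reads: list[str] = []
    alignments: list[AlignedRead] = []
    offset = 0
    for (chrom, strand), values in zip(keys, weights):
        segment = counts[offset:offset + len(values)]
        offset += len(values)
        for pos in np.flatnonzero(segment):
            if strand == "+":
                start, end = int(pos), int(pos) + read_len
                insert = genome[chrom][start:end]
            else:
                start, end = int(pos) - read_len + 1, int(pos) + 1
                insert = str(Seq(genome[chrom][start:end]).reverse_complement())
            for _ in range(int(segment[pos])):
                reads.append(insert + adapter)
                alignments.append(AlignedRead(chrom, start, end, strand))
    return reads, alignments


# ---------------------------------------------------------------------------
# Standard layouts


def standard_loci(
    n_chrom: int = 12,
    chrom_len: int = 100_000,
    n_nonpa: int = 20,
    n_mrna: int = 10,
    body_rate: float = 5.0,
    spacing: int | None = None,
    start_offset: int | None = None,
    nonpa_len: int = 500,
    mrna_len: int = 1200,
) -> tuple[list[LocusSpec], dict[str, int]]:
    """Deterministic standard locus layout for simulated studies.

    Loci occupy evenly spaced slots with alternating strands, non-pA
    terminators (alternating snoRNA/CUT) first, then mRNAs.  By default
    the slot spacing is fitted to the requested locus count; spacing
    always guarantees >= 2 kb same-strand separation and >= 1 kb
    chromosome-end flanks for the default readthrough extents.
    """
    needed = n_nonpa + n_mrna
    chrom_lengths = {f"chr{i + 1:02d}": chrom_len for i in range(n_chrom)}
    margin = mrna_len + 4000
    if start_offset is None:
        start_offset = max(5000, chrom_len // 12)
    if spacing is None:
        available = chrom_len - start_offset - margin
        per_chrom = -(-needed // n_chrom)  # ceil
        spacing = available // max(1, per_chrom - 1) if per_chrom > 1 else available
    min_spacing = (2000 + max(nonpa_len, mrna_len) + 1) // 2 + 1
    if spacing < min_spacing:
        raise ValueError(
            f"layout cannot hold {needed} loci with >= 2 kb same-strand "
            f"separation; increase n_chrom or chrom_len"
        )
    slots = [
        (chrom, start_offset + j * spacing)
        for chrom in sorted(chrom_lengths)
        for j in range((chrom_len - start_offset - margin) // spacing + 1)
    ]
    if len(slots) < needed:
        raise ValueError(
            f"layout holds {len(slots)} loci but {needed} were requested; "
            "increase n_chrom or chrom_len"
        )
    loci: list[LocusSpec] = []
    for k in range(needed):
        chrom, pos = slots[k]
        strand = "+" if k % 2 == 0 else "-"
        if k < n_nonpa:
            locus_class = "snoRNA" if (k // 2) % 2 == 0 else "CUT"
            gene_len = nonpa_len
        else:
            locus_class = "mRNA"
            gene_len = mrna_len
        if strand == "+":
            tss, term = pos, pos + gene_len
        else:
            tss, term = pos + gene_len, pos
        loci.append(
            LocusSpec(
                id=f"{locus_class}_{k:03d}", chrom=chrom, strand=strand,
                tss=tss, term_point=term, locus_class=locus_class,
                body_rate=body_rate,
            )
        )
    validate_loci(loci, chrom_lengths)
    return loci, chrom_lengths


def compact_loci(n_nonpa: int = 20, n_mrna: int = 5) -> tuple[list[LocusSpec], dict[str, int]]:
    """Scaled-down layout (5 × 60 kb) for multi-seed replicate studies."""
    return standard_loci(
        n_chrom=5, chrom_len=60_000, n_nonpa=n_nonpa, n_mrna=n_mrna,
        spacing=10_000, start_offset=8_000,
    )
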