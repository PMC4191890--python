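# Methods

## Overview

`termscan` maps the positions where RNA polymerase II is released from the
template ("termination points") by comparing strand-specific Pol II
occupancy between a control condition and a condition in which a
termination factor has been depleted from the nucleus. Depleting a factor
of the non-polyadenylation (NNS) pathway — the RNA-binding sensor Nrd1 or
the helicase Sen1 — converts termination into readthrough transcription
downstream of snoRNAs and cryptic unstable transcripts (CUTs); depleting
the cleavage endonuclease Ysh1 of the polyadenylation (pA) pathway causes
Pol II to accumulate just downstream of pA sites without extended
readthrough. The occupancy signature of each event is therefore a *loss*
of signal upstream of the termination point (the pre-termination pause
disappears) and a *gain* downstream.

## Readthrough Index

For a position *p* on one strand, occupancy is summed in two flanking
windows of *w* = 500 nt: upstream `U = Σ values[p−w, p)` and downstream
`D = Σ values[p, p+w)` (windows swap roles on the minus strand, where
transcription runs toward decreasing coordinates). The readthrough
fraction is

    f = D / (U + D),

and the Readthrough Index at *p* is

    RI(p) = f_depleted(p) − f_control(p).

The downstream window includes the focal position and the upstream window
excludes it, so the two windows exactly partition a 2*w* span; this
convention is arbitrary at the 1-nt level and is recorded here for
reproducibility. The genome-wide scan evaluates RI at every position on
both strands and keeps positions passing all of:

* `RI > 0.10`;
* summed occupancy over the 2*w* span of at least 1000 in either sample
  (applied to the depth-normalized track values by default; a raw-count
  mode divides by each library's normalization factor first);
* more total signal over the span in the depleted than the control sample.

Passing positions form plateaus around each terminator; a greedy pass in
order of decreasing RI keeps the strongest position per region, requiring
≥ 1000 nt separation between kept candidates on one strand (the combined
window span; configurable).

## Termination-point refinement

Around each candidate the per-base difference `control − depleted` is
extracted over ±1000 nt, oriented 5'→3' in transcription direction. The
profile is positive upstream (pause lost on depletion) and negative
downstream (readthrough gained), so the termination point is the
downward zero crossing. The estimator:

1. pre-smooths the profile with a centered 25-nt moving average;
2. fits a cubic smoothing spline, with the penalty chosen by generalized
   cross-validation (GCV); the spline is fitted to the smoothed profile
   sampled every 5 nt — the moving average has already removed structure
   below its window scale, and the subsampling keeps the GCV fit ~25×
   cheaper without moving crossings — and is evaluated at every base;
3. enumerates positive→negative crossings of the spline and scores each
   by its *crossing amplitude*: the mean smoothed difference over 100 nt
   upstream minus 100 nt downstream;
4. returns the crossing with the largest positive amplitude, rounded to
   the nearest base with ties toward the upstream side. Candidates with
   no qualifying crossing are dropped and logged, never force-assigned.

Refined sites closer than 1000 nt on one strand are deduplicated keeping
the larger amplitude. The reported point is the center of a ~50-nt
release region, not a base-precise event; the `region_halfwidth` field
(25 nt) records that width.

Because the control occupancy decays exponentially past the termination
point (time constant τ) while the depleted occupancy sustains a fraction
α of the gene-body rate, the expected crossing sits `τ·ln(1/α)`
downstream of the release point — ~14 nt at the default τ = 20 nt,
α = 0.5. Recovery tolerances (±25 nt) include this offset.

## pA-site anchor selection

From a table of (chrom, pos, strand, raw_reads) pA sites the selector:
(1) drops sites with < 200 raw reads; (2) single-linkage clusters
surviving same-strand sites at ≤ 200 nt; (3) in a multi-site cluster
compares the two strongest sites — if second/first < 0.4 the dominant
site is kept and the rest dropped, otherwise the locus has no unambiguous
major 3' end and the whole cluster is discarded (`ambiguous_action=
"keep_top"` implements the opposite reading); (4) ranks survivors by read
count and returns the top 500. Note the selection is *not* monotone in
the read cutoff: raising it can delete a competitor and turn a previously
ambiguous cluster into a kept singleton. This is a property of the
dominance rule itself, not of the implementation.

## Metagenes and rankings

Anchor-centered matrices average occupancy in 10-bp bins over ±1000 nt
windows oriented with transcription (minus-strand windows reversed before
binning); a trailing partial bin averages over its actual base count.
Profiles are unweighted means across anchors. Percent readthrough per
terminator is `100 × (f_depleted − f_control)` computed with the same
window machinery at the refined point; rankings are sorted descending and
plotted against rank fraction k/N.

## Terminator sequence analysis

The 150-nt RNA-sense window 5' of each termination point is extracted
(reverse-complemented on the minus strand, T→U). Degenerate motifs
(Nrd1: GUA[AG]; Nab3: UCUU, UCUUG) are counted with overlaps allowed —
the motifs are short and may tile. Maximal U-runs of ≥ 3 nt are tallied,
by default within ±50 nt of the termination point, mirroring the ~50-nt
release region. Enrichment is tested against per-sequence
dinucleotide-preserving shuffles (Altschul–Erickson Eulerian-walk
shuffle, exact dinucleotide counts preserved), which controls for the
AT-richness of yeast intergenic sequence; the empirical p-value is
`(1 + #{shuffle totals ≥ observed}) / (1 + n_shuffles)` with 1000
shuffles by default.

## Synthetic data generator

The generator plants ground truth with the occupancy structure the
analysis assumes. Per-base counts are independent Poisson draws from a
rate function (no autocorrelated noise — the simplest model for count
data; an autocorrelation knob is future work):

* background 0.05 events/base everywhere;
* a gene-body plateau at `body_rate` (default 5) on [TSS, termination
  point];
* in control, a Gaussian pre-termination pause bump of amplitude
  2 × body_rate, σ = 15 nt, centered 30 nt *upstream* of the termination
  point — polymerase pauses before it terminates, and the upstream offset
  keeps the planted difference-profile crossing within the stated
  recovery tolerance — plus an exponential tail `exp(−d/τ)`, τ = 20 nt,
  past the point;
* under depletion, target-class loci change according to the factor:
  * **Nrd1-like** (targets snoRNA/CUT/antisense CUT): pause eliminated;
    plateau sustained at α = 0.5 of body rate for 1500 nt (processive,
    ≥ 1 kb) before decaying;
  * **Sen1-like** (same targets): identical shape but 250 nt extent
    (an increase just downstream by a few hundred nucleotides);
  * **Ysh1-like** (targets mRNA pA sites): the pause bump remains in both
    conditions and the depleted condition adds an enlarged pileup bump
    (gain 3×, σ = 40 nt) centered 80 nt downstream of the pA site, so the
    gained occupancy is confined within ~200 nt with no extension.

Genomes are 30% GC intergenic and 40% GC genic, with three GUA[A/G] and
three UCUUG motifs planted in the 150 nt upstream of every non-pA
terminator and two 5-nt U-runs within ±50 nt of it, on the transcribed
strand at non-overlapping random positions. pA tables give every mRNA
locus a major site at its pA point (Poisson mean 1000 reads), with
optional clustered minor sites and weakly supported decoys. Raw reads are
sampled with 5'-end positions proportional to occupancy and carry the 3'
adapter, with true alignments returned for oracle tests.

The standard study layout is 12 chromosomes × 100 kb holding 20 non-pA
terminators (alternating snoRNA/CUT, alternating strands) and 10 mRNA
loci, with ≥ 2 kb same-strand separation and ≥ 1 kb end flanks.
Multi-seed calibration studies use a scaled 5 × 60 kb layout with the
same 20 terminators and identical model parameters, sized so dozens of
replicate simulations run in seconds. Simulated depths are chosen so the
1000-read scan filter is meaningful at the default window (plateau
windows sum to ~2500), not to match any real library.

What the generator does *not* emulate: crosslinking chemistry and its
T→C conversions, RNA turnover and exosome dynamics, replicate library
structure, autocorrelated coverage noise, or overlapping/nested
transcription units. Passing tests therefore demonstrate correctness of
the statistics and estimators under the assumed occupancy model, not
robustness to every artifact of real libraries.

## Numerical and interface choices

* Coordinates are 0-based half-open internally; bedGraph I/O shares that
  convention, fixed-step wiggle converts to/from 1-based at the file
  boundary. Format readers report the offending line number for unknown
  chromosomes, negative values, malformed or overlapping intervals.
* Track normalization multiplies each read's contribution by
  `10^7 / total_aligned`; the library size is the aligned, condensed
  count before exclusion-interval (tRNA) removal, switchable.
* Adapter trimming removes the longest read suffix matching an adapter
  prefix with ≥ 5 nt overlap and ≤ 10% mismatches.
* Exclusion filtering removes reads overlapping an excluded interval by
  ≥ 1 bp on the same strand (strand-agnostic mode by flag). Full-read
  coverage is the default track mode; a 5'-end-only mode is provided.
* Readthrough fractions are undefined (not zero) on empty spans; such
  positions are excluded rather than imputed.
* The pipeline fans one global seed out to fixed per-stage offsets, so
  stages are individually reproducible and reruns are byte-identical
  (outputs carry no timestamps).

## Known limitations

* The crossing estimator carries the `τ·ln(1/α)` downstream offset
  discussed above; on real data the analogous bias depends on the local
  decay shape and is not corrected.
* Per-bin significance checks at 3× Monte-Carlo standard error are
  applied without multiplicity correction inside the expected signal
  ranges (where effect sizes are ~40 SE); extent measurements combine
  significance with a materiality floor (0.3 events/base, ~12% of the
  planted readthrough amplitude) because over hundreds of bins pure
  3-SE exceedances occur by chance.
* The pA dominance rule discards genuinely bimodal 3' ends by design;
  loci with two comparably used pA sites never anchor metagenes.
* Candidate selection is greedy, not globally optimal, matching the
  stated non-overlap procedure.
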