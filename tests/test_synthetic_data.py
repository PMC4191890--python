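"""Synthetic genome/occupancy/pA/read generators and their guarantees."""

from __future__ import annotations

import numpy as np
import pytest

from termscan import window_sums
from termscan import synthetic_data as sd
from termscan.coverage_io import ADAPTER_3P


class TestLocusValidation:
    def test_tss_must_precede_term_point(self):
        with pytest.raises(ValueError, match="tss"):
            sd.LocusSpec("x", "chr01", "+", 500, 400, "snoRNA", 1.0)

    def test_overlapping_same_strand_loci_named(self):
        loci = [
            sd.LocusSpec("left", "chr01", "+", 2000, 2500, "snoRNA", 1.0),
            sd.LocusSpec("right", "chr01", "+", 3000, 3500, "snoRNA", 1.0),
        ]
        with pytest.raises(ValueError, match="left.*right"):
            sd.validate_loci(loci, {"chr01": 50_000})

    def test_flank_requirement(self):
        locus = sd.LocusSpec("edge", "chr01", "+", 100, 600, "snoRNA", 1.0)
        with pytest.raises(ValueError, match="edge"):
            sd.validate_loci([locus], {"chr01": 50_000})


class TestSimulateGenome:
    def test_gc_composition_within_binomial_bound(self):
        spec = sd.SequenceSpec(gc_intergenic=0.30, motif_inserts=(), u_run_inserts=())
        genome, _ = sd.simulate_genome(spec, [], {"chr01": 100_000}, seed=0)
        seq = genome["chr01"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.30) < 0.01

    def test_motif_insertion_constructive(self):
        loci, chrom_lengths = sd.compact_loci(n_nonpa=4, n_mrna=0)
        spec = sd.SequenceSpec(motif_inserts=(("UCUUG", 3, (-150, 0)),), u_run_inserts=())
        genome, _ = sd.simulate_genome(spec, loci, chrom_lengths, seed=1)
        for locus in loci:
            seq = genome[locus.chrom]
            if locus.strand == "+":
                window = seq[locus.term_point - 150:locus.term_point]
            else:
                from Bio.Seq import Seq

                window = str(
                    Seq(seq[locus.term_point + 1:locus.term_point + 151]).reverse_complement()
                )
            rna = window.replace("T", "U")
            assert rna.count("UCUUG") >= 3, locus.id

    def test_deterministic_under_seed(self):
        loci, chrom_lengths = sd.compact_loci(n_nonpa=2, n_mrna=1)
        spec = sd.SequenceSpec()
        first, ann_first = sd.simulate_genome(spec, loci, chrom_lengths, seed=9)
        second, ann_second = sd.simulate_genome(spec, loci, chrom_lengths, seed=9)
        assert first == second
        assert ann_first == ann_second

    def test_annotations_cover_loci(self):
        loci, chrom_lengths = sd.compact_loci(n_nonpa=2, n_mrna=2)
        _, annotations = sd.simulate_genome(sd.SequenceSpec(), loci, chrom_lengths, seed=2)
        by_name = {a.name: a for a in annotations}
        for locus in loci:
            annotation = by_name[locus.id]
            assert annotation.start == locus.gene_start
            assert annotation.end == locus.gene_end + 1
            assert annotation.strand == locus.strand


class TestSimulateOccupancy:
    def test_zero_rates_give_zero_track(self):
        model = sd.OccupancyModel(background_rate=0.0)
        track = sd.simulate_occupancy([], model, "control", "Nrd1", {"chr01": 5000}, seed=0)
        assert track.total() == 0.0

    def test_plateau_mean_matches_body_rate(self):
        loci = [sd.LocusSpec("g", "chr01", "+", 2000, 4000, "snoRNA", 5.0)]
        model = sd.OccupancyModel(background_rate=0.0)
        track = sd.simulate_occupancy(loci, model, "control", "Nrd1", {"chr01": 10_000}, seed=3)
        plateau = track.values("chr01", "+")[2000:3000]
        assert abs(plateau.mean() - 5.0) < 3 * np.sqrt(5.0 / 1000)

    def test_unknown_condition_and_factor_rejected(self):
        with pytest.raises(ValueError, match="condition"):
            sd.simulate_occupancy([], sd.OccupancyModel(), "bogus", "Nrd1", {"c": 100}, seed=0)
        with pytest.raises(ValueError, match="factor_class"):
            sd.simulate_occupancy([], sd.OccupancyModel(), "control", "Xrn1", {"c": 100}, seed=0)

    def test_depletion_only_affects_target_classes(self):
        loci = [
            sd.LocusSpec("ncrna", "chr01", "+", 2000, 2500, "snoRNA", 5.0),
            sd.LocusSpec("coding", "chr01", "+", 6000, 7200, "mRNA", 5.0),
        ]
        model = sd.OccupancyModel.for_factor("Nrd1")
        control = sd.expected_rate_track(loci, model, "control", "Nrd1", {"chr01": 12_000})
        depleted = sd.expected_rate_track(loci, model, "depleted", "Nrd1", {"chr01": 12_000})
        c, d = control.values("chr01", "+"), depleted.values("chr01", "+")
        assert np.any(d[2500:4000] > c[2500:4000])  # snoRNA gains readthrough
        np.testing.assert_allclose(d[5000:12_000], c[5000:12_000])  # mRNA untouched

    def test_conservation_of_total_counts(self):
        """Summed counts match the rate integral within 3 SE over 30 seeds."""
        loci = [sd.LocusSpec("g", "chr01", "+", 2000, 3000, "CUT", 4.0)]
        model = sd.OccupancyModel.for_factor("Nrd1")
        rates = sd.expected_rate_track(loci, model, "depleted", "Nrd1", {"chr01": 8000})
        expected = rates.values("chr01", "+").sum()
        totals = [
            sd.simulate_occupancy(
                loci, model, "depleted", "Nrd1", {"chr01": 8000}, seed=s
            ).values("chr01", "+").sum()
            for s in range(30)
        ]
        se = np.sqrt(expected / 30)  # Poisson variance of the mean total
        assert abs(np.mean(totals) - expected) < 3 * se

    def test_deterministic_under_seed(self):
        loci, chrom_lengths = sd.compact_loci(n_nonpa=2, n_mrna=0)
        model = sd.OccupancyModel.for_factor("Sen1")
        a = sd.simulate_occupancy(loci, model, "depleted", "Sen1", chrom_lengths, seed=8)
        b = sd.simulate_occupancy(loci, model, "depleted", "Sen1", chrom_lengths, seed=8)
        assert a.allclose(b)


class TestAnalyticReadthrough:
    def test_simulated_fraction_matches_rate_integral(self):
        """Monte-Carlo readthrough fraction ≈ ratio of rate integrals."""
        loci = [sd.LocusSpec("g", "chr01", "+", 2000, 3000, "snoRNA", 5.0)]
        model = sd.OccupancyModel.for_factor("Nrd1")
        lengths = {"chr01": 8000}
        rates = sd.expected_rate_track(loci, model, "depleted", "Nrd1", lengths)
        up, down = window_sums(rates, "chr01", 3000, "+", 500)
        analytic = down / (up + down)
        fractions = []
        for seed in range(50):
            track = sd.simulate_occupancy(loci, model, "depleted", "Nrd1", lengths, seed=seed)
            u, d = window_sums(track, "chr01", 3000, "+", 500)
            fractions.append(d / (u + d))
        assert abs(np.mean(fractions) - analytic) < 0.02


class TestSimulatePaTable:
    def test_one_row_per_mrna_locus(self):
        loci, chrom_lengths = sd.compact_loci(n_nonpa=2, n_mrna=3)
        table = sd.simulate_pa_table(loci, seed=0)
        assert len(table) == 3
        assert set(table.columns) == {"chrom", "pos", "strand", "raw_reads"}
        assert (table.raw_reads >= 0).all()

    def test_minor_competitor_pair_present(self):
        loci, _ = sd.compact_loci(n_nonpa=0, n_mrna=2)
        table = sd.simulate_pa_table(loci, seed=0, minor_frac=0.3, minor_offset=50)
        assert len(table) == 4
        major = table.iloc[0]
        minor = table.iloc[1]
        assert abs(int(minor.pos) - int(major.pos)) == 50
        assert minor.raw_reads == int(round(major.raw_reads * 0.3))

    def test_reproducible(self):
        loci, chrom_lengths = sd.compact_loci(n_nonpa=2, n_mrna=3)
        a = sd.simulate_pa_table(loci, seed=4, noise_sites=10, chrom_lengths=chrom_lengths)
        b = sd.simulate_pa_table(loci, seed=4, noise_sites=10, chrom_lengths=chrom_lengths)
        assert a.equals(b)


@pytest.fixture(scope="module")
def point_source():
    from termscan import CoverageTrack

    genome = {"chr01": "ACGT" * 500}
    track = CoverageTrack({"chr01": 2000})
    values = np.zeros(2000)
    values[700] = 10.0
    track.set_values("chr01", "+", values)
    return genome, track


class TestSimulateReads:

    def test_point_source_reads_start_there(self, point_source):
        genome, track = point_source
        reads, alignments = sd.simulate_reads(track, genome, read_len=30, n_reads=50, seed=0)
        assert len(reads) == 50
        assert all(a.start == 700 and a.strand == "+" for a in alignments)
        assert all(r == genome["chr01"][700:730] + ADAPTER_3P for r in reads)

    def test_reads_end_with_adapter_prefix(self, point_source):
        genome, track = point_source
        reads, _ = sd.simulate_reads(track, genome, read_len=25, n_reads=20, seed=1)
        assert all(r.endswith(ADAPTER_3P) for r in reads)

    def test_invalid_n_reads(self, point_source):
        genome, track = point_source
        with pytest.raises(ValueError, match="n_reads"):
            sd.simulate_reads(track, genome, n_reads=0)

    def test_start_distribution_close_to_occupancy(self):
        """Empirical 5'-end distribution vs occupancy: TV distance < 0.05."""
        from termscan import CoverageTrack

        rng = np.random.default_rng(12)
        genome = {"chr01": "".join(rng.choice(list("ACGT"), size=3000))}
        track = CoverageTrack({"chr01": 3000})
        # ~500 occupied positions: E[TV] ~ 0.4*sqrt(k/n) stays below 0.05
        weights = np.zeros(3000)
        occupied = rng.choice(2900, size=500, replace=False)
        weights[occupied] = rng.gamma(2.0, 1.0, 500)
        weights[-29:] = 0.0  # read of length 30 must fit
        track.set_values("chr01", "+", weights)
        n_reads = 100_000
        _, alignments = sd.simulate_reads(track, genome, read_len=30, n_reads=n_reads, seed=13)
        counts = np.zeros(3000)
        for a in alignments:
            counts[a.start] += 1
        p = weights / weights.sum()
        q = counts / n_reads
        tv = 0.5 * np.abs(p - q).sum()
        assert tv < 0.05

    def test_minus_strand_reads_reverse_complemented(self):
        from Bio.Seq import Seq

        from termscan import CoverageTrack

        genome = {"chr01": "AACCGGTTAACCGGTTAACCGGTT"}
        track = CoverageTrack({"chr01": 24})
        values = np.zeros(24)
        values[20] = 5.0
        track.set_values("chr01", "-", values)
        reads, alignments = sd.simulate_reads(track, genome, read_len=10, n_reads=5, seed=2)
        expected = str(Seq(genome["chr01"][11:21]).reverse_complement()) + ADAPTER_3P
        assert all(r == expected for r in reads)
        assert all(a.start == 11 and a.end == 21 and a.strand == "-" for a in alignments)
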