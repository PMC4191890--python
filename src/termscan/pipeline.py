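"""End-to-end pipeline orchestration with config files and run manifests.

``run_pipeline`` chains scan → refine → metagene → motifs (plus pA anchor
selection when a pA table is supplied) over on-disk inputs, writing every
stage's table, a machine-readable manifest, and per-filter tallies to the
log.  ``simulate_dataset`` emits a complete ready-to-analyze synthetic
dataset with truth tables for any factor-class preset.

A single global seed fans out to per-stage seeds by fixed offsets so each
stage is individually reproducible; outputs carry no timestamps, making
reruns byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import synthetic_data
from .coverage_io import read_track, write_track
from .metagene import anchor_matrix, mean_profile, percent_readthrough_ranking
from .pa_selector import PASelectorParams, read_pa_table, select_top_pa, write_pa_anchors_bed
from .readthrough_scan import ScanThresholds, global_scan, select_candidates
from .terminator_sequence import extract_upstream, motif_enrichment, scan_motif, u_run_stats
from .termination_point import refine_all

logger = logging.getLogger(__name__)

# fixed per-stage seed offsets fanned out from the global seed
_STAGE_SEED_OFFSETS = {"genome": 11, "control": 23, "depleted": 37, "pa": 53, "motifs": 71}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage is named in the message."""


@dataclass
class InputPaths:
    control_plus: str
    control_minus: str
    treated_plus: str
    treated_minus: str
    genome: str
    pa_table: str | None = None
    annotation: str | None = None
    track_format: str = "bedgraph"


@dataclass
class RefineParams:
    halfwidth: int = 1000
    smooth_window: int = 25
    flank: int = 100
    min_separation: int = 1000


@dataclass
class MetageneParams:
    flank: int = 1000
    bin_size: int = 10


@dataclass
class MotifParams:
    upstream: int = 150
    patterns: tuple[str, ...] = ("GUA[AG]", "UCUU", "UCUUG")
    n_shuffles: int = 1000
    u_run_min_len: int = 3
    u_run_halfwidth: int = 50


@dataclass
class RunConfig:
    """Full pipeline configuration; every threshold lives here."""

    inputs: InputPaths
    outdir: str
    scan: ScanThresholds = field(default_factory=ScanThresholds)
    refine: RefineParams = field(default_factory=RefineParams)
    pa: PASelectorParams = field(default_factory=PASelectorParams)
    metagene: MetageneParams = field(default_factory=MetageneParams)
    motifs: MotifParams = field(default_factory=MotifParams)
    seed: int = 0
    plots: bool = False

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(dataclasses.asdict(self), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        return cls(
            inputs=InputPaths(**raw["inputs"]),
            outdir=raw["outdir"],
            scan=ScanThresholds(**raw.get("scan", {})),
            refine=RefineParams(**raw.get("refine", {})),
            pa=PASelectorParams(**raw.get("pa", {})),
            metagene=MetageneParams(
                **{k: v for k, v in raw.get("metagene", {}).items()}
            ),
            motifs=MotifParams(
                **{
                    k: tuple(v) if k == "patterns" else v
                    for k, v in raw.get("motifs", {}).items()
                }
            ),
            seed=raw.get("seed", 0),
            plots=raw.get("plots", False),
        )


def _require(path: str | None, label: str) -> str:
    if path is None:
        raise PipelineError(f"input '{label}' is required but not configured")
    if not os.path.exists(path):
        raise PipelineError(f"input '{label}' is missing: {path}")
    return path


def read_genome_fasta(path: str) -> dict[str, str]:
    return {record.id: str(record.seq).upper() for record in SeqIO.parse(path, "fasta")}


def _write_tsv(frame: pd.DataFrame, path: str) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute scan → refine → metagene → motifs and write all outputs.

    Returns the manifest (also written as ``manifest.json``): parameters,
    per-stage row counts, and output paths.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    os.makedirs(config.outdir, exist_ok=True)
    out = lambda name: os.path.join(config.outdir, name)
    manifest: dict = {
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }

    # --- load inputs
    stage = "load"
    try:
        genome = read_genome_fasta(_require(config.inputs.genome, "genome"))
        chrom_lengths = {chrom: len(seq) for chrom, seq in genome.items()}
        control = read_track(
            _require(config.inputs.control_plus, "control_plus"),
            _require(config.inputs.control_minus, "control_minus"),
            chrom_lengths, fmt=config.inputs.track_format,
        )
        treated = read_track(
            _require(config.inputs.treated_plus, "treated_plus"),
            _require(config.inputs.treated_minus, "treated_minus"),
            chrom_lengths, fmt=config.inputs.track_format,
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage is named for the caller
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    # --- genome-wide scan
    stage = "scan"
    try:
        points = global_scan(control, treated, config.scan)
        candidates = select_candidates(points, config.scan.min_separation)
        logger.info(
            "scan: %d positions passed filters, %d non-overlapping candidates",
            len(points), len(candidates),
        )
        frame = pd.DataFrame(
            [
                (p.chrom, p.pos, p.strand, p.up_control, p.down_control,
                 p.up_treated, p.down_treated, p.frac_control, p.frac_treated,
                 p.index)
                for p in candidates
            ],
            columns=["chrom", "pos", "strand", "up_control", "down_control",
                     "up_treated", "down_treated", "frac_control",
                     "frac_treated", "index"],
        )
        _write_tsv(frame, out("candidates.tsv"))
        with open(out("candidates.bed"), "w") as handle:
            for i, p in enumerate(candidates):
                score = max(0, min(1000, int(round(1000 * p.index))))
                handle.write(
                    f"{p.chrom}\t{p.pos}\t{p.pos + 1}\tcand_{i}\t{score}\t{p.strand}\n"
                )
        manifest["stages"]["scan"] = {
            "passing_points": len(points), "candidates": len(candidates),
        }
        manifest["outputs"]["candidates"] = out("candidates.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    # --- spline refinement
    stage = "refine"
    try:
        sites, dropped = refine_all(
            candidates, control, treated,
            halfwidth=config.refine.halfwidth,
            smooth_window=config.refine.smooth_window,
            flank=config.refine.flank,
            min_separation=config.refine.min_separation,
        )
        logger.info("refine: %d sites, %d candidates dropped", len(sites), len(dropped))
        frame = pd.DataFrame(
            [
                (s.chrom, s.pos, s.strand, s.crossing_amplitude,
                 s.region_halfwidth, s.source_id)
                for s in sites
            ],
            columns=["chrom", "pos", "strand", "crossing_amplitude",
                     "region_halfwidth", "source_id"],
        )
        _write_tsv(frame, out("termination_sites.tsv"))
        with open(out("termination_sites.bed"), "w") as handle:
            max_amp = max((s.crossing_amplitude for s in sites), default=1.0)
            for s in sites:
                score = max(0, min(1000, int(round(1000 * s.crossing_amplitude / max_amp))))
                handle.write(
                    f"{s.chrom}\t{s.pos}\t{s.pos + 1}\t{s.source_id}\t{score}\t{s.strand}\n"
                )
        manifest["stages"]["refine"] = {
            "sites": len(sites), "dropped": len(dropped),
            "drop_reasons": sorted({reason for _, reason in dropped}),
        }
        manifest["outputs"]["termination_sites"] = out("termination_sites.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    # --- metagenes and readthrough ranking at refined sites
    stage = "metagene"
    try:
        if sites:
            profiles = {}
            for label, track in (("control", control), ("treated", treated)):
                matrix = anchor_matrix(
                    track, sites, flank=config.metagene.flank,
                    bin_size=config.metagene.bin_size,
                )
                profiles[label] = mean_profile(matrix)
            frame = pd.DataFrame(
                {
                    "bin_offset": matrix.bin_offsets(),
                    "control_mean": profiles["control"],
                    "treated_mean": profiles["treated"],
                }
            )
            _write_tsv(frame, out("metagene_terminators.tsv"))
            manifest["outputs"]["metagene_terminators"] = out("metagene_terminators.tsv")

            ranking = percent_readthrough_ranking(
                sites, control, treated, window=config.scan.window
            )
            frame = pd.DataFrame(
                {
                    "id": ranking.ids,
                    "percent_readthrough": ranking.values,
                    "rank_fraction": ranking.rank_fraction,
                }
            )
            _write_tsv(frame, out("readthrough_ranking.tsv"))
            manifest["outputs"]["readthrough_ranking"] = out("readthrough_ranking.tsv")
            if config.plots:
                from . import plots as _plots

                _plots.plot_metagene(
                    matrix.bin_offsets(), profiles["control"], profiles["treated"],
                    out("metagene_terminators.svg"),
                )
                _plots.plot_ranking(ranking, out("readthrough_ranking.svg"))
                manifest["outputs"]["plots"] = [
                    out("metagene_terminators.svg"), out("readthrough_ranking.svg"),
                ]
            manifest["stages"]["metagene"] = {
                "anchors": len(sites), "ranked": len(ranking),
                "ranking_excluded": len(ranking.excluded),
            }
        else:
            manifest["stages"]["metagene"] = {"anchors": 0, "ranked": 0}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    # --- pA anchors (optional)
    stage = "pa_select"
    try:
        if config.inputs.pa_table is not None:
            records = read_pa_table(_require(config.inputs.pa_table, "pa_table"))
            anchors = select_top_pa(records, config.pa)
            write_pa_anchors_bed(anchors, out("pa_anchors.bed"))
            logger.info("pa_select: %d of %d sites kept", len(anchors), len(records))
            if anchors:
                pa_tuples = [
                    (a.chrom, a.pos, a.strand, f"pa_{i}")
                    for i, a in enumerate(anchors)
                ]
                pa_profiles = {}
                for label, track in (("control", control), ("treated", treated)):
                    matrix = anchor_matrix(
                        track, pa_tuples, flank=config.metagene.flank,
                        bin_size=config.metagene.bin_size,
                    )
                    pa_profiles[label] = mean_profile(matrix)
                frame = pd.DataFrame(
                    {
                        "bin_offset": matrix.bin_offsets(),
                        "control_mean": pa_profiles["control"],
                        "treated_mean": pa_profiles["treated"],
                    }
                )
                _write_tsv(frame, out("metagene_pa.tsv"))
                manifest["outputs"]["metagene_pa"] = out("metagene_pa.tsv")
            manifest["stages"]["pa_select"] = {
                "input_sites": len(records), "anchors": len(anchors),
            }
            manifest["outputs"]["pa_anchors"] = out("pa_anchors.bed")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    # --- terminator sequence analysis
    stage = "motifs"
    try:
        if sites:
            windows = [
                extract_upstream(genome, site, length=config.motifs.upstream)
                for site in sites
            ]
            with open(out("terminator_windows.fa"), "w") as handle:
                for window in windows:
                    handle.write(f">{window.site_id}\n{window.sequence}\n")
            per_site_rows = []
            for window in windows:
                row: dict = {"site": window.site_id}
                for pattern in config.motifs.patterns:
                    row[pattern] = scan_motif(window.sequence, pattern).count
                runs = u_run_stats(
                    window.sequence, min_len=config.motifs.u_run_min_len
                )
                row["u_runs"] = runs.count
                row["max_u_run"] = max(runs.lengths, default=0)
                per_site_rows.append(row)
            _write_tsv(pd.DataFrame(per_site_rows), out("motif_counts.tsv"))

            sequences = [w.sequence for w in windows if len(w.sequence) > 2]
            enrich_rows = []
            if len(sequences) >= 2:
                motif_seed = config.seed + _STAGE_SEED_OFFSETS["motifs"]
                for pattern in config.motifs.patterns:
                    result = motif_enrichment(
                        sequences, pattern,
                        n_shuffles=config.motifs.n_shuffles, seed=motif_seed,
                    )
                    enrich_rows.append(
                        {
                            "pattern": pattern,
                            "observed": result.observed,
                            "null_mean": result.null_mean,
                            "fold_enrichment": result.fold_enrichment,
                            "p_value": result.p_value,
                        }
                    )
            _write_tsv(pd.DataFrame(enrich_rows), out("motif_enrichment.tsv"))
            manifest["stages"]["motifs"] = {
                "windows": len(windows), "patterns": list(config.motifs.patterns),
            }
            manifest["outputs"]["motif_counts"] = out("motif_counts.tsv")
            manifest["outputs"]["motif_enrichment"] = out("motif_enrichment.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    with open(out("manifest.json"), "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# Synthetic dataset presets


@dataclass(frozen=True)
class Preset:
    factor_class: str
    description: str
    n_chrom: int = 12
    chrom_len: int = 100_000
    n_nonpa: int = 20
    n_mrna: int = 10


PRESETS: dict[str, Preset] = {
    "nrd1-demo": Preset(
        "Nrd1", "processive non-pA readthrough (>= 1 kb) on depletion"
    ),
    "sen1-demo": Preset(
        "Sen1", "short non-pA readthrough (a few hundred nt) on depletion"
    ),
    "ysh1-demo": Preset(
        "Ysh1", "pA-site pileup confined within 200 nt, no extension"
    ),
}


def simulate_dataset(
    preset_name: str,
    outdir: str,
    seed: int = 0,
    n_chrom: int | None = None,
    chrom_len: int | None = None,
) -> dict:
    """Emit a complete ready-to-analyze synthetic dataset plus truth tables.

    Writes genome FASTA, annotation BED6, per-strand control/treated
    bedGraph tracks, a pA table TSV, a locus truth TSV, and a ready-to-run
    pipeline config.  Returns a manifest of paths.
    """
    if preset_name not in PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; available: {sorted(PRESETS)}"
        )
    preset = PRESETS[preset_name]
    os.makedirs(outdir, exist_ok=True)
    out = lambda name: os.path.join(outdir, name)

    loci, chrom_lengths = synthetic_data.standard_loci(
        n_chrom=n_chrom or preset.n_chrom,
        chrom_len=chrom_len or preset.chrom_len,
        n_nonpa=preset.n_nonpa,
        n_mrna=preset.n_mrna,
    )
    model = synthetic_data.OccupancyModel.for_factor(preset.factor_class)
    genome, annotations = synthetic_data.simulate_genome(
        synthetic_data.SequenceSpec(), loci, chrom_lengths,
        seed=seed + _STAGE_SEED_OFFSETS["genome"],
    )
    control = synthetic_data.simulate_occupancy(
        loci, model, "control", preset.factor_class, chrom_lengths,
        seed=seed + _STAGE_SEED_OFFSETS["control"],
    )
    treated = synthetic_data.simulate_occupancy(
        loci, model, "depleted", preset.factor_class, chrom_lengths,
        seed=seed + _STAGE_SEED_OFFSETS["depleted"],
    )
    pa_table = synthetic_data.simulate_pa_table(
        loci, seed=seed + _STAGE_SEED_OFFSETS["pa"], noise_sites=20,
        chrom_lengths=chrom_lengths,
    )

    SeqIO.write(
        [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sorted(genome.items())],
        out("genome.fa"), "fasta",
    )
    with open(out("annotation.bed"), "w") as handle:
        for a in annotations:
            handle.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.name}\t{a.score}\t{a.strand}\n")
    control_paths = write_track(control, out("control"))
    treated_paths = write_track(treated, out("treated"))
    pa_table.to_csv(out("pa_table.tsv"), sep="\t", index=False, header=False)
    truth = pd.DataFrame(
        [
            (l.id, l.chrom, l.strand, l.tss, l.term_point, l.locus_class, l.body_rate)
            for l in loci
        ],
        columns=["id", "chrom", "strand", "tss", "term_point", "locus_class", "body_rate"],
    )
    truth.to_csv(out("truth.tsv"), sep="\t", index=False)

    config = RunConfig(
        inputs=InputPaths(
            control_plus=control_paths["+"], control_minus=control_paths["-"],
            treated_plus=treated_paths["+"], treated_minus=treated_paths["-"],
            genome=out("genome.fa"), pa_table=out("pa_table.tsv"),
            annotation=out("annotation.bed"),
        ),
        outdir=os.path.join(outdir, "results"),
        seed=seed,
    )
    config.to_yaml(out("run_config.yaml"))
    return {
        "preset": preset_name,
        "factor_class": preset.factor_class,
        "loci": len(loci),
        "genome": out("genome.fa"),
        "annotation": out("annotation.bed"),
        "control": control_paths,
        "treated": treated_paths,
        "pa_table": out("pa_table.tsv"),
        "truth": out("truth.tsv"),
        "config": out("run_config.yaml"),
    }
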