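"""Selection of polyadenylation-site anchors for metagene analysis.

From a table of mapped pA sites with raw read support, the strongest
unambiguous 3'-end per locus is chosen: weakly supported sites are cut,
nearby same-strand sites are clustered, clusters without a clearly
dominant site are discarded, and the survivors are ranked by read support.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True, order=True)
class PASiteRecord:
    """One mapped polyadenylation site with its raw read count."""

    chrom: str
    pos: int
    strand: str
    raw_reads: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.raw_reads < 0:
            raise ValueError(f"raw_reads must be non-negative, got {self.raw_reads}")


@dataclass(frozen=True)
class PASelectorParams:
    """Anchor-selection parameters.

    min_reads
        hard cutoff on raw read support per site.
    cluster_dist
        same-strand sites within this distance (nt) form one cluster.
    dominance_ratio
        within a multi-site cluster, ratio of the second-highest to the
        highest read count below which the top site is an unambiguous
        dominant 3' end.
    top_n
        number of ranked anchors returned.
    ambiguous_action
        what to do with a cluster whose ratio is >= dominance_ratio:
        ``"drop_cluster"`` discards it (no unambiguous major site);
        ``"keep_top"`` keeps the strongest site anyway.
    """

    min_reads: int = 200
    cluster_dist: int = 200
    dominance_ratio: float = 0.4
    top_n: int = 500
    ambiguous_action: str = "drop_cluster"

    def __post_init__(self) -> None:
        if self.min_reads <= 0 or self.cluster_dist <= 0 or self.top_n <= 0:
            raise ValueError("min_reads, cluster_dist and top_n must be positive")
        if not 0 < self.dominance_ratio < 1:
            raise ValueError("dominance_ratio must be in (0, 1)")
        if self.ambiguous_action not in ("drop_cluster", "keep_top"):
            raise ValueError(f"unknown ambiguous_action {self.ambiguous_action!r}")


def _clusters(
    records: Sequence[PASiteRecord], cluster_dist: int
) -> Iterable[list[PASiteRecord]]:
    """Single-linkage clusters of same-strand sites at ``cluster_dist``."""
    keyed = sorted(records, key=lambda r: (r.chrom, r.strand, r.pos))
    for _, group_iter in itertools.groupby(keyed, key=lambda r: (r.chrom, r.strand)):
        group = list(group_iter)
        cluster = [group[0]]
        for record in group[1:]:
            if record.pos - cluster[-1].pos <= cluster_dist:
                cluster.append(record)
            else:
                yield cluster
                cluster = [record]
        yield cluster


def select_top_pa(
    records: Iterable[PASiteRecord | tuple],
    params: PASelectorParams | None = None,
) -> list[PASiteRecord]:
    """Select the top pA-site anchors.

    Steps: (1) discard sites below ``min_reads``; (2) cluster surviving
    same-strand sites by single linkage at ``cluster_dist``; (3) in each
    multi-site cluster compare the two strongest sites — a second/first
    read ratio below ``dominance_ratio`` keeps only the dominant site,
    otherwise the whole cluster is ambiguous and discarded; (4) rank kept
    sites by read count descending (ties by chrom, pos, strand) and return
    the top ``top_n``.
    """
    params = params or PASelectorParams()
    normalized = [
        r if isinstance(r, PASiteRecord) else PASiteRecord(*r) for r in records
    ]
    survivors = [r for r in normalized if r.raw_reads >= params.min_reads]
    if not survivors:
        return []

    kept: list[PASiteRecord] = []
    for cluster in _clusters(survivors, params.cluster_dist):
        if len(cluster) == 1:
            kept.append(cluster[0])
            continue
        ranked = sorted(cluster, key=lambda r: (-r.raw_reads, r.chrom, r.pos, r.strand))
        top, second = ranked[0], ranked[1]
        ratio = second.raw_reads / top.raw_reads if top.raw_reads > 0 else 1.0
        if ratio < params.dominance_ratio or params.ambiguous_action == "keep_top":
            kept.append(top)
        # else: no unambiguous major site; drop the cluster

    kept.sort(key=lambda r: (-r.raw_reads, r.chrom, r.pos, r.strand))
    return kept[: params.top_n]


def read_pa_table(path: str) -> list[PASiteRecord]:
    """Read a 4-column TSV (chrom, pos, strand, raw_reads) of pA sites."""
    frame = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "pos", "strand", "raw_reads"],
        dtype={"chrom": str, "pos": int, "strand": str, "raw_reads": int},
    )
    return [
        PASiteRecord(row.chrom, int(row.pos), row.strand, int(row.raw_reads))
        for row in frame.itertuples(index=False)
    ]


def write_pa_anchors_bed(anchors: Sequence[PASiteRecord], path: str) -> None:
    """Write selected anchors as BED6 with score = raw read count."""
    with open(path, "w") as handle:
        for i, anchor in enumerate(anchors):
            handle.write(
                f"{anchor.chrom}\t{anchor.pos}\t{anchor.pos + 1}\t"
                f"pa_{i}\t{anchor.raw_reads}\t{anchor.strand}\n"
            )
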