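"""ChIP/input enrichment statistics.

Per repeat cluster: normalized enrichment as the ratio of library-size-
normalized ChIP and input hit proportions. Per genomic window: the log2
ratio of normalized ChIP over input counts in fixed-width windows (1 kb by
default), plus a simple run-based caller that turns the window track into
enriched segments (a stand-in estimate of centromere array extent).

A pseudocount (default 1 read) is added to every window/cluster count
before normalization so zero-input bins stay defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .io_formats import GenomicInterval

__all__ = [
    "ClusterEnrichment",
    "WindowTrack",
    "cluster_enrichment",
    "window_log2_track",
    "call_enriched_segments",
]


@dataclass(frozen=True)
class ClusterEnrichment:
    cluster_id: str
    chip_hits: int
    input_hits: int
    chip_total: int
    input_total: int
    enrichment: float
    genome_proportion: Optional[float] = None


@dataclass
class WindowTrack:
    """Per-window log2(ChIP/input) values tiling one chromosome."""

    chrom: str
    window_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def window_interval(self, idx: int) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, idx * self.window_size, (idx + 1) * self.window_size
        )


def cluster_enrichment(
    counts: Iterable[tuple],
    chip_total: int,
    input_total: int,
    pseudocount: float = 1.0,
) -> list[ClusterEnrichment]:
    """Normalized ChIP/input enrichment per repeat cluster.

    ``counts`` rows are (cluster_id, chip_hits, input_hits) or
    (cluster_id, chip_hits, input_hits, genome_proportion). Enrichment is
    ((chip+p)/chip_total) / ((input+p)/input_total); output is sorted by
    enrichment, descending.
    """
    if chip_total <= 0 or input_total <= 0:
        raise ValueError("library totals must be positive")
    out: list[ClusterEnrichment] = []
    for row in counts:
        cluster_id, chip_hits, input_hits = row[0], int(row[1]), int(row[2])
        gp = float(row[3]) if len(row) > 3 else None
        if chip_hits > chip_total or input_hits > input_total:
            raise ValueError(f"cluster {cluster_id}: hits exceed library total")
        enr = ((chip_hits + pseudocount) / chip_total) / (
            (input_hits + pseudocount) / input_total
        )
        out.append(
            ClusterEnrichment(
                cluster_id=str(cluster_id), chip_hits=chip_hits,
                input_hits=input_hits, chip_total=chip_total,
                input_total=input_total, enrichment=enr, genome_proportion=gp,
            )
        )
    out.sort(key=lambda c: (-c.enrichment, c.cluster_id))
    return out


def window_log2_track(
    chip_counts: Sequence[float],
    input_counts: Sequence[float],
    chip_total: float,
    input_total: float,
    pseudocount: float = 1.0,
    chrom: str = "chr",
    window_size: int = 1000,
) -> WindowTrack:
    """log2 of normalized ChIP over input read counts per window."""
    chip = np.asarray(chip_counts, dtype=float)
    inp = np.asarray(input_counts, dtype=float)
    if chip.shape != inp.shape:
        raise ValueError(
            f"window grids differ: {chip.shape} ChIP vs {inp.shape} input windows"
        )
    if chip_total <= 0 or input_total <= 0:
        raise ValueError("library totals must be positive")
    values = np.log2(
        ((chip + pseudocount) / chip_total) / ((inp + pseudocount) / input_total)
    )
    return WindowTrack(chrom=chrom, window_size=window_size, values=values)


def call_enriched_segments(
    track: WindowTrack,
    threshold: float,
    merge_gap: int = 1,
    min_len: int = 5,
) -> list[GenomicInterval]:
    """Maximal runs of windows with value >= threshold, as genomic intervals.

    Runs separated by at most ``merge_gap`` sub-threshold windows are
    merged; merged runs spanning fewer than ``min_len`` windows are dropped.
    """
    above = track.values >= threshold
    runs: list[list[int]] = []  # [first, last] window indices, inclusive
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append([start, i - 1])
            start = None
    if start is not None:
        runs.append([start, len(above) - 1])

    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    out = []
    for first, last in merged:
        if last - first + 1 >= min_len:
            out.append(
                GenomicInterval(
                    track.chrom,
                    first * track.window_size,
                    (last + 1) * track.window_size,
                    name="enriched",
                )
            )
    return out
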