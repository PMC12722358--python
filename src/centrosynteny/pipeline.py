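"""End-to-end orchestration and summary statistics.

``run_pipeline`` sequences the stages — noise filtering and single-copy
classification, link positioning, synteny chaining, rearrangement calling,
and (when centromere BED files are given) centromere-origin classification
— writing every stage's output and a JSON summary. ``genome_summary`` is
the per-chromosome size arithmetic used to compare genomes of similar
chromosome dimensions.
"""

from __future__ import annotations

import decimal
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

from . import io_formats, ortholog_links, synteny_centromere

logger = logging.getLogger("centrosynteny")

__all__ = ["PipelineConfig", "SummaryReport", "run_pipeline", "genome_summary"]


@dataclass
class PipelineConfig:
    gff_a: str
    gff_b: str
    hits_ab: str
    hits_ba: str
    outdir: str
    cen_a_bed: str | None = None
    cen_b_bed: str | None = None
    min_identity: float = 90.0
    min_align_len: int = 150
    mode: str = "reciprocal"
    max_gap_genes: int = 10
    min_block_links: int = 5
    min_event_links: int = 5
    min_overlap_frac: float = 0.1

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def validate(self) -> None:
        required = [self.gff_a, self.gff_b, self.hits_ab, self.hits_ba]
        optional = [self.cen_a_bed, self.cen_b_bed]
        for path in required + [p for p in optional if p]:
            if not os.path.exists(path):
                raise FileNotFoundError(f"input file not found: {path}")


@dataclass
class SummaryReport:
    n_links: int = 0
    n_blocks: int = 0
    n_block_links: int = 0
    n_unchained_links: int = 0
    n_inversions: int = 0
    n_translocations: int = 0
    origin_tallies: dict[str, int] = field(default_factory=dict)
    genome_stats: dict[str, dict] = field(default_factory=dict)
    config_digest: str = ""

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


def genome_summary(genome_size_mb: float, n_chromosomes: int) -> float:
    """Mean chromosome size in Mb (half-up to one decimal).

    E.g. an 887 Mb/1C genome over 12 chromosomes averages 73.9 Mb per
    chromosome; 789 Mb over 10 averages 78.9 Mb.
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    if genome_size_mb <= 0:
        raise ValueError("genome_size_mb must be positive")
    mean = decimal.Decimal(str(genome_size_mb)) / decimal.Decimal(n_chromosomes)
    return float(mean.quantize(decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP))


def _annot_stats(annot: io_formats.GenomeAnnotation) -> dict:
    chroms = annot.chromosomes()
    extent = {}
    for g in annot.genes:
        extent[g.chrom] = max(extent.get(g.chrom, 0), g.end)
    size_mb = sum(extent.values()) / 1e6
    return {
        "n_genes": len(annot.genes),
        "n_chromosomes": len(chroms),
        "genome_size_mb": round(size_mb, 3),
        "mean_chromosome_mb": genome_summary(size_mb, len(chroms)) if chroms else 0.0,
    }


def run_pipeline(config: PipelineConfig) -> SummaryReport:
    """Run all stages; outputs land in ``config.outdir``.

    Any stage failure aborts with the stage name in the exception message.
    Deterministic: the same config produces byte-identical outputs.
    """
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    report = SummaryReport(config_digest=config.digest())

    def stage(name, fn):
        logger.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    annot_a = stage("read_gff_a", lambda: io_formats.read_gff3_genes(config.gff_a, "A"))
    annot_b = stage("read_gff_b", lambda: io_formats.read_gff3_genes(config.gff_b, "B"))
    hits_ab = stage("read_hits_ab", lambda: io_formats.read_tabular_hits(config.hits_ab))
    hits_ba = stage("read_hits_ba", lambda: io_formats.read_tabular_hits(config.hits_ba))

    thresholds = ortholog_links.FilterThresholds(
        min_identity=config.min_identity, min_align_len=config.min_align_len
    )
    links = stage(
        "ortholog_links",
        lambda: ortholog_links.links_from_hits(
            hits_ab, hits_ba, annot_a, annot_b, thresholds, mode=config.mode
        ),
    )
    io_formats.write_links_tsv(links, os.path.join(config.outdir, "links.tsv"))

    blocks, leftovers = stage(
        "chain_blocks",
        lambda: synteny_centromere.chain_blocks(
            links, annot_a, annot_b,
            max_gap_genes=config.max_gap_genes,
            min_block_links=config.min_block_links,
        ),
    )
    inversions = stage(
        "call_inversions",
        lambda: synteny_centromere.call_inversions(
            blocks, config.min_event_links, leftover_links=leftovers
        ),
    )
    translocations = stage(
        "call_translocations",
        lambda: synteny_centromere.call_translocations(blocks, config.min_event_links),
    )

    with open(os.path.join(config.outdir, "blocks.tsv"), "w") as fh:
        fh.write("#block_id\tchrom_a\tchrom_b\torientation\tn_links\t"
                 "start_a\tend_a\tstart_b\tend_b\n")
        for b in blocks:
            fh.write(
                f"{b.block_id}\t{b.chrom_a}\t{b.chrom_b}\t{b.orientation:+d}\t"
                f"{len(b.links)}\t{b.span_a.start}\t{b.span_a.end}\t"
                f"{b.span_b.start}\t{b.span_b.end}\n"
            )
    with open(os.path.join(config.outdir, "events.tsv"), "w") as fh:
        fh.write("#kind\tchrom_a\tchrom_b\tn_links\tstart_a\tend_a\tcontext\n")
        for call in inversions + translocations:
            span_start = min(b.span_a.start for b in call.blocks)
            span_end = max(b.span_a.end for b in call.blocks)
            fh.write(
                f"{call.kind}\t{call.block.chrom_a}\t{call.block.chrom_b}\t"
                f"{sum(len(b.links) for b in call.blocks)}\t"
                f"{span_start}\t{span_end}\t{call.reference_context}\n"
            )

    origin_calls = []
    if config.cen_a_bed and config.cen_b_bed:
        units_a = stage("read_cen_a", lambda: io_formats.read_bed(config.cen_a_bed))
        units_b = stage("read_cen_b", lambda: io_formats.read_bed(config.cen_b_bed))
        origin_calls = stage(
            "classify_centromere_origin",
            lambda: synteny_centromere.classify_centromere_origin(
                units_b, units_a, links, blocks,
                min_overlap_frac=config.min_overlap_frac,
            ),
        )
        with open(os.path.join(config.outdir, "origin_calls.tsv"), "w") as fh:
            fh.write("#chrom\tstart\tend\tname\tklass\tprojected\n")
            for call in origin_calls:
                proj = (
                    f"{call.projected.chrom}:{call.projected.start}-{call.projected.end}"
                    if call.projected else "."
                )
                u = call.unit
                fh.write(f"{u.chrom}\t{u.start}\t{u.end}\t{u.name}\t{call.klass}\t{proj}\n")

    report.n_links = len(links)
    report.n_blocks = len(blocks)
    report.n_block_links = sum(len(b.links) for b in blocks)
    report.n_unchained_links = len(leftovers)
    report.n_inversions = len(inversions)
    report.n_translocations = len(translocations)
    tallies: dict[str, int] = {}
    for call in origin_calls:
        tallies[call.klass] = tallies.get(call.klass, 0) + 1
    report.origin_tallies = tallies
    report.genome_stats = {"A": _annot_stats(annot_a), "B": _annot_stats(annot_b)}
    report.to_json(os.path.join(config.outdir, "summary.json"))
    return report
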