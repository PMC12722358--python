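"""Conserved single-copy ortholog classification and link construction.

The procedure mirrors the classic reciprocal-uniqueness workflow: filter
noisy protein alignments, collapse multiple HSPs of a gene pair into one
relationship, keep genes whose similarity points to exactly one gene in the
other genome, and position the surviving pairs on both genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, NamedTuple

from .io_formats import AlignmentHit, GeneModel, GenomeAnnotation

__all__ = [
    "FilterThresholds",
    "OrthologLink",
    "OrthologPair",
    "filter_noise",
    "collapse_hits_per_gene_pair",
    "classify_single_copy",
    "build_links",
    "links_from_hits",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Noise filter: alignments below either bound are discarded.

    Defaults follow the convention of treating <90% identity or <150 aa
    aligned length as noise, so equality at the boundary is kept.
    """

    min_identity: float = 90.0
    min_align_len: int = 150

    def __post_init__(self) -> None:
        if self.min_identity < 0 or self.min_align_len < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class OrthologLink:
    """A reciprocal single-copy gene pair, positioned on both genomes."""

    gene_a: GeneModel
    gene_b: GeneModel
    identity: float
    bitscore: float
    orientation: int  # +1 if both genes on the same strand, else -1


class OrthologPair(NamedTuple):
    gene_a: str
    gene_b: str
    identity: float
    bitscore: float


def filter_noise(
    hits: Iterable[AlignmentHit], thresholds: FilterThresholds = FilterThresholds()
) -> list[AlignmentHit]:
    """Keep hits with pident >= min_identity and align_len >= min_align_len.

    Order-preserving and idempotent; the output is always a subset of the
    input.
    """
    return [
        h for h in hits
        if h.pident >= thresholds.min_identity
        and h.align_len >= thresholds.min_align_len
    ]


def _better(h1: AlignmentHit, h2: AlignmentHit) -> AlignmentHit:
    """Pick the representative HSP: highest bitscore, then highest pident,
    then lexicographically smaller subject id."""
    k1 = (-h1.bitscore, -h1.pident, h1.subject_id)
    k2 = (-h2.bitscore, -h2.pident, h2.subject_id)
    return h1 if k1 <= k2 else h2


def collapse_hits_per_gene_pair(
    hits: Iterable[AlignmentHit],
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    on_unknown: Literal["error", "drop"] = "error",
) -> list[AlignmentHit]:
    """Reduce HSPs to at most one hit per (gene A, gene B) pair.

    Multiple HSPs between the same two genes are one similarity
    relationship; the highest-scoring HSP represents it. Self-hits and
    within-genome hits are ignored. Hits naming proteins unknown to either
    annotation raise (strict) or are dropped with a count (lenient).
    """
    prot_a = annot_a.protein_to_gene()
    prot_b = annot_b.protein_to_gene()
    best: dict[tuple[str, str], AlignmentHit] = {}
    order: list[tuple[str, str]] = []
    for h in hits:
        ga = prot_a.get(h.query_id)
        gb = prot_b.get(h.subject_id)
        if ga is None or gb is None:
            # within-genome / wrong-direction hits are silently ignored
            if h.query_id in prot_b or h.subject_id in prot_a:
                continue
            if on_unknown == "error":
                which = h.query_id if ga is None else h.subject_id
                raise KeyError(f"hit names unknown protein {which!r}")
            continue
        key = (ga.gene_id, gb.gene_id)
        if key in best:
            best[key] = _better(best[key], h)
        else:
            best[key] = h
            order.append(key)
    return [best[k] for k in order]


def _gene_adjacency(
    hits: Iterable[AlignmentHit],
    annot_q: GenomeAnnotation,
    annot_s: GenomeAnnotation,
) -> dict[str, dict[str, AlignmentHit]]:
    prot_q = annot_q.protein_to_gene()
    prot_s = annot_s.protein_to_gene()
    adj: dict[str, dict[str, AlignmentHit]] = {}
    for h in hits:
        gq = prot_q.get(h.query_id)
        gs = prot_s.get(h.subject_id)
        if gq is None or gs is None:
            continue
        adj.setdefault(gq.gene_id, {})[gs.gene_id] = h
    return adj


def classify_single_copy(
    hits_ab: Iterable[AlignmentHit],
    hits_ba: Iterable[AlignmentHit],
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    mode: Literal["one_way", "reciprocal"] = "reciprocal",
) -> list[OrthologPair]:
    """Classify conserved single-copy gene pairs.

    A gene qualifies when its (filtered, collapsed) similarity points to a
    single gene in the other genome. ``one_way`` emits a pair for every
    qualifying genome-A gene; ``reciprocal`` (default) additionally requires
    the genome-B gene's only hit to point back, which guarantees no gene
    repeats on either side.
    """
    ab = _gene_adjacency(hits_ab, annot_a, annot_b)
    ba = _gene_adjacency(hits_ba, annot_b, annot_a)

    pairs: list[OrthologPair] = []
    if mode == "one_way":
        for ga in sorted(ab):
            if len(ab[ga]) == 1:
                (gb, h), = ab[ga].items()
                pairs.append(OrthologPair(ga, gb, h.pident, h.bitscore))
    elif mode == "reciprocal":
        for ga in sorted(ab):
            if len(ab[ga]) != 1:
                continue
            (gb, h), = ab[ga].items()
            back = ba.get(gb, {})
            if len(back) == 1 and ga in back:
                pairs.append(OrthologPair(ga, gb, h.pident, h.bitscore))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pairs


def build_links(
    pairs: Iterable[OrthologPair],
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
) -> list[OrthologLink]:
    """Attach genomic coordinates to classified pairs.

    Links are sorted by genome-A position; orientation is +1 when the two
    genes lie on the same strand, -1 otherwise.
    """
    by_a = annot_a.by_gene_id()
    by_b = annot_b.by_gene_id()
    links: list[OrthologLink] = []
    for p in pairs:
        if p.gene_a not in by_a:
            raise KeyError(f"unknown gene id {p.gene_a!r} in genome {annot_a.genome_id}")
        if p.gene_b not in by_b:
            raise KeyError(f"unknown gene id {p.gene_b!r} in genome {annot_b.genome_id}")
        ga, gb = by_a[p.gene_a], by_b[p.gene_b]
        links.append(
            OrthologLink(
                gene_a=ga, gene_b=gb, identity=p.identity, bitscore=p.bitscore,
                orientation=1 if ga.strand == gb.strand else -1,
            )
        )
    links.sort(key=lambda ln: (ln.gene_a.chrom, ln.gene_a.start))
    return links


def links_from_hits(
    hits_ab: Iterable[AlignmentHit],
    hits_ba: Iterable[AlignmentHit],
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    thresholds: FilterThresholds = FilterThresholds(),
    mode: Literal["one_way", "reciprocal"] = "reciprocal",
) -> list[OrthologLink]:
    """Full classification: filter, collapse, classify, position.

    Filtering precedes uniqueness counting, so a gene with one strong and
    several noisy similarities still qualifies as single-copy.
    """
    ab = collapse_hits_per_gene_pair(
        filter_noise(hits_ab, thresholds), annot_a, annot_b, on_unknown="drop"
    )
    ba = collapse_hits_per_gene_pair(
        filter_noise(hits_ba, thresholds), annot_b, annot_a, on_unknown="drop"
    )
    pairs = classify_single_copy(ab, ba, annot_a, annot_b, mode=mode)
    return build_links(pairs, annot_a, annot_b)
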