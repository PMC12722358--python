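"""Synteny block chaining, rearrangement calling, and centromere-origin
classification.

Blocks are greedy left-to-right chains of ortholog links whose gene-rank
order is conserved (strictly increasing on genome A, strictly monotone on
genome B). Inversions are minority-orientation blocks within a chromosome
pair; translocations are blocks whose partner chromosome differs from the
dominant partner. Centromere intervals are projected across genomes via
their nearest flanking links; an interval whose projection lands inside an
otherwise contiguous syntenic block, away from any centromere of the other
genome, is classified as a de novo insertion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

from .io_formats import GenomeAnnotation, GenomicInterval
from .ortholog_links import OrthologLink

__all__ = [
    "SyntenyBlock",
    "RearrangementCall",
    "Projection",
    "CentromereOriginCall",
    "chain_blocks",
    "call_inversions",
    "call_translocations",
    "project_interval",
    "classify_centromere_origin",
]


@dataclass
class SyntenyBlock:
    """A maximal chain of order-consistent ortholog links."""

    chrom_a: str
    chrom_b: str
    links: list[OrthologLink]
    orientation: int  # +1 collinear, -1 inverted (genome-B rank direction)
    span_a: GenomicInterval
    span_b: GenomicInterval
    block_id: int = -1

    def __len__(self) -> int:
        return len(self.links)


@dataclass
class RearrangementCall:
    """An inversion or translocation, with the block(s) supporting it."""

    kind: Literal["inversion", "translocation"]
    blocks: tuple[SyntenyBlock, ...]
    reference_context: str

    @property
    def block(self) -> SyntenyBlock:
        return self.blocks[0]

    @property
    def links(self) -> list[OrthologLink]:
        return [ln for b in self.blocks for ln in b.links]

    @property
    def gene_ids_a(self) -> set[str]:
        return {ln.gene_a.gene_id for b in self.blocks for ln in b.links}


@dataclass
class Projection:
    projected: Optional[GenomicInterval]
    flank_left: Optional[OrthologLink]
    flank_right: Optional[OrthologLink]


@dataclass
class CentromereOriginCall:
    unit: GenomicInterval
    flank_left: Optional[OrthologLink]
    flank_right: Optional[OrthologLink]
    projected: Optional[GenomicInterval]
    klass: Literal["corresponding", "de_novo_insertion", "unresolved"]


def _span(intervals: Sequence[tuple[str, int, int]]) -> GenomicInterval:
    chrom = intervals[0][0]
    return GenomicInterval(
        chrom=chrom,
        start=min(iv[1] for iv in intervals),
        end=max(iv[2] for iv in intervals),
    )


def _make_block(chain: list[OrthologLink], orientation: int, block_id: int) -> SyntenyBlock:
    return SyntenyBlock(
        chrom_a=chain[0].gene_a.chrom,
        chrom_b=chain[0].gene_b.chrom,
        links=chain,
        orientation=orientation,
        span_a=_span([(ln.gene_a.chrom, ln.gene_a.start, ln.gene_a.end) for ln in chain]),
        span_b=_span([(ln.gene_b.chrom, ln.gene_b.start, ln.gene_b.end) for ln in chain]),
        block_id=block_id,
    )


def chain_blocks(
    links: Sequence[OrthologLink],
    annot_a: GenomeAnnotation,
    annot_b: GenomeAnnotation,
    max_gap_genes: int = 10,
    min_block_links: int = 5,
) -> tuple[list[SyntenyBlock], list[OrthologLink]]:
    """Chain links into synteny blocks; returns (blocks, unchained leftovers).

    Links must be sorted by genome-A position. Links are grouped by
    chromosome pair; within each pair a chain extends greedily while the
    genome-B rank steps in one direction and the rank gap on both genomes
    is <= ``max_gap_genes`` (links of other chromosome pairs, e.g. an
    interposed translocated segment, do not interrupt a chain). A one-link
    lookahead resolves boundary links: when a candidate would extend the
    chain with a large genome-B jump but pairs more tightly with the
    following link in the opposite direction (the typical first link of an
    inverted segment), the chain is closed instead. Chains shorter than
    ``min_block_links`` become leftovers. Every link is assigned to exactly
    one block or to the leftover set.
    """
    for prev, nxt in zip(links, links[1:]):
        if (prev.gene_a.chrom, prev.gene_a.start) > (nxt.gene_a.chrom, nxt.gene_a.start):
            raise ValueError("links must be sorted by genome-A position")

    rank_a = annot_a.gene_ranks()
    rank_b = annot_b.gene_ranks()

    groups: dict[tuple[str, str], list[OrthologLink]] = {}
    for ln in links:
        groups.setdefault((ln.gene_a.chrom, ln.gene_b.chrom), []).append(ln)

    blocks: list[SyntenyBlock] = []
    leftovers: list[OrthologLink] = []

    def step(l1: OrthologLink, l2: OrthologLink):
        """(a_gap, b_step) between two same-pair links, or None."""
        a_gap = rank_a[l2.gene_a.gene_id] - rank_a[l1.gene_a.gene_id]
        b_step = rank_b[l2.gene_b.gene_id] - rank_b[l1.gene_b.gene_id]
        if 0 < a_gap <= max_gap_genes and 0 < abs(b_step) <= max_gap_genes:
            return a_gap, b_step
        return None

    for key in sorted(groups):
        group = groups[key]
        chain: list[OrthologLink] = []
        orientation = 0  # 0 = undetermined (single-link chain)

        def close() -> None:
            nonlocal chain, orientation
            if not chain:
                return
            ori = orientation if orientation != 0 else chain[0].orientation
            if len(chain) >= min_block_links:
                blocks.append(_make_block(chain, ori, len(blocks)))
            else:
                leftovers.extend(chain)
            chain, orientation = [], 0

        for i, ln in enumerate(group):
            if not chain:
                chain = [ln]
                continue
            st = step(chain[-1], ln)
            ok = st is not None
            if ok and orientation != 0:
                ok = (st[1] > 0) == (orientation > 0)
            if ok and i + 1 < len(group):
                # lookahead: does ln bind more tightly to the next link, in
                # a direction incompatible with the extended chain?
                eff = orientation if orientation != 0 else (1 if st[1] > 0 else -1)
                st2 = step(ln, group[i + 1])
                if st2 is not None and ((st2[1] > 0) != (eff > 0)):
                    if abs(st[1]) > abs(st2[1]):
                        ok = False
            if ok:
                if orientation == 0:
                    orientation = 1 if st[1] > 0 else -1
                chain.append(ln)
            else:
                close()
                chain = [ln]
        close()

    blocks.sort(key=lambda b: (b.chrom_a, b.span_a.start, b.chrom_b))
    for i, b in enumerate(blocks):
        b.block_id = i
    leftovers.sort(key=lambda ln: (ln.gene_a.chrom, ln.gene_a.start))
    return blocks, leftovers


def _majority(counts: dict, tie_winner) -> dict:
    """argmax per key with deterministic tie resolution."""
    out = {}
    for key, sub in counts.items():
        best = None
        tied = False
        for cand in sorted(sub):
            if best is None or sub[cand] > sub[best]:
                best, tied = cand, False
            elif sub[cand] == sub[best]:
                tied = True
                if tie_winner(cand, best):
                    best = cand
        if tied:
            warnings.warn(f"tie for dominant context of {key}; resolved to {best}")
        out[key] = best
    return out


def call_inversions(
    blocks: Sequence[SyntenyBlock],
    min_event_links: int = 5,
    leftover_links: Sequence[OrthologLink] = (),
) -> list[RearrangementCall]:
    """Call a block as inverted when its orientation is the minority for its
    chromosome pair (by link count) and it is large enough to trust.

    Unchained leftover links, when given, vote for the dominant orientation
    through their strand-product orientation; blocks vote through their
    rank-direction orientation.
    """
    counts: dict[tuple[str, str], dict[int, int]] = {}
    for b in blocks:
        counts.setdefault((b.chrom_a, b.chrom_b), {}).setdefault(b.orientation, 0)
        counts[(b.chrom_a, b.chrom_b)][b.orientation] += len(b.links)
    for ln in leftover_links:
        key = (ln.gene_a.chrom, ln.gene_b.chrom)
        if key in counts:  # leftovers only weigh in on pairs that have blocks
            counts[key].setdefault(ln.orientation, 0)
            counts[key][ln.orientation] += 1
    dominant = _majority(counts, tie_winner=lambda cand, best: cand > best)  # tie -> +1

    calls = []
    for b in blocks:
        dom = dominant[(b.chrom_a, b.chrom_b)]
        if b.orientation != dom and len(b.links) >= min_event_links:
            calls.append(
                RearrangementCall(
                    kind="inversion",
                    blocks=(b,),
                    reference_context=f"dominant_orientation={dom:+d}",
                )
            )
    return calls


def call_translocations(
    blocks: Sequence[SyntenyBlock], min_event_links: int = 5
) -> list[RearrangementCall]:
    """Call blocks whose partner chromosome is not the dominant partner.

    Dominance is assessed from both genomes' sides; candidate blocks on the
    same chromosome pair whose genome-A spans overlap are merged into one
    call per contiguous region.
    """
    count_a: dict[str, dict[str, int]] = {}
    count_b: dict[str, dict[str, int]] = {}
    for b in blocks:
        count_a.setdefault(b.chrom_a, {}).setdefault(b.chrom_b, 0)
        count_a[b.chrom_a][b.chrom_b] += len(b.links)
        count_b.setdefault(b.chrom_b, {}).setdefault(b.chrom_a, 0)
        count_b[b.chrom_b][b.chrom_a] += len(b.links)
    dom_a = _majority(count_a, tie_winner=lambda cand, best: cand < best)
    dom_b = _majority(count_b, tie_winner=lambda cand, best: cand < best)

    cands = [
        b for b in blocks
        if len(b.links) >= min_event_links
        and (b.chrom_b != dom_a[b.chrom_a] or b.chrom_a != dom_b[b.chrom_b])
    ]

    # merge overlapping candidates per chromosome pair, in genome-A order
    grouped: dict[tuple[str, str], list[SyntenyBlock]] = {}
    for b in cands:
        grouped.setdefault((b.chrom_a, b.chrom_b), []).append(b)

    calls: list[RearrangementCall] = []
    for (ca, cb), group in sorted(grouped.items()):
        group.sort(key=lambda b: b.span_a.start)
        merged: list[list[SyntenyBlock]] = []
        for b in group:
            if merged and b.span_a.start < merged[-1][-1].span_a.end:
                merged[-1].append(b)
            else:
                merged.append([b])
        for region in merged:
            calls.append(
                RearrangementCall(
                    kind="translocation",
                    blocks=tuple(region),
                    reference_context=f"dominant_partner={dom_a[ca]}",
                )
            )
    return calls


def project_interval(
    interval: GenomicInterval,
    links: Sequence[OrthologLink],
    genome: Literal["a", "b"] = "a",
) -> Projection:
    """Project an interval onto the other genome via its flanking links.

    The nearest link entirely left and entirely right of the interval (on
    the interval's genome) define the projection: if both exist and their
    partner genes share a chromosome, the projected interval spans the gap
    between the partner genes' inner (gene-proximal) edges, which handles
    both collinear and inverted flank order. Missing or inconsistent flanks
    yield no projection.
    """
    def own(ln: OrthologLink):
        return ln.gene_a if genome == "a" else ln.gene_b

    def partner(ln: OrthologLink):
        return ln.gene_b if genome == "a" else ln.gene_a

    here = [ln for ln in links if own(ln).chrom == interval.chrom]
    left = [ln for ln in here if own(ln).end <= interval.start]
    right = [ln for ln in here if own(ln).start >= interval.end]
    flank_left = max(left, key=lambda ln: own(ln).end, default=None)
    flank_right = min(right, key=lambda ln: own(ln).start, default=None)

    if flank_left is None or flank_right is None:
        return Projection(None, flank_left, flank_right)
    p1, p2 = partner(flank_left), partner(flank_right)
    if p1.chrom != p2.chrom:
        return Projection(None, flank_left, flank_right)
    if p1.end <= p2.start:
        lo, hi = p1.end, p2.start
    elif p2.end <= p1.start:
        lo, hi = p2.end, p1.start
    else:
        return Projection(None, flank_left, flank_right)  # degenerate overlap
    if lo >= hi:
        return Projection(None, flank_left, flank_right)
    name = f"proj:{interval.name}" if interval.name else "proj"
    return Projection(
        GenomicInterval(chrom=p1.chrom, start=lo, end=hi, name=name),
        flank_left,
        flank_right,
    )


def _block_continuity(
    flank_left: OrthologLink,
    flank_right: OrthologLink,
    blocks: Sequence[SyntenyBlock],
) -> bool:
    """True when both flanks sit in one block, or in two blocks that are
    rank-adjacent continuations of each other (same chromosome pair,
    consecutive in genome-A order)."""
    membership: dict[str, SyntenyBlock] = {}
    for b in blocks:
        for ln in b.links:
            membership[ln.gene_a.gene_id] = b
    bl = membership.get(flank_left.gene_a.gene_id)
    br = membership.get(flank_right.gene_a.gene_id)
    if bl is None or br is None:
        return False
    if bl is br:
        return True
    if (bl.chrom_a, bl.chrom_b) != (br.chrom_a, br.chrom_b):
        return False
    ordered = sorted(
        (b for b in blocks if (b.chrom_a, b.chrom_b) == (bl.chrom_a, bl.chrom_b)),
        key=lambda b: b.span_a.start,
    )
    ids = [b.block_id for b in ordered]
    return abs(ids.index(bl.block_id) - ids.index(br.block_id)) == 1


def classify_centromere_origin(
    units_on_b: Sequence[GenomicInterval],
    units_on_a: Sequence[GenomicInterval],
    links: Sequence[OrthologLink],
    blocks: Sequence[SyntenyBlock],
    min_overlap_frac: float = 0.1,
) -> list[CentromereOriginCall]:
    """Classify each genome-B centromere unit by cross-genome projection.

    corresponding: the projection overlaps a genome-A unit (overlap >=
    ``min_overlap_frac`` of the smaller of the two intervals).
    de_novo_insertion: the projection exists, overlaps no genome-A unit,
    and the unit's flanks belong to one syntenic block (or two adjacent
    continuations) — the unit splits an otherwise contiguous block.
    unresolved: anything else (missing/inconsistent flanks, broken context).
    """
    calls: list[CentromereOriginCall] = []
    for unit in units_on_b:
        proj = project_interval(unit, links, genome="b")
        klass: str = "unresolved"
        if proj.projected is not None:
            hit = False
            for ua in units_on_a:
                ov = proj.projected.overlap(ua)
                if ov >= min_overlap_frac * min(len(proj.projected), len(ua)) and ov > 0:
                    hit = True
                    break
            if hit:
                klass = "corresponding"
            elif _block_continuity(proj.flank_left, proj.flank_right, blocks):
                klass = "de_novo_insertion"
        calls.append(
            CentromereOriginCall(
                unit=unit,
                flank_left=proj.flank_left,
                flank_right=proj.flank_right,
                projected=proj.projected,
                klass=klass,  # type: ignore[arg-type]
            )
        )
    return calls
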