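"""Readers and writers for the external formats the pipeline consumes.

All in-memory coordinates are 0-based half-open. GFF3 (1-based inclusive)
is converted on load; BED is already 0-based half-open. Keeping a single
internal convention avoids off-by-one drift between modules.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "GeneModel",
    "GenomeAnnotation",
    "AlignmentHit",
    "GenomicInterval",
    "read_gff3_genes",
    "read_tabular_hits",
    "write_tabular_hits",
    "read_bed",
    "write_links_tsv",
    "read_links_tsv",
]

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line/row."""


class ValidationError(ValueError):
    """Parsed content violates an invariant (e.g. empty interval)."""


@dataclass(frozen=True)
class GeneModel:
    """One gene with its representative protein.

    ``start``/``end`` are 0-based half-open genomic coordinates.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    protein_id: str
    protein_len: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")


@dataclass
class GenomeAnnotation:
    """Ordered gene models of one genome; the coordinate backbone for links."""

    genome_id: str
    genes: list[GeneModel] = field(default_factory=list)
    skipped_no_cds: int = 0
    unknown_feature_types: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate gene ids in genome {self.genome_id}")
        self.genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))

    def by_gene_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def protein_to_gene(self) -> dict[str, GeneModel]:
        return {g.protein_id: g for g in self.genes}

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g.chrom, None)
        return list(seen)

    def gene_ranks(self) -> dict[str, int]:
        """Rank of each gene within its chromosome (0-based, by start)."""
        ranks: dict[str, int] = {}
        current_chrom = None
        r = 0
        for g in self.genes:
            if g.chrom != current_chrom:
                current_chrom, r = g.chrom, 0
            ranks[g.gene_id] = r
            r += 1
        return ranks


@dataclass(frozen=True)
class AlignmentHit:
    """One row of 12-column tabular protein alignment output."""

    query_id: str
    subject_id: str
    pident: float
    align_len: int
    mismatches: int
    gapopens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0):
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: pident {self.pident} out of [0, 100]"
            )
        if self.align_len < 1:
            raise ValidationError(
                f"hit {self.query_id}->{self.subject_id}: align_len must be >= 1"
            )


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


# ---------------------------------------------------------------------------
# GFF3


def _validate_gff3_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            ncol = len(line.split("\t"))
            if ncol != 9:
                raise ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, got {ncol}"
                )


def read_gff3_genes(path: str, genome_id: str | None = None) -> GenomeAnnotation:
    """Load gene models from a GFF3 file.

    One :class:`GeneModel` per gene; the representative transcript is the
    mRNA with the longest summed CDS (ties broken by lexicographically
    smallest transcript id), and ``protein_len`` is its CDS length in codons.
    Genes without any CDS-bearing transcript are skipped and counted.
    Unknown feature types are ignored but tallied.
    """
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        path, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=True,
    )
    known = {"gene", "mRNA", "CDS", "exon"}
    unknown: dict[str, int] = {}
    for ft in db.featuretypes():
        if ft not in known:
            unknown[ft] = sum(1 for _ in db.features_of_type(ft))

    genes: list[GeneModel] = []
    skipped = 0
    for gene in db.features_of_type("gene"):
        best: tuple[int, str] | None = None  # (cds_bp, transcript id)
        for mrna in db.children(gene, featuretype="mRNA"):
            cds_bp = sum(
                c.end - c.start + 1 for c in db.children(mrna, featuretype="CDS")
            )
            if cds_bp == 0:
                continue
            cand = (cds_bp, mrna.id)
            if best is None or cds_bp > best[0] or (cds_bp == best[0] and mrna.id < best[1]):
                best = cand
        if best is None:
            skipped += 1
            continue
        cds_bp, tx_id = best
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start - 1,  # GFF3 is 1-based inclusive
                end=gene.end,
                strand=gene.strand if gene.strand in ("+", "-") else "+",
                protein_id=tx_id,
                protein_len=cds_bp // 3,
            )
        )
    return GenomeAnnotation(
        genome_id=genome_id or os.path.basename(path),
        genes=genes,
        skipped_no_cds=skipped,
        unknown_feature_types=unknown,
    )


# ---------------------------------------------------------------------------
# Tabular alignment hits (blast outfmt-6 style)


def read_tabular_hits(path: str) -> list[AlignmentHit]:
    """Read 12-column tab-separated alignment records, preserving row order."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", names=HIT_COLUMNS,
            dtype=str, keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] != 12:
        raise ParseError(f"{path}: expected 12 columns, got {df.shape[1]}")

    numeric = {
        "pident": float, "length": int, "mismatch": int, "gapopen": int,
        "qstart": int, "qend": int, "sstart": int, "send": int,
        "evalue": float, "bitscore": float,
    }
    for col, kind in numeric.items():
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ParseError(
                f"{path}: row {row}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col}"
            )
        # astype parses via strtod (correctly rounded); to_numeric's fast
        # parser is not, which would break write/read round-trips
        df[col] = df[col].astype(float).astype(kind)

    return [
        AlignmentHit(
            query_id=r.qseqid, subject_id=r.sseqid, pident=float(r.pident),
            align_len=int(r.length), mismatches=int(r.mismatch),
            gapopens=int(r.gapopen), qstart=int(r.qstart), qend=int(r.qend),
            sstart=int(r.sstart), send=int(r.send), evalue=float(r.evalue),
            bitscore=float(r.bitscore),
        )
        for r in df.itertuples(index=False)
    ]


def write_tabular_hits(hits: list[AlignmentHit], path: str) -> None:
    rows = [
        (h.query_id, h.subject_id, h.pident, h.align_len, h.mismatches,
         h.gapopens, h.qstart, h.qend, h.sstart, h.send, h.evalue, h.bitscore)
        for h in hits
    ]
    pd.DataFrame(rows, columns=HIT_COLUMNS).to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str) -> list[GenomicInterval]:
    """Read a BED3+ file; intervals come back sorted per chromosome."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str,
                         keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 3:
        raise ParseError(f"{path}: BED needs at least 3 columns, got {df.shape[1]}")
    out: list[GenomicInterval] = []
    for idx, row in enumerate(df.itertuples(index=False), start=1):
        try:
            start, end = int(row[1]), int(row[2])
        except ValueError as exc:
            raise ParseError(f"{path}: row {idx}: non-integer coordinate") from exc
        name = str(row[3]) if df.shape[1] > 3 else f"{row[0]}:{start}-{end}"
        strand = str(row[5]) if df.shape[1] > 5 and str(row[5]) in ("+", "-") else "."
        if start >= end:
            raise ValidationError(
                f"{path}: row {idx}: start {start} must be < end {end}"
            )
        out.append(GenomicInterval(chrom=str(row[0]), start=start, end=end,
                                   name=name, strand=strand))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_bed(intervals: list[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Links TSV

_LINK_HEADER = (
    "#chrom_a\tstart_a\tend_a\tstrand_a\tchrom_b\tstart_b\tend_b\tstrand_b\t"
    "identity\tgene_a\tgene_b\tprotein_a\tprotein_len_a\tprotein_b\t"
    "protein_len_b\tbitscore\torientation"
)


def write_links_tsv(links, path: str) -> None:
    """Write ortholog links as TSV (0-based half-open coordinates).

    The first nine columns carry the positional payload used by synteny
    plotters; the remaining columns make the file a lossless round-trip of
    the in-memory link list.
    """
    with open(path, "w") as fh:
        fh.write(_LINK_HEADER + "\n")
        for ln in links:
            a, b = ln.gene_a, ln.gene_b
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{a.strand}\t"
                f"{b.chrom}\t{b.start}\t{b.end}\t{b.strand}\t"
                f"{ln.identity:.6g}\t{a.gene_id}\t{b.gene_id}\t"
                f"{a.protein_id}\t{a.protein_len}\t{b.protein_id}\t{b.protein_len}\t"
                f"{ln.bitscore:.6g}\t{ln.orientation:+d}\n"
            )


def read_links_tsv(path: str):
    """Inverse of :func:`write_links_tsv`."""
    from .ortholog_links import OrthologLink  # local import: avoid cycle

    links = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 17:
                raise ParseError(f"{path}: line {lineno}: expected 17 columns, got {len(f)}")
            gene_a = GeneModel(f[9], f[0], int(f[1]), int(f[2]), f[3], f[11], int(f[12]))
            gene_b = GeneModel(f[10], f[4], int(f[5]), int(f[6]), f[7], f[13], int(f[14]))
            links.append(
                OrthologLink(
                    gene_a=gene_a, gene_b=gene_b, identity=float(f[8]),
                    bitscore=float(f[15]), orientation=int(f[16]),
                )
            )
    return links
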