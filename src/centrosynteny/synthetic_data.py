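"""Synthetic fixtures with planted truth.

Emulates the study design of a pair of sister genomes with contrasting
centromere types: genome B derives from genome A by inversions (reversed
gene order + flipped strands), inter-chromosomal translocations, gene-free
centromere-interval insertions, and optional gene duplications; proteins
are divergent copies at a controlled identity. Satellite arrays are built
from a monomer with controlled per-base mutation, orientation-flip runs,
and a higher-order repeat period. ChIP/input counts carry planted
enrichment over known window blocks.

All generators are pure functions of (config, seed): reruns are
byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    AlignmentHit,
    GeneModel,
    GenomeAnnotation,
    GenomicInterval,
)
from .satellite_analysis import revcomp

__all__ = [
    "SimulationConfig",
    "TruthTables",
    "SimulatedGenomePair",
    "simulate_genome_pair",
    "hits_from_truth",
    "mutate_protein",
    "simulate_satellite_array",
    "simulate_chip_counts",
    "write_genome_fixtures",
]

AA = "ACDEFGHIKLMNPQRSTVWY"
DNA = "ACGT"

GENE_LEN = 1_200       # bp, uniform synthetic gene length
GENE_SPACING = 10_000  # bp between gene starts
CEN_UNIT_LEN = 50_000  # bp, inserted centromere interval
CEN_PAD = 5_000        # bp of plain gap flanking an inserted unit


@dataclass
class SimulationConfig:
    """Knobs of the paired-genome simulation.

    Defaults reproduce the planted-truth study conditions used throughout
    the test-bed: a genome of 4 chromosomes x 60 genes, 3 inversions and 4
    translocations of 5-10 genes each, proteins at 95% identity, 7
    centromere insertions in genome B and one centromere interval elsewhere
    in genome A.
    """

    seed: int = 0
    n_chromosomes: int = 4
    genes_per_chromosome: int = 60
    n_inversions: int = 3
    n_translocations: int = 4
    inversion_size_genes: tuple[int, int] = (5, 10)
    translocation_size_genes: tuple[int, int] = (5, 10)
    duplicate_fraction: float = 0.0
    protein_identity: float = 0.95
    protein_len_range: tuple[int, int] = (180, 400)
    centromere_insertions_b: int = 7
    centromere_intervals_a: int = 1
    noise_hits: int = 50

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_chromosomes", "genes_per_chromosome", "n_inversions",
                     "n_translocations", "centromere_insertions_b",
                     "centromere_intervals_a", "noise_hits"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.protein_identity <= 1):
            raise ValueError("protein_identity must be in (0, 1]")


@dataclass
class EventTruth:
    kind: str                 # inversion | translocation
    chrom_a: str
    chrom_b: str              # destination chromosome in genome B
    gene_ids: tuple[str, ...]

    def to_json(self) -> dict:
        return asdict(self)


@dataclass
class CentromereUnitTruth:
    interval: GenomicInterval
    origin: str               # de_novo_insertion | corresponding
    flank_gene_left: str = ""
    flank_gene_right: str = ""


@dataclass
class TruthTables:
    """Everything that was planted, recorded exactly once."""

    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    realized_identity: dict[str, float] = field(default_factory=dict)
    duplicated_genes: list[str] = field(default_factory=list)
    inversions: list[EventTruth] = field(default_factory=list)
    translocations: list[EventTruth] = field(default_factory=list)
    centromere_units_a: list[GenomicInterval] = field(default_factory=list)
    centromere_units_b: list[CentromereUnitTruth] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "ortholog_pairs": [list(p) for p in self.ortholog_pairs],
            "realized_identity": self.realized_identity,
            "duplicated_genes": self.duplicated_genes,
            "inversions": [e.to_json() for e in self.inversions],
            "translocations": [e.to_json() for e in self.translocations],
            "centromere_units_a": [asdict(iv) for iv in self.centromere_units_a],
            "centromere_units_b": [
                {"interval": asdict(u.interval), "origin": u.origin,
                 "flank_gene_left": u.flank_gene_left,
                 "flank_gene_right": u.flank_gene_right}
                for u in self.centromere_units_b
            ],
        }


@dataclass
class SimulatedGenomePair:
    annot_a: GenomeAnnotation
    annot_b: GenomeAnnotation
    proteins_a: dict[str, str]
    proteins_b: dict[str, str]
    truth: TruthTables


# ---------------------------------------------------------------------------
# Protein / DNA mutation


def mutate_protein(seq: str, target_identity: float, seed) -> str:
    """Substitute positions (sampled without replacement) so the realized
    identity is exactly round(len * target_identity) / len."""
    if not seq:
        raise ValueError("empty sequence")
    if not (0 < target_identity <= 1):
        raise ValueError("target_identity must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(seq)
    n_sub = n - int(round(n * target_identity))
    if n_sub == 0:
        return seq
    positions = rng.choice(n, size=n_sub, replace=False)
    out = list(seq)
    for p in positions:
        alternatives = [a for a in AA if a != out[p]]
        out[p] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _mutate_dna_exact(seq: str, divergence: float, rng: np.random.Generator) -> str:
    n_sub = int(round(len(seq) * divergence))
    if n_sub == 0:
        return seq
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for p in positions:
        alternatives = [b for b in DNA if b != out[p]]
        out[p] = alternatives[rng.integers(3)]
    return "".join(out)


def _mutate_dna_rate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    mask = rng.random(len(seq)) < rate
    out = list(seq)
    for p in np.nonzero(mask)[0]:
        alternatives = [b for b in DNA if b != out[p]]
        out[p] = alternatives[rng.integers(3)]
    return "".join(out)


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(DNA[i] for i in rng.integers(4, size=length))


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AA[i] for i in rng.integers(len(AA), size=length))


# ---------------------------------------------------------------------------
# Paired genomes


def _place_windows(
    rng: np.random.Generator,
    sizes_by_chrom: dict[str, int],
    n_events: int,
    size_range: tuple[int, int],
    occupied: dict[str, list[tuple[int, int]]],
    margin: int = 2,
    buffer: int = 1,
) -> list[tuple[str, int, int]]:
    """Sample non-overlapping gene-rank windows across chromosomes."""
    placed: list[tuple[str, int, int]] = []
    chroms = sorted(sizes_by_chrom)
    for _ in range(n_events):
        for attempt in range(500):
            chrom = chroms[rng.integers(len(chroms))]
            n = sizes_by_chrom[chrom]
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            if n - 2 * margin - size <= 0:
                continue
            start = int(rng.integers(margin, n - margin - size + 1))
            window = (start - buffer, start + size + buffer)
            if all(
                window[1] <= s or window[0] >= e
                for s, e in occupied.get(chrom, [])
            ):
                occupied.setdefault(chrom, []).append(window)
                placed.append((chrom, start, start + size))
                break
        else:
            raise ValueError(
                "could not place non-overlapping events; reduce counts/sizes"
            )
    return placed


@dataclass
class _BGene:
    gene_id: str
    strand: str


def simulate_genome_pair(config: SimulationConfig) -> SimulatedGenomePair:
    """Generate a pair of annotated genomes with planted truth.

    Genome A lays genes on a uniform grid. Genome B applies, in order:
    translocation extraction/insertion, inversions (reverse gene order +
    strand flips), centromere-interval insertions between consecutive
    genes, and duplications. Truth tables record every planted event.
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthTables()

    # --- genome A
    chrom_names_a = [f"A_chr{c + 1}" for c in range(config.n_chromosomes)]
    genes_a: list[GeneModel] = []
    proteins_a: dict[str, str] = {}
    order_a: dict[str, list[str]] = {}
    for ci, chrom in enumerate(chrom_names_a):
        order_a[chrom] = []
        for k in range(config.genes_per_chromosome):
            gid = f"gA_{ci + 1}_{k + 1:03d}"
            start = k * GENE_SPACING + 4_000
            strand = "+" if rng.random() < 0.5 else "-"
            plen = int(rng.integers(*config.protein_len_range))
            genes_a.append(
                GeneModel(gid, chrom, start, start + GENE_LEN, strand,
                          f"{gid}.p1", plen)
            )
            proteins_a[f"{gid}.p1"] = random_protein(plen, rng)
            order_a[chrom].append(gid)
    by_id_a = {g.gene_id: g for g in genes_a}

    # --- plant event windows on genome-A gene ranks
    sizes = {c: config.genes_per_chromosome for c in chrom_names_a}
    occupied: dict[str, list[tuple[int, int]]] = {}
    tr_windows = _place_windows(
        rng, sizes, config.n_translocations, config.translocation_size_genes,
        occupied,
    )
    inv_windows = _place_windows(
        rng, sizes, config.n_inversions, config.inversion_size_genes, occupied,
    )

    # --- genome B as per-chromosome gene lists (A order to start)
    chrom_map = {a: a.replace("A_chr", "B_chr") for a in chrom_names_a}
    b_lists: dict[str, list[_BGene]] = {
        chrom_map[c]: [_BGene(g, by_id_a[g].strand) for g in order_a[c]]
        for c in chrom_names_a
    }
    inv_gene_sets = [
        set(order_a[c][s:e]) for c, s, e in inv_windows
    ]

    # translocations: extract the run, insert into another chromosome at a
    # junction that (i) does not split a planted inversion window or a
    # previously inserted run, and (ii) keeps a clearance of more than the
    # chaining gap from earlier inserted runs, so planted events remain
    # distinguishable as separate blocks
    protected_sets = list(inv_gene_sets)
    inserted_genes: set[str] = set()
    clearance = 12  # > default max_gap_genes
    for c, s, e in tr_windows:
        run_ids = order_a[c][s:e]
        src = chrom_map[c]
        run = [bg for bg in b_lists[src] if bg.gene_id in set(run_ids)]
        b_lists[src] = [bg for bg in b_lists[src] if bg.gene_id not in set(run_ids)]
        targets = [x for x in sorted(b_lists) if x != src]
        placed = False
        for _ in range(200):
            target = targets[rng.integers(len(targets))]
            tl = b_lists[target]
            k = int(rng.integers(1, len(tl)))
            if any(
                tl[k - 1].gene_id in sset and tl[k].gene_id in sset
                for sset in protected_sets
            ):
                continue
            nearby = tl[max(0, k - clearance):k + clearance]
            if any(bg.gene_id in inserted_genes for bg in nearby):
                continue
            b_lists[target] = tl[:k] + run + tl[k:]
            placed = True
            break
        if not placed:
            raise ValueError(
                "could not place translocation insertion with clearance"
            )
        protected_sets.append(set(run_ids))
        inserted_genes |= set(run_ids)
        truth.translocations.append(
            EventTruth("translocation", c, target, tuple(run_ids))
        )

    # inversions: reverse the run in place and flip strands
    for (c, s, e), sset in zip(inv_windows, inv_gene_sets):
        chrom_b = None
        for bc, tl in b_lists.items():
            idx = [k for k, bg in enumerate(tl) if bg.gene_id in sset]
            if idx:
                chrom_b = bc
                lo, hi = min(idx), max(idx) + 1
                seg = tl[lo:hi][::-1]
                for bg in seg:
                    bg.strand = "+" if bg.strand == "-" else "-"
                b_lists[bc] = tl[:lo] + seg + tl[hi:]
                break
        truth.inversions.append(
            EventTruth("inversion", c, chrom_b or chrom_map[c],
                       tuple(order_a[c][s:e]))
        )

    # --- centromere insertions in genome B: pick junctions inside unbroken
    # collinear context (a run of consecutive, event-free genes), so each
    # planted unit genuinely splits one syntenic block
    event_genes = set().union(*inv_gene_sets) if inv_gene_sets else set()
    for ev in truth.translocations:
        event_genes |= set(ev.gene_ids)
    a_index = {
        gid: (chrom, idx)
        for chrom in chrom_names_a
        for idx, gid in enumerate(order_a[chrom])
    }

    def intact_run(tl: list[_BGene], k: int, radius: int = 3) -> bool:
        if k - radius < 0 or k + radius > len(tl):
            return False
        window = tl[k - radius:k + radius]
        if any(bg.gene_id in event_genes for bg in window):
            return False
        positions = [a_index[bg.gene_id] for bg in window]
        chroms = {c for c, _ in positions}
        if len(chroms) != 1:
            return False
        idxs = [i for _, i in positions]
        return idxs == list(range(idxs[0], idxs[0] + len(idxs)))

    cen_junctions: list[tuple[str, int]] = []  # (B chrom, junction index)
    attempts = 0
    while len(cen_junctions) < config.centromere_insertions_b:
        attempts += 1
        if attempts > 5000:
            raise ValueError("could not place centromere insertions")
        bc = sorted(b_lists)[rng.integers(len(b_lists))]
        tl = b_lists[bc]
        k = int(rng.integers(3, len(tl) - 3))
        if not intact_run(tl, k):
            continue
        if any(bc == c2 and abs(k - k2) < 3 for c2, k2 in cen_junctions):
            continue
        cen_junctions.append((bc, k))
    cen_junctions.sort()

    # --- assign genome-B coordinates, inserting centromere gaps
    genes_b: list[GeneModel] = []
    proteins_b: dict[str, str] = {}
    for bc in sorted(b_lists):
        tl = b_lists[bc]
        junctions_here = {k for c2, k in cen_junctions if c2 == bc}
        pos = 0
        for k, bg in enumerate(tl):
            if k in junctions_here:
                unit = GenomicInterval(
                    bc, pos + CEN_PAD, pos + CEN_PAD + CEN_UNIT_LEN,
                    name=f"cenB_{bc}_{k}",
                )
                truth.centromere_units_b.append(
                    CentromereUnitTruth(
                        interval=unit, origin="de_novo_insertion",
                        flank_gene_left=tl[k - 1].gene_id,
                        flank_gene_right=tl[k].gene_id,
                    )
                )
                pos += 2 * CEN_PAD + CEN_UNIT_LEN
            gid_b = bg.gene_id.replace("gA_", "gB_")
            start = pos + 4_000
            prot_a = proteins_a[bg.gene_id + ".p1"]
            prot_b = mutate_protein(
                prot_a, config.protein_identity, rng
            )
            realized = sum(x == y for x, y in zip(prot_a, prot_b)) / len(prot_a)
            genes_b.append(
                GeneModel(gid_b, bc, start, start + GENE_LEN, bg.strand,
                          f"{gid_b}.p1", len(prot_b))
            )
            proteins_b[f"{gid_b}.p1"] = prot_b
            truth.ortholog_pairs.append((bg.gene_id, gid_b))
            truth.realized_identity[bg.gene_id] = realized
            pos += GENE_SPACING

    # --- genome-A centromere interval(s), away from any B-unit junction
    b_flank_pairs = {
        (u.flank_gene_left.replace("gB_", "gA_"),
         u.flank_gene_right.replace("gB_", "gA_"))
        for u in truth.centromere_units_b
    }
    placed_a = 0
    attempts = 0
    while placed_a < config.centromere_intervals_a:
        attempts += 1
        if attempts > 5000:
            raise ValueError("could not place genome-A centromere interval")
        chrom = chrom_names_a[rng.integers(len(chrom_names_a))]
        k = int(rng.integers(3, config.genes_per_chromosome - 3))
        left, right = order_a[chrom][k - 1], order_a[chrom][k]
        if (left, right) in b_flank_pairs or {left, right} & event_genes:
            continue
        gap_start = by_id_a[left].end
        truth.centromere_units_a.append(
            GenomicInterval(chrom, gap_start + 2_000, gap_start + 7_000,
                            name=f"cenA_{chrom}_{k}")
        )
        placed_a += 1

    # --- planted duplicates
    n_dup = int(round(config.duplicate_fraction * len(genes_a)))
    if n_dup:
        eligible = sorted(
            g.gene_id for g in genes_a if g.gene_id not in event_genes
        )
        dup_ids = [eligible[i] for i in
                   rng.choice(len(eligible), size=n_dup, replace=False)]
        b_chroms = sorted({g.chrom for g in genes_b})
        tail_pos = {bc: max(g.end for g in genes_b if g.chrom == bc)
                    for bc in b_chroms}
        for gid in sorted(dup_ids):
            bc = b_chroms[rng.integers(len(b_chroms))]
            start = tail_pos[bc] + GENE_SPACING
            tail_pos[bc] = start + GENE_LEN
            dup_gid = gid.replace("gA_", "gB_") + "_dup"
            prot = mutate_protein(proteins_a[gid + ".p1"],
                                  config.protein_identity, rng)
            genes_b.append(
                GeneModel(dup_gid, bc, start, start + GENE_LEN, "+",
                          f"{dup_gid}.p1", len(prot))
            )
            proteins_b[f"{dup_gid}.p1"] = prot
            truth.duplicated_genes.append(gid)
        dup_set = set(truth.duplicated_genes)
        truth.ortholog_pairs = [
            p for p in truth.ortholog_pairs if p[0] not in dup_set
        ]

    annot_a = GenomeAnnotation("genomeA", genes_a)
    annot_b = GenomeAnnotation("genomeB", genes_b)
    return SimulatedGenomePair(annot_a, annot_b, proteins_a, proteins_b, truth)


def hits_from_truth(
    sim: SimulatedGenomePair, config: SimulationConfig
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Emit alignment hit tables directly from the planted truth.

    Every ortholog (and duplicate) pair yields one hit in each direction at
    its realized identity; sub-threshold noise hits between random
    non-ortholog proteins exercise the filtering stage.
    """
    rng = np.random.default_rng(config.seed + 101)
    by_a = sim.annot_a.by_gene_id()
    by_b = sim.annot_b.by_gene_id()

    def mk(qgene: GeneModel, sgene: GeneModel, pident: float) -> AlignmentHit:
        alen = min(qgene.protein_len, sgene.protein_len)
        mism = int(round(alen * (1 - pident / 100.0)))
        return AlignmentHit(
            query_id=qgene.protein_id, subject_id=sgene.protein_id,
            pident=pident, align_len=alen, mismatches=mism, gapopens=0,
            qstart=1, qend=alen, sstart=1, send=alen,
            evalue=1e-180, bitscore=round(2.0 * alen * pident / 100.0, 1),
        )

    ab: list[AlignmentHit] = []
    ba: list[AlignmentHit] = []
    pair_targets: list[tuple[str, str]] = list(sim.truth.ortholog_pairs)
    for gid_a in sim.truth.duplicated_genes:
        pair_targets.append((gid_a, gid_a.replace("gA_", "gB_")))
        pair_targets.append((gid_a, gid_a.replace("gA_", "gB_") + "_dup"))
    for gid_a, gid_b in pair_targets:
        ga, gb = by_a[gid_a], by_b[gid_b]
        pid = 100.0 * sim.truth.realized_identity.get(gid_a, config.protein_identity)
        ab.append(mk(ga, gb, pid))
        ba.append(mk(gb, ga, pid))

    genes_a = sorted(by_a)
    genes_b = sorted(by_b)
    for _ in range(config.noise_hits):
        ga = by_a[genes_a[rng.integers(len(genes_a))]]
        gb = by_b[genes_b[rng.integers(len(genes_b))]]
        pid = float(np.round(rng.uniform(35.0, 89.5), 2))
        ab.append(mk(ga, gb, pid))
        ba.append(mk(gb, ga, pid))

    ab.sort(key=lambda h: (h.query_id, h.subject_id, -h.bitscore))
    ba.sort(key=lambda h: (h.query_id, h.subject_id, -h.bitscore))
    return ab, ba


# ---------------------------------------------------------------------------
# Satellite arrays


def simulate_satellite_array(
    monomer: str,
    copies: int,
    mutation_rate: float,
    hor_period: int = 1,
    flips: Sequence[tuple[int, int]] = (),
    seed: int = 0,
    variant_divergence: float = 0.08,
) -> tuple[str, list[dict]]:
    """Build a satellite array with a planted higher-order structure.

    ``hor_period`` divergent monomer variants (each at ``variant_divergence``
    per-base divergence from the input monomer, giving ~85% between-variant
    identity at the default) cycle along the array; each copy then receives
    independent per-base substitutions at ``mutation_rate``. ``flips`` are
    (start, end) monomer-index ranges whose copies are reverse-complemented
    in place. Returns the sequence and a per-copy truth list with keys
    start/end/variant/orientation.
    """
    if not monomer:
        raise ValueError("monomer must be non-empty")
    if not (0 <= mutation_rate <= 0.5):
        raise ValueError("mutation_rate must be in [0, 0.5]")
    if hor_period < 1:
        raise ValueError("hor_period must be >= 1")
    rng = np.random.default_rng(seed)
    monomer = monomer.upper()
    variants = [monomer]
    for _ in range(hor_period - 1):
        variants.append(_mutate_dna_exact(monomer, variant_divergence, rng))

    flipped = set()
    for s, e in flips:
        flipped.update(range(s, e))

    pieces: list[str] = []
    truth: list[dict] = []
    pos = 0
    for i in range(copies):
        var = i % hor_period
        copy = _mutate_dna_rate(variants[var], mutation_rate, rng)
        orient = "F"
        if i in flipped:
            copy = revcomp(copy)
            orient = "R"
        pieces.append(copy)
        truth.append(
            {"start": pos, "end": pos + len(copy), "variant": var,
             "orientation": orient}
        )
        pos += len(copy)
    return "".join(pieces), truth


# ---------------------------------------------------------------------------
# ChIP / input counts


def simulate_chip_counts(
    n_windows: int,
    enriched_blocks: Sequence[tuple[int, int]],
    depth: float,
    enrichment: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Poisson ChIP/input window counts with planted enrichment.

    input ~ Poisson(depth) everywhere; ChIP ~ Poisson(depth * enrichment)
    inside the given (start, end) window blocks and Poisson(depth) outside.
    Returns (chip, input, truth_mask).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    mask = np.zeros(n_windows, dtype=bool)
    for s, e in enriched_blocks:
        if not (0 <= s < e <= n_windows):
            raise ValueError(f"block ({s}, {e}) outside window range")
        mask[s:e] = True
    lam_chip = np.where(mask, depth * enrichment, depth)
    chip = rng.poisson(lam_chip)
    inp = rng.poisson(np.full(n_windows, float(depth)))
    return chip, inp, mask


# ---------------------------------------------------------------------------
# Fixture files


def write_genome_fixtures(sim: SimulatedGenomePair, outdir: str) -> dict[str, str]:
    """Write GFF3 / FASTA / BED / hits-TSV / truth-JSON fixture files."""
    import os

    from .io_formats import write_bed, write_tabular_hits

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "gff_a": os.path.join(outdir, "genomeA.gff3"),
        "gff_b": os.path.join(outdir, "genomeB.gff3"),
        "prot_a": os.path.join(outdir, "genomeA.faa"),
        "prot_b": os.path.join(outdir, "genomeB.faa"),
        "cen_a": os.path.join(outdir, "cen_a.bed"),
        "cen_b": os.path.join(outdir, "cen_b.bed"),
        "truth": os.path.join(outdir, "truth.json"),
    }

    def write_gff3(annot: GenomeAnnotation, proteins: dict[str, str], path: str):
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in annot.genes:
                s1, e1 = g.start + 1, g.end  # back to 1-based inclusive
                fh.write(
                    f"{g.chrom}\tsim\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}\n"
                )
                fh.write(
                    f"{g.chrom}\tsim\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                    f"ID={g.protein_id};Parent={g.gene_id}\n"
                )
                fh.write(
                    f"{g.chrom}\tsim\tCDS\t{s1}\t{s1 + 3 * g.protein_len - 1}\t.\t"
                    f"{g.strand}\t0\tID={g.protein_id}.cds;Parent={g.protein_id}\n"
                )

    def write_fasta(proteins: dict[str, str], path: str):
        with open(path, "w") as fh:
            for pid in sorted(proteins):
                fh.write(f">{pid}\n")
                seq = proteins[pid]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")

    write_gff3(sim.annot_a, sim.proteins_a, paths["gff_a"])
    write_gff3(sim.annot_b, sim.proteins_b, paths["gff_b"])
    write_fasta(sim.proteins_a, paths["prot_a"])
    write_fasta(sim.proteins_b, paths["prot_b"])
    write_bed(sim.truth.centromere_units_a, paths["cen_a"])
    write_bed([u.interval for u in sim.truth.centromere_units_b], paths["cen_b"])
    with open(paths["truth"], "w") as fh:
        json.dump(sim.truth.to_json(), fh, indent=1, sort_keys=True)
    return paths
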