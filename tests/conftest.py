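import numpy as np
import pytest

from centrosynteny.io_formats import AlignmentHit, GeneModel, GenomeAnnotation
from centrosynteny.ortholog_links import links_from_hits
from centrosynteny.synthetic_data import (
    SimulationConfig,
    hits_from_truth,
    simulate_genome_pair,
)


def make_hit(query="pA", subject="pB", pident=95.0, align_len=200,
             bitscore=400.0, **kw):
    defaults = dict(mismatches=10, gapopens=0, qstart=1, qend=align_len,
                    sstart=1, send=align_len, evalue=1e-50)
    defaults.update(kw)
    return AlignmentHit(query_id=query, subject_id=subject, pident=pident,
                        align_len=align_len, bitscore=bitscore, **defaults)


def make_annotation(genome_id, n_genes, chrom=None, prefix=None, strands=None):
    """Uniform-grid annotation with one gene per 10 kb."""
    chrom = chrom or f"{genome_id}_chr1"
    prefix = prefix or f"g{genome_id}"
    genes = []
    for k in range(n_genes):
        strand = strands[k] if strands else "+"
        gid = f"{prefix}_{k + 1:03d}"
        genes.append(GeneModel(gid, chrom, k * 10_000, k * 10_000 + 1_200,
                               strand, f"{gid}.p", 200))
    return GenomeAnnotation(genome_id, genes)


def toy_link_set(b_order, b_strands=None):
    """Links between an n-gene genome A (identity order) and genome B whose
    gene k sits at position b_order[k] (0-based), with optional strands.

    Returns (annot_a, annot_b, links) with one link per gene.
    """
    n = len(b_order)
    annot_a = make_annotation("A", n)
    strands_b = b_strands or ["+"] * n
    genes_b = []
    for k in range(n):
        gid = f"gB_{k + 1:03d}"
        pos = b_order[k]
        genes_b.append(GeneModel(gid, "B_chr1", pos * 10_000,
                                 pos * 10_000 + 1_200, strands_b[k],
                                 f"{gid}.p", 200))
    annot_b = GenomeAnnotation("B", genes_b)
    hits_ab = [make_hit(f"gA_{k + 1:03d}.p", f"gB_{k + 1:03d}.p") for k in range(n)]
    hits_ba = [make_hit(f"gB_{k + 1:03d}.p", f"gA_{k + 1:03d}.p") for k in range(n)]
    links = links_from_hits(hits_ab, hits_ba, annot_a, annot_b)
    return annot_a, annot_b, links


def random_bipartite_instance(rng):
    """Random bipartite hit instance (<= 50 genes/side) plus its edge lists."""
    na, nb = int(rng.integers(1, 51)), int(rng.integers(1, 51))
    annot_a = make_annotation("A", na, prefix="gA")
    annot_b = make_annotation("B", nb, prefix="gB")
    n_edges = int(rng.integers(0, 3 * max(na, nb)))
    ab_edges = set()
    ba_edges = set()
    for _ in range(n_edges):
        ga = f"gA_{int(rng.integers(1, na + 1)):03d}"
        gb = f"gB_{int(rng.integers(1, nb + 1)):03d}"
        if rng.random() < 0.5:
            ab_edges.add((ga, gb))
        else:
            ba_edges.add((gb, ga))
        if rng.random() < 0.5:  # make some edges reciprocal
            ab_edges.add((ga, gb))
            ba_edges.add((gb, ga))
    hits_ab = [make_hit(f"{ga}.p", f"{gb}.p") for ga, gb in sorted(ab_edges)]
    hits_ba = [make_hit(f"{gb}.p", f"{ga}.p") for gb, ga in sorted(ba_edges)]
    return annot_a, annot_b, hits_ab, hits_ba, ab_edges, ba_edges


def run_synteny(sim, config):
    """ortholog links + blocks + leftovers for a simulated pair."""
    from centrosynteny.synteny_centromere import chain_blocks

    ab, ba = hits_from_truth(sim, config)
    links = links_from_hits(ab, ba, sim.annot_a, sim.annot_b)
    blocks, leftovers = chain_blocks(links, sim.annot_a, sim.annot_b)
    return links, blocks, leftovers


@pytest.fixture(scope="session")
def default_sim():
    config = SimulationConfig(seed=1)
    return config, simulate_genome_pair(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
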