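import pytest

from centrosynteny.io_formats import GenomicInterval
from centrosynteny.ortholog_links import OrthologLink
from centrosynteny.synteny_centromere import (
    call_inversions,
    call_translocations,
    chain_blocks,
    classify_centromere_origin,
    project_interval,
)
from centrosynteny.synthetic_data import SimulationConfig, simulate_genome_pair

from conftest import run_synteny, toy_link_set


class TestChainBlocks:
    def test_collinear_links_form_one_block(self):
        a, b, links = toy_link_set(list(range(8)))
        blocks, leftovers = chain_blocks(links, a, b, min_block_links=5)
        assert len(blocks) == 1 and not leftovers
        assert len(blocks[0].links) == 8 and blocks[0].orientation == 1

    def test_reversed_middle_splits_with_opposite_orientation(self):
        # genome-B order reversed for the middle four genes
        order = [0, 1, 5, 4, 3, 2, 6, 7]
        strands = ["+", "+", "-", "-", "-", "-", "+", "+"]
        a, b, links = toy_link_set(order, b_strands=strands)
        blocks, leftovers = chain_blocks(links, a, b, min_block_links=2)
        orientations = [blk.orientation for blk in blocks]
        assert len(blocks) >= 2
        assert 1 in orientations and -1 in orientations
        inverted = [blk for blk in blocks if blk.orientation == -1]
        assert {ln.gene_a.gene_id for blk in inverted for ln in blk.links} == {
            "gA_003", "gA_004", "gA_005", "gA_006"
        }

    def test_empty_input(self):
        a, b, _ = toy_link_set([0])
        assert chain_blocks([], a, b) == ([], [])

    def test_unsorted_links_rejected(self):
        a, b, links = toy_link_set(list(range(8)))
        with pytest.raises(ValueError, match="sorted"):
            chain_blocks(links[::-1], a, b)

    def test_every_link_in_exactly_one_block_or_leftover(self):
        for seed in (3, 4, 5):
            config = SimulationConfig(seed=seed, duplicate_fraction=0.05)
            sim = simulate_genome_pair(config)
            links, blocks, leftovers = run_synteny(sim, config)
            seen = [id(ln) for blk in blocks for ln in blk.links]
            seen += [id(ln) for ln in leftovers]
            assert sorted(seen) == sorted(id(ln) for ln in links)

    def test_invariant_under_genome_relabeling(self):
        config = SimulationConfig(seed=9)
        sim = simulate_genome_pair(config)
        links, blocks, _ = run_synteny(sim, config)
        swapped = sorted(
            (
                OrthologLink(ln.gene_b, ln.gene_a, ln.identity, ln.bitscore,
                             ln.orientation)
                for ln in links
            ),
            key=lambda ln: (ln.gene_a.chrom, ln.gene_a.start),
        )
        blocks_sw, _ = chain_blocks(swapped, sim.annot_b, sim.annot_a)
        def signature(blks, flip):
            out = set()
            for blk in blks:
                ids = frozenset(
                    (ln.gene_b.gene_id if flip else ln.gene_a.gene_id)
                    for ln in blk.links
                )
                out.add((ids, blk.orientation))
            return out
        assert signature(blocks, False) == signature(blocks_sw, True)


class TestCallInversions:
    def test_all_collinear_yields_no_calls(self):
        a, b, links = toy_link_set(list(range(10)))
        blocks, _ = chain_blocks(links, a, b)
        assert call_inversions(blocks) == []

    def test_fully_reversed_chromosome_is_its_own_dominant(self):
        n = 10
        order = list(range(n))[::-1]
        a, b, links = toy_link_set(order, b_strands=["-"] * n)
        blocks, _ = chain_blocks(links, a, b)
        assert len(blocks) == 1 and blocks[0].orientation == -1
        assert call_inversions(blocks) == []

    def test_planted_inversions_recovered(self):
        for seed in (2, 6, 10):
            config = SimulationConfig(seed=seed)
            sim = simulate_genome_pair(config)
            _, blocks, leftovers = run_synteny(sim, config)
            calls = call_inversions(blocks, leftover_links=leftovers)
            assert len(calls) == len(sim.truth.inversions) == 3
            for truth in sim.truth.inversions:
                assert any(set(truth.gene_ids) & c.gene_ids_a for c in calls)


class TestCallTranslocations:
    def test_perfect_correspondence_yields_no_calls(self):
        a, b, links = toy_link_set(list(range(10)))
        blocks, _ = chain_blocks(links, a, b)
        assert call_translocations(blocks) == []

    def test_small_stray_block_below_threshold_ignored(self):
        config = SimulationConfig(seed=3)
        sim = simulate_genome_pair(config)
        _, blocks, _ = run_synteny(sim, config)
        # a 2-link stray could never reach min_event_links=5
        calls = call_translocations(blocks, min_event_links=5)
        assert all(sum(len(b.links) for b in c.blocks) >= 5 for c in calls)

    def test_planted_translocations_recovered(self):
        for seed in (2, 6, 10):
            config = SimulationConfig(seed=seed)
            sim = simulate_genome_pair(config)
            _, blocks, _ = run_synteny(sim, config)
            calls = call_translocations(blocks)
            assert len(calls) == len(sim.truth.translocations) == 4
            for truth in sim.truth.translocations:
                assert any(set(truth.gene_ids) & c.gene_ids_a for c in calls)


class TestProjectInterval:
    def test_interval_between_adjacent_links(self):
        # partner genes at 100-200 and 500-600 on chrB
        a, b, links = toy_link_set([0, 1])
        links = [
            OrthologLink(ln.gene_a,
                         type(ln.gene_b)(ln.gene_b.gene_id, "B_chr1",
                                         100 if i == 0 else 500,
                                         200 if i == 0 else 600,
                                         "+", ln.gene_b.protein_id, 200),
                         ln.identity, ln.bitscore, ln.orientation)
            for i, ln in enumerate(links)
        ]
        interval = GenomicInterval("A_chr1", 2_000, 9_000)
        proj = project_interval(interval, links, genome="a")
        assert proj.projected is not None
        assert (proj.projected.start, proj.projected.end) == (200, 500)

    def test_interval_beyond_terminal_link_unresolved(self):
        a, b, links = toy_link_set(list(range(4)))
        before = GenomicInterval("A_chr1", 0, 50)  # left of the first gene? no
        # use an interval left of all links: genes start at 0, so shift links
        interval = GenomicInterval("A_chr1", 35_000, 40_000)  # right of last
        proj = project_interval(interval, links, genome="a")
        assert proj.projected is None and proj.flank_right is None

    def test_linked_gene_projection_contains_its_ortholog(self, default_sim):
        config, sim = default_sim
        links, _, _ = run_synteny(sim, config)
        for ln in links[10:40]:
            g = ln.gene_a
            proj = project_interval(
                GenomicInterval(g.chrom, g.start, g.end), links, genome="a"
            )
            if proj.projected is None:
                continue
            assert proj.projected.chrom == ln.gene_b.chrom
            assert proj.projected.start <= ln.gene_b.start
            assert proj.projected.end >= ln.gene_b.end

    def test_nested_intervals_project_consistently(self):
        a, b, links = toy_link_set(list(range(6)))
        outer = GenomicInterval("A_chr1", 12_000, 29_000)
        inner = GenomicInterval("A_chr1", 13_000, 28_000)
        p_out = project_interval(outer, links, genome="a")
        p_in = project_interval(inner, links, genome="a")
        if p_out.projected and p_in.projected and (
            p_out.flank_left is p_in.flank_left
            and p_out.flank_right is p_in.flank_right
        ):
            assert p_out.projected.start <= p_in.projected.start
            assert p_in.projected.end <= p_out.projected.end


class TestCentromereOrigin:
    def test_planted_insertions_classified_de_novo(self):
        for seed in (2, 6):
            config = SimulationConfig(seed=seed)
            sim = simulate_genome_pair(config)
            links, blocks, _ = run_synteny(sim, config)
            units_b = [u.interval for u in sim.truth.centromere_units_b]
            calls = classify_centromere_origin(
                units_b, sim.truth.centromere_units_a, links, blocks
            )
            assert [c.klass for c in calls] == ["de_novo_insertion"] * 7

    def test_overlapping_projection_is_corresponding(self):
        a, b, links = toy_link_set(list(range(10)))
        unit_b = GenomicInterval("B_chr1", 42_000, 48_000, name="u")
        # its projection on A spans the gap between genes 4 and 5
        unit_a = GenomicInterval("A_chr1", 42_000, 48_000, name="cenA")
        blocks, _ = chain_blocks(links, a, b)
        (call,) = classify_centromere_origin([unit_b], [unit_a], links, blocks)
        assert call.klass == "corresponding"

    def test_unit_beyond_terminal_link_unresolved(self):
        a, b, links = toy_link_set(list(range(10)))
        unit_b = GenomicInterval("B_chr1", 95_000, 99_000, name="tail")
        blocks, _ = chain_blocks(links, a, b)
        (call,) = classify_centromere_origin([unit_b], [], links, blocks)
        assert call.klass == "unresolved"
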