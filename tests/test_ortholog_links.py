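import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from centrosynteny.ortholog_links import (
    FilterThresholds,
    classify_single_copy,
    collapse_hits_per_gene_pair,
    build_links,
    filter_noise,
    links_from_hits,
)
from centrosynteny.synthetic_data import (
    SimulationConfig,
    hits_from_truth,
    simulate_genome_pair,
)

from conftest import make_annotation, make_hit, random_bipartite_instance
from oracles import brute_single_copy


class TestFilterNoise:
    @pytest.mark.parametrize("pident,align_len,kept", [
        (89.9, 200, False),   # identity below the noise cut-off
        (90.0, 150, True),    # both exactly at the boundary are kept
        (95.0, 149, False),   # length below the cut-off
        (90.0, 151, True),
        (89.9, 149, False),
    ])
    def test_boundary_cases(self, pident, align_len, kept):
        hits = [make_hit(pident=pident, align_len=align_len)]
        assert (len(filter_noise(hits)) == 1) is kept

    def test_empty_input(self):
        assert filter_noise([]) == []

    @given(st.lists(st.tuples(st.floats(0, 100), st.integers(1, 1000))))
    @settings(max_examples=50, deadline=None)
    def test_subset_order_and_idempotence(self, specs):
        hits = [make_hit(query=f"p{i}", pident=p, align_len=l)
                for i, (p, l) in enumerate(specs)]
        out = filter_noise(hits)
        assert all(h in hits for h in out)
        assert [h for h in hits if h in out] == out  # order preserved
        assert filter_noise(out) == out


class TestCollapse:
    def test_best_hsp_kept_per_pair(self):
        a = make_annotation("A", 1, prefix="gA")
        b = make_annotation("B", 2, prefix="gB")
        hits = [
            make_hit("gA_001.p", "gB_001.p", bitscore=300.0),
            make_hit("gA_001.p", "gB_001.p", bitscore=250.0),
            make_hit("gA_001.p", "gB_002.p", bitscore=100.0),
        ]
        out = collapse_hits_per_gene_pair(hits, a, b)
        assert len(out) == 2
        assert out[0].bitscore == 300.0

    def test_unknown_protein_policies(self):
        a = make_annotation("A", 1, prefix="gA")
        b = make_annotation("B", 1, prefix="gB")
        hits = [make_hit("mystery.p", "gB_001.p")]
        with pytest.raises(KeyError, match="mystery.p"):
            collapse_hits_per_gene_pair(hits, a, b, on_unknown="error")
        assert collapse_hits_per_gene_pair(hits, a, b, on_unknown="drop") == []

    def test_within_genome_hits_ignored(self):
        a = make_annotation("A", 2, prefix="gA")
        b = make_annotation("B", 2, prefix="gB")
        hits = [make_hit("gA_001.p", "gA_002.p"),  # within genome A
                make_hit("gA_001.p", "gB_001.p")]
        out = collapse_hits_per_gene_pair(hits, a, b)
        assert [h.subject_id for h in out] == ["gB_001.p"]

    def test_random_set_equals_group_by_max(self, rng):
        a = make_annotation("A", 10, prefix="gA")
        b = make_annotation("B", 10, prefix="gB")
        hits = [
            make_hit(
                f"gA_{int(rng.integers(1, 11)):03d}.p",
                f"gB_{int(rng.integers(1, 11)):03d}.p",
                pident=float(np.round(rng.uniform(90, 100), 1)),
                bitscore=float(rng.integers(100, 120)),  # force score ties
            )
            for _ in range(100)
        ]
        out = collapse_hits_per_gene_pair(hits, a, b)
        prot_a, prot_b = a.protein_to_gene(), b.protein_to_gene()
        groups = {}
        for h in hits:
            key = (prot_a[h.query_id].gene_id, prot_b[h.subject_id].gene_id)
            groups.setdefault(key, []).append(h)
        for h in out:
            key = (prot_a[h.query_id].gene_id, prot_b[h.subject_id].gene_id)
            expect = max(
                groups[key],
                key=lambda x: (x.bitscore, x.pident,
                               tuple(-ord(c) for c in x.subject_id)),
            )
            assert h == expect
        assert len(out) == len(groups)


class TestClassifySingleCopy:
    def test_reciprocal_identity_case(self):
        a = make_annotation("A", 1, prefix="gA")
        b = make_annotation("B", 1, prefix="gB")
        ab = [make_hit("gA_001.p", "gB_001.p")]
        ba = [make_hit("gB_001.p", "gA_001.p")]
        pairs = classify_single_copy(ab, ba, a, b)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("gA_001", "gB_001")]

    def test_multi_target_gene_excluded(self):
        a = make_annotation("A", 1, prefix="gA")
        b = make_annotation("B", 2, prefix="gB")
        ab = [make_hit("gA_001.p", "gB_001.p"), make_hit("gA_001.p", "gB_002.p")]
        ba = [make_hit("gB_001.p", "gA_001.p")]
        assert classify_single_copy(ab, ba, a, b) == []

    def test_one_way_ignores_back_direction(self):
        a = make_annotation("A", 1, prefix="gA")
        b = make_annotation("B", 2, prefix="gB")
        ab = [make_hit("gA_001.p", "gB_001.p")]
        ba = [make_hit("gB_001.p", "gA_001.p"), make_hit("gB_002.p", "gA_001.p")]
        assert classify_single_copy(ab, ba, a, b, mode="reciprocal") != []
        one = classify_single_copy(ab, ba, a, b, mode="one_way")
        assert [(p.gene_a, p.gene_b) for p in one] == [("gA_001", "gB_001")]

    @pytest.mark.parametrize("mode", ["reciprocal", "one_way"])
    def test_random_graphs_match_brute_force(self, mode):
        rng = np.random.default_rng(99)
        for _ in range(60):
            a, b, hits_ab, hits_ba, ab_edges, ba_edges = random_bipartite_instance(rng)
            got = {(p.gene_a, p.gene_b)
                   for p in classify_single_copy(hits_ab, hits_ba, a, b, mode=mode)}
            assert got == brute_single_copy(ab_edges, ba_edges, mode=mode)

    def test_reciprocal_symmetric_under_genome_swap(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            a, b, hits_ab, hits_ba, *_ = random_bipartite_instance(rng)
            fwd = {(p.gene_a, p.gene_b)
                   for p in classify_single_copy(hits_ab, hits_ba, a, b)}
            rev = {(p.gene_b, p.gene_a)
                   for p in classify_single_copy(hits_ba, hits_ab, b, a)}
            assert fwd == rev


class TestBuildLinks:
    def test_orientation_from_strands(self):
        a = make_annotation("A", 2, prefix="gA", strands=["+", "+"])
        b = make_annotation("B", 2, prefix="gB", strands=["+", "-"])
        ab = [make_hit("gA_001.p", "gB_001.p"), make_hit("gA_002.p", "gB_002.p")]
        ba = [make_hit("gB_001.p", "gA_001.p"), make_hit("gB_002.p", "gA_002.p")]
        links = links_from_hits(ab, ba, a, b)
        assert [ln.orientation for ln in links] == [1, -1]

    def test_unknown_gene_id_named_in_error(self):
        a = make_annotation("A", 1, prefix="gA")
        b = make_annotation("B", 1, prefix="gB")
        from centrosynteny.ortholog_links import OrthologPair

        with pytest.raises(KeyError, match="ghost"):
            build_links([OrthologPair("ghost", "gB_001", 95.0, 100.0)], a, b)

    def test_simulated_link_coordinates_match_truth(self, default_sim):
        config, sim = default_sim
        ab, ba = hits_from_truth(sim, config)
        links = links_from_hits(ab, ba, sim.annot_a, sim.annot_b)
        by_a = sim.annot_a.by_gene_id()
        by_b = sim.annot_b.by_gene_id()
        for ln in links:
            assert ln.gene_a == by_a[ln.gene_a.gene_id]
            assert ln.gene_b == by_b[ln.gene_b.gene_id]


class TestPlantedRecovery:
    def test_clean_simulation_recovers_all_pairs(self, default_sim):
        config, sim = default_sim
        ab, ba = hits_from_truth(sim, config)
        links = links_from_hits(ab, ba, sim.annot_a, sim.annot_b)
        got = {(ln.gene_a.gene_id, ln.gene_b.gene_id) for ln in links}
        assert got == set(map(tuple, sim.truth.ortholog_pairs))

    def test_duplicate_removes_exactly_its_gene(self):
        base = SimulationConfig(seed=11, n_chromosomes=2,
                                genes_per_chromosome=30, n_inversions=0,
                                n_translocations=0, centromere_insertions_b=0,
                                centromere_intervals_a=0)
        dup = SimulationConfig(**{**base.__dict__, "duplicate_fraction": 0.1})
        sim_d = simulate_genome_pair(dup)
        assert len(sim_d.truth.duplicated_genes) == 6
        ab, ba = hits_from_truth(sim_d, dup)
        links = links_from_hits(ab, ba, sim_d.annot_a, sim_d.annot_b)
        got_a = {ln.gene_a.gene_id for ln in links}
        all_a = {g.gene_id for g in sim_d.annot_a.genes}
        assert all_a - got_a == set(sim_d.truth.duplicated_genes)
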