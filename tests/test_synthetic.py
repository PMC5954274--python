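import numpy as np
import pytest

from granulome import SignedBlockGenome, dcj_distance
from granulome.blocks import build_three_way
from granulome.model import genome_from_table
from granulome.resolution import ResolutionSchedule, sweep
from granulome.synthetic import (
    BranchConfig,
    SimulationConfig,
    emit_pairwise_tables,
    evolve,
    generate_ancestor,
    random_genome,
    simulate,
)


class TestGenerateAncestor:
    def test_one_block_per_chromosome(self):
        cfg = SimulationConfig(n_blocks=7, n_chromosomes=7, seed=0)
        g, colours, counts = generate_ancestor(cfg)
        assert g.n_chromosomes == 7
        assert all(len(c) == 1 for c in g.chromosomes)
        assert len(set(colours.values())) == 7

    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(seed=42)
        assert generate_ancestor(cfg) == generate_ancestor(cfg)

    def test_gene_counts_within_bounds(self):
        cfg = SimulationConfig(seed=3)
        _, _, counts = generate_ancestor(cfg)
        assert all(cfg.gene_count_min <= v <= cfg.gene_count_max for v in counts.values())


class TestEvolve:
    def test_zero_operations(self, rng):
        g = random_genome(10, 2, rng)
        out, scen = evolve(g, BranchConfig(n_ops=0), rng)
        assert out.chromosomes == g.chromosomes and scen == []

    def test_single_reversal_distance_one(self, rng):
        g = SignedBlockGenome("g", ((1, 2, 3, 4, 5),))
        branch = BranchConfig(n_ops=1, reversal=1.0, translocation=0, fusion=0, fission=0)
        out, scen = evolve(g, branch, rng, name="h")
        assert len(scen) == 1
        assert dcj_distance(g, out) == 1

    def test_distance_bounded_by_op_count(self, rng):
        g = random_genome(20, 4, rng)
        for k in (2, 5, 9):
            out, scen = evolve(g, BranchConfig(n_ops=k), rng, name="h")
            assert len(scen) == k
            assert dcj_distance(g, out) <= k

    def test_no_circular_products(self, rng):
        g = random_genome(15, 3, rng)
        out, _ = evolve(g, BranchConfig(n_ops=12), rng, name="h")
        # SignedBlockGenome construction itself rejects malformed output;
        # content must be conserved
        assert out.blocks() == g.blocks()


class TestEmitPairwiseTables:
    def test_identical_leaves_one_block_per_chromosome(self):
        g = SignedBlockGenome("a", ((1, 2, 3), (4, 5)))
        h = SignedBlockGenome("b", g.chromosomes)
        counts = {b: 20 for b in range(1, 6)}
        colours = {1: 1, 2: 1, 3: 1, 4: 2, 5: 2}
        t = emit_pairwise_tables(g, h, counts, colours, dict(counts), dict(counts))
        assert len(t) == 2
        assert {r.genes["a"] for r in t.records} == {60, 40}

    def test_reversal_splits_runs(self):
        g = SignedBlockGenome("a", ((1, 2, 3),))
        h = SignedBlockGenome("b", ((1, -2, 3),))
        counts = {1: 10, 2: 10, 3: 10}
        colours = {1: 1, 2: 1, 3: 1}
        t = emit_pairwise_tables(g, h, counts, colours, dict(counts), dict(counts))
        assert len(t) == 3
        strands = {r.block_id: r.placements["b"].strand for r in t.records}
        assert "-" in strands.values()

    def test_erosion_zero_keeps_exact_counts(self):
        g = SignedBlockGenome("a", ((1, 2),))
        h = SignedBlockGenome("b", ((1, -2),))  # keep blocks separate
        counts = {1: 13, 2: 17}
        colours = {1: 1, 2: 1}
        t = emit_pairwise_tables(g, h, counts, colours, dict(counts), dict(counts))
        assert {r.genes["a"] for r in t.records} == {13, 17}

    def test_colour_change_splits_runs(self):
        g = SignedBlockGenome("a", ((1, 2),))
        h = SignedBlockGenome("b", ((1, 2),))
        counts = {1: 10, 2: 10}
        t = emit_pairwise_tables(g, h, counts, {1: 1, 2: 2}, dict(counts), dict(counts))
        assert len(t) == 2


class TestSimulate:
    def test_deterministic(self):
        cfg = SimulationConfig(seed=5)
        s1, s2 = simulate(cfg), simulate(cfg)
        assert s1.truth.leaves == s2.truth.leaves
        for k in s1.tables:
            assert [r.placements for r in s1.tables[k].records] == [
                r.placements for r in s2.tables[k].records
            ]

    def test_scenarios_have_configured_lengths(self):
        sim = simulate(SimulationConfig(seed=8))
        for name, branch in sim.config.branches.items():
            assert len(sim.truth.scenarios[name]) == branch.n_ops
            assert dcj_distance(sim.truth.ancestor, sim.truth.leaves[name]) <= branch.n_ops

    def test_content_shared_across_genomes(self):
        sim = simulate(SimulationConfig(seed=8))
        blocks = sim.truth.ancestor.blocks()
        for leaf in sim.truth.leaves.values():
            assert leaf.blocks() == blocks

    def test_end_to_end_distance_recovery_clean(self):
        """Without erosion or fragmentation, the three-way construction must
        reproduce the true pairwise distances exactly (blocks merge only
        where all genomes agree, which leaves distances unchanged)."""
        cfg = SimulationConfig(seed=13, erosion_mean=0.0, pivot_break_prob=0.0)
        sim = simulate(cfg)
        tw = build_three_way(*(sim.tables[k] for k in sim.tables), cfg.pivot)
        ids = tw.block_index()
        gs = {g: genome_from_table(tw, g, block_ids=ids) for g in tw.genome_names}
        for (x, y), d_true in sim.truth.distances.items():
            assert dcj_distance(gs[x], gs[y]) == d_true

    def test_median_lower_bound_vs_true_ancestor(self):
        from granulome import dcj_median

        sim = simulate(SimulationConfig(seed=21, erosion_mean=0.0, pivot_break_prob=0.0))
        leaves = [sim.truth.leaves[n] for n in sim.config.genome_names]
        res = dcj_median(*leaves, enumerate_all=False)
        true_sum = sum(dcj_distance(sim.truth.ancestor, l) for l in leaves)
        assert res.total_score <= true_sum
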