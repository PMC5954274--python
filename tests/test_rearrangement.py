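import itertools

import pytest

from granulome import (
    SignedBlockGenome,
    breakpoint_distance,
    dcj_distance,
    normalized_total,
    reuse_rate,
    sort_scenario,
)
from granulome.model import ContentMismatchError, UndefinedValueError
from granulome.synthetic import random_genome

import oracles


def G(*chroms, name="g"):
    return SignedBlockGenome(name, tuple(tuple(c) for c in chroms))


class TestDCJDistance:
    @pytest.mark.parametrize(
        "a,b,d",
        [
            (G([1, 2, 3]), G([1, 2, 3]), 0),
            (G([1, 2, 3]), G([1, -2, 3]), 1),
            (G([1, 2, 3]), G([-3, -2, -1]), 0),   # whole-chromosome flip
            (G([1, 2], [3]), G([1, 2, 3]), 1),    # fusion
            (G([1, 2, 3]), G([2, 1, 3]), 2),      # block interchange
        ],
    )
    def test_examples(self, a, b, d):
        assert dcj_distance(a, b) == d
        assert dcj_distance(b, a) == d

    def test_content_mismatch(self):
        with pytest.raises(ContentMismatchError, match="4"):
            dcj_distance(G([1, 2, 3]), G([1, 2, 4]))

    def test_bfs_oracle_random_pairs(self, rng):
        genomes = oracles.all_linear_genomes(4)
        idx = rng.integers(0, len(genomes), size=(30, 2))
        for i, j in idx:
            a, b = genomes[i], genomes[j]
            assert dcj_distance(a, b) == oracles.bfs_dcj_distance(a, b)

    def test_metric_on_random_triples(self, rng):
        for _ in range(40):
            a = random_genome(8, 2, rng, "a")
            b = random_genome(8, 2, rng, "b")
            c = random_genome(8, 2, rng, "c")
            dab, dac, dbc = dcj_distance(a, b), dcj_distance(a, c), dcj_distance(b, c)
            assert dab == dcj_distance(b, a)
            assert dab >= 0 and (dab > 0 or a.canonical() == b.canonical("a"))
            assert dab <= dac + dbc
            assert dac <= dab + dbc


class TestBreakpointDistance:
    @pytest.mark.parametrize(
        "a,b,bp",
        [
            (G([1, 2, 3]), G([1, 2, 3]), 0.0),
            (G([1, 2, 3]), G([1, -2, 3]), 2.0),
        ],
    )
    def test_examples(self, a, b, bp):
        assert breakpoint_distance(a, b) == bp
        assert breakpoint_distance(b, a) == bp

    def test_set_difference_oracle(self, rng):
        for _ in range(40):
            a = random_genome(9, 3, rng, "a")
            b = random_genome(9, 3, rng, "b")
            # independent computation straight from adjacency/telomere sets
            ma, mb = oracles.matching_of(a), oracles.matching_of(b)
            tel_a = {e for e in oracles.extremities(range(1, 10)) if e not in {x for p in ma for x in p}}
            tel_b = {e for e in oracles.extremities(range(1, 10)) if e not in {x for p in mb for x in p}}
            expected = 9 - len(ma & mb) - len(tel_a & tel_b) / 2
            assert breakpoint_distance(a, b) == expected

    def test_bounds_vs_dcj(self, rng):
        for _ in range(60):
            a = random_genome(10, 2, rng, "a")
            b = random_genome(10, 2, rng, "b")
            d, bp = dcj_distance(a, b), breakpoint_distance(a, b)
            assert d <= bp <= 2 * d or (d == 0 and bp == 0)


class TestReuseRate:
    def test_identical_genomes_undefined(self):
        with pytest.raises(UndefinedValueError):
            reuse_rate(G([1, 2, 3]), G([1, 2, 3]))

    def test_single_reversal_is_one(self):
        assert reuse_rate(G([1, 2, 3]), G([1, -2, 3])) == 1.0

    def test_bounds_on_random_pairs(self, rng):
        for _ in range(50):
            a = random_genome(12, 3, rng, "a")
            b = random_genome(12, 3, rng, "b")
            if breakpoint_distance(a, b) == 0:
                continue
            assert 1.0 <= reuse_rate(a, b) <= 2.0


class TestNormalizedTotal:
    def test_arithmetic(self):
        assert normalized_total(0, 100) == 0.0
        assert normalized_total(50, 200) == 0.25

    def test_zero_blocks_rejected(self):
        with pytest.raises(UndefinedValueError):
            normalized_total(5, 0)


class TestSortScenario:
    def test_identical_genomes_empty(self):
        for mode in ("translocations-first", "reversals-first"):
            assert len(sort_scenario(G([1, 2, 3]), G([1, 2, 3]), mode)) == 0

    def test_single_reversal(self):
        for mode in ("translocations-first", "reversals-first"):
            scen = sort_scenario(G([1, 2, 3]), G([1, -2, 3]), mode)
            assert [op.kind for op in scen.operations] == ["reversal"]

    def test_block_interchange_uses_excision_pair(self):
        scen = sort_scenario(G([1, 2, 3]), G([2, 1, 3]))
        assert [op.kind for op in scen.operations] == ["excision", "reintegration"]
        assert len(scen) == dcj_distance(G([1, 2, 3]), G([2, 1, 3]))

    def test_length_equals_distance_random(self, rng):
        for _ in range(25):
            a = random_genome(10, 3, rng, "a")
            b = random_genome(10, 3, rng, "b")
            d = dcj_distance(a, b)
            for mode in ("translocations-first", "reversals-first"):
                assert len(sort_scenario(a, b, mode)) == d

    def test_counts_bracket_exhaustive_optimum(self, rng):
        """Greedy per-mode counts must lie within the min/max achievable by
        any optimal scenario (exhaustive enumeration, small genomes)."""
        checked = 0
        genomes = oracles.all_linear_genomes(4)
        while checked < 6:
            i, j = rng.integers(0, len(genomes), size=2)
            a, b = genomes[i], genomes[j].rename("b")
            if dcj_distance(a, b) == 0:
                continue
            bounds = oracles.optimal_scenario_bounds(a, b)
            for mode in ("translocations-first", "reversals-first"):
                scen = sort_scenario(a, b, mode)
                for kind in ("translocation", "reversal"):
                    lo, hi = bounds[kind]
                    assert lo <= scen.count(kind) <= hi
            checked += 1

    def test_priority_ordering(self, rng):
        for _ in range(20):
            a = random_genome(8, 3, rng, "a")
            b = random_genome(8, 3, rng, "b")
            tf = sort_scenario(a, b, "translocations-first")
            rf = sort_scenario(a, b, "reversals-first")
            assert tf.count("translocation") >= rf.count("translocation")
            assert rf.count("reversal") >= tf.count("reversal")
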