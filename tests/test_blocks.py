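import pytest

from granulome.blocks import build_three_way, filter_informative_scaffolds, map_subinterval
from conftest import rec, table


def pairwise(records, names):
    return table(records, names)


class TestMapSubinterval:
    def test_identity_scale_is_exact(self):
        assert map_subinterval((1, 100), (1, 100), (1, 40)) == (1, 40)
        assert map_subinterval((1, 100), (1, 100), (61, 100)) == (61, 100)

    def test_reverse_orientation(self):
        assert map_subinterval((1, 100), (201, 300), (1, 40), reverse=True) == (261, 300)

    def test_disjoint_subintervals_stay_disjoint(self):
        # halving scale: boundaries must not collide after rounding
        parent = (1, 99)
        dst = (1, 50)
        a = map_subinterval(parent, dst, (1, 33))
        b = map_subinterval(parent, dst, (34, 66))
        c = map_subinterval(parent, dst, (67, 99))
        assert a[1] < b[0] and b[1] < c[0]
        for lo, hi in (a, b, c):
            assert dst[0] <= lo <= hi <= dst[1]

    def test_outside_parent_rejected(self):
        with pytest.raises(ValueError):
            map_subinterval((10, 20), (1, 11), (5, 15))


class TestFilterInformativeScaffolds:
    def test_single_block_scaffold_dropped(self, toy_threeway):
        out = filter_informative_scaffolds(toy_threeway, "p")
        # scaffold s2 has one block: uninformative; s1 witnesses b3's flip
        scaffolds = {r.placements["p"].scaffold for r in out.records}
        assert scaffolds == {"s1"}

    def test_fully_conserved_scaffold_dropped(self):
        recs = [
            rec("b1", 1, p=("s1", 1, 10, "+", 9), a=("x", 1, 10, "+", 9)),
            rec("b2", 1, p=("s1", 12, 20, "+", 8), a=("x", 12, 20, "+", 8)),
        ]
        out = filter_informative_scaffolds(pairwise(recs, ("p", "a")), "p")
        assert len(out) == 0

    def test_split_counterparts_retained(self):
        # adjacent on the pivot but on different chromosomes of the other genome
        recs = [
            rec("b1", 1, p=("s1", 1, 10, "+", 9), a=("x1", 1, 10, "+", 9)),
            rec("b2", 1, p=("s1", 12, 20, "+", 8), a=("x2", 1, 9, "+", 8)),
        ]
        out = filter_informative_scaffolds(pairwise(recs, ("p", "a")), "p")
        assert len(out) == 2

    def test_orientation_flip_is_informative(self):
        recs = [
            rec("b1", 1, p=("s1", 1, 10, "+", 9), a=("x", 1, 10, "+", 9)),
            rec("b2", 1, p=("s1", 12, 20, "+", 8), a=("x", 12, 20, "-", 8)),
        ]
        out = filter_informative_scaffolds(pairwise(recs, ("p", "a")), "p")
        assert len(out) == 2

    def test_unknown_pivot_rejected(self, toy_threeway):
        with pytest.raises(ValueError):
            filter_informative_scaffolds(toy_threeway, "nope")


class TestBuildThreeWay:
    def test_exact_coincidence(self):
        ab = pairwise([rec("x1", 3, a=("ca", 1, 100, "+", 95), p=("s1", 1, 100, "+", 90))], ("a", "p"))
        bc = pairwise([rec("y1", 3, p=("s1", 1, 100, "+", 92), c=("cc", 11, 110, "+", 96))], ("p", "c"))
        out = build_three_way(ab, bc, None, "p")
        assert len(out) == 1
        r = out.records[0]
        assert r.placements["p"].start == 1 and r.placements["p"].end == 100
        assert r.placements["a"] .start == 1 and r.placements["a"].end == 100
        assert r.placements["c"].start == 11 and r.placements["c"].end == 110
        assert r.colour == 3

    def test_partial_overlap_splits_proportionally(self):
        ab = pairwise([rec("x1", 1, a=("ca", 1, 100, "+", 100), p=("s1", 1, 100, "+", 100))], ("a", "p"))
        bc = pairwise(
            [
                rec("y1", 1, p=("s1", 1, 40, "+", 40), c=("cc", 1, 40, "+", 40)),
                rec("y2", 1, p=("s1", 61, 100, "+", 40), c=("cc", 61, 100, "+", 40)),
            ],
            ("p", "c"),
        )
        out = build_three_way(ab, bc, None, "p")
        spans_p = sorted((r.placements["p"].start, r.placements["p"].end) for r in out.records)
        spans_a = sorted((r.placements["a"].start, r.placements["a"].end) for r in out.records)
        assert spans_p == [(1, 40), (61, 100)]
        assert spans_a == [(1, 40), (61, 100)]  # same-size parent: exact split

    def test_disjoint_tables_give_empty_result(self):
        ab = pairwise([rec("x1", 1, a=("ca", 1, 50, "+", 45), p=("s1", 1, 50, "+", 45))], ("a", "p"))
        bc = pairwise([rec("y1", 1, p=("s1", 100, 150, "+", 45), c=("cc", 1, 50, "+", 45))], ("p", "c"))
        assert len(build_three_way(ab, bc, None, "p")) == 0

    def test_colour_conflict_skipped(self, caplog):
        ab = pairwise([rec("x1", 1, a=("ca", 1, 50, "+", 45), p=("s1", 1, 50, "+", 45))], ("a", "p"))
        bc = pairwise([rec("y1", 2, p=("s1", 1, 50, "+", 45), c=("cc", 1, 50, "+", 45))], ("p", "c"))
        import logging

        with caplog.at_level(logging.WARNING):
            out = build_three_way(ab, bc, None, "p")
        assert len(out) == 0
        assert any("colour conflict" in m for m in caplog.messages)

    def test_pivot_intervals_disjoint_and_contained(self, rng):
        # random overlapping pairwise tables: output pivot intervals must be
        # pairwise disjoint and contained in one parent interval of each table
        ab_recs, bc_recs = [], []
        cursor = 1
        for i in range(6):
            span = int(rng.integers(30, 90))
            ab_recs.append(rec(f"x{i}", 1, a=("ca", cursor, cursor + span - 1, "+", span),
                               p=("s1", cursor, cursor + span - 1, "+", span)))
            cursor += span
        cursor = 1
        for i in range(9):
            span = int(rng.integers(20, 60))
            bc_recs.append(rec(f"y{i}", 1, p=("s1", cursor, cursor + span - 1, "+", span),
                               c=("cc", cursor, cursor + span - 1, "+", span)))
            cursor += span
        out = build_three_way(pairwise(ab_recs, ("a", "p")), pairwise(bc_recs, ("p", "c")), None, "p")
        spans = sorted((r.placements["p"].start, r.placements["p"].end) for r in out.records)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2
        for r in out.records:
            p = r.placements["p"]
            assert any(x.placements["p"].start <= p.start and p.end <= x.placements["p"].end for x in ab_recs)
            assert any(y.placements["p"].start <= p.start and p.end <= y.placements["p"].end for y in bc_recs)

    def test_idempotent_on_own_projections(self):
        # re-intersecting a clean three-way output with itself changes nothing
        ab = pairwise(
            [
                rec("x1", 1, a=("ca", 1, 60, "+", 60), p=("s1", 1, 60, "+", 60)),
                rec("x2", 1, a=("ca", 61, 120, "+", 60), p=("s1", 61, 120, "+", 60)),
            ],
            ("a", "p"),
        )
        bc = pairwise(
            [
                rec("y1", 1, p=("s1", 1, 60, "+", 60), c=("cc", 1, 60, "+", 60)),
                rec("y2", 1, p=("s1", 61, 120, "+", 60), c=("cc", 61, 120, "+", 60)),
            ],
            ("p", "c"),
        )
        once = build_three_way(ab, bc, None, "p")
        ab2 = table([rec(r.block_id, r.colour,
                         a=(r.placements["a"].scaffold, r.placements["a"].start, r.placements["a"].end, r.placements["a"].strand, r.genes["a"]),
                         p=(r.placements["p"].scaffold, r.placements["p"].start, r.placements["p"].end, r.placements["p"].strand, r.genes["p"]))
                     for r in once.records], ("a", "p"))
        bc2 = table([rec(r.block_id, r.colour,
                         p=(r.placements["p"].scaffold, r.placements["p"].start, r.placements["p"].end, r.placements["p"].strand, r.genes["p"]),
                         c=(r.placements["c"].scaffold, r.placements["c"].start, r.placements["c"].end, r.placements["c"].strand, r.genes["c"]))
                     for r in once.records], ("p", "c"))
        twice = build_three_way(ab2, bc2, None, "p")
        assert [(r.placements["p"].start, r.placements["p"].end) for r in twice.records] == \
               [(r.placements["p"].start, r.placements["p"].end) for r in once.records]
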