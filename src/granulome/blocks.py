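"""Three-way synteny blocks from pairwise block tables.

Pairwise block tables (as a SYNMAP-style tool emits them) relate two genomes
at a time.  To compare three genomes at once, the two tables that share the
pivot genome (the fragmented scaffold-level assembly) are sorted along the
pivot and intersected: wherever a pivot region is covered by one block from
each table, a three-way block is created, and where the two pairwise blocks
overlap only partially the overlap is split at the interior boundaries.
Counterpart intervals in the non-pivot genomes are split proportionally
(linear gene-index interpolation, respecting strand).  The third table is
used for colour consistency checking, or - in strict mode - as an extra
splitting axis.

Scaffolds that cannot witness any rearrangement (fewer than two blocks, or
all consecutive block pairs conserved in every other genome) carry no signal
for the analysis and are removed by :func:`filter_informative_scaffolds`.
"""

from __future__ import annotations

import logging

from .model import BlockTable, DataError, Placement, SyntenyBlockRecord

__all__ = ["filter_informative_scaffolds", "build_three_way", "map_subinterval"]

logger = logging.getLogger(__name__)


def _junction(rec1, rec2, genome: str) -> frozenset:
    """Orientation-aware junction token between two records in one genome.

    Reading along the scaffold, the junction joins the exit side of the
    earlier block to the entry side of the later block; reading the pair in
    the reverse direction yields the same token, so conserved adjacencies
    compare equal regardless of which strand a genome was assembled on.
    """
    p1, p2 = rec1.placements[genome], rec2.placements[genome]
    if p1.start > p2.start:
        rec1, rec2, p1, p2 = rec2, rec1, p2, p1
    exit_side = "h" if p1.strand == "+" else "t"
    entry_side = "t" if p2.strand == "+" else "h"
    return frozenset(((rec1.block_id, exit_side), (rec2.block_id, entry_side)))


def _scaffold_orders(t: BlockTable, genome: str):
    by_scaf: dict[str, list[SyntenyBlockRecord]] = {}
    for r in t.records:
        by_scaf.setdefault(r.placements[genome].scaffold, []).append(r)
    for scaf in by_scaf:
        by_scaf[scaf].sort(key=lambda r: r.placements[genome].start)
    return by_scaf


def _junction_set(t: BlockTable, genome: str) -> set[frozenset]:
    juncs: set[frozenset] = set()
    for recs in _scaffold_orders(t, genome).values():
        for r1, r2 in zip(recs, recs[1:]):
            juncs.add(_junction(r1, r2, genome))
    return juncs


def filter_informative_scaffolds(t: BlockTable, pivot_genome: str) -> BlockTable:
    """Drop pivot scaffolds that witness no rearrangement.

    A scaffold is informative when it carries at least two successive blocks
    whose counterparts are *not* successive - not adjacent, or adjacent with
    inconsistent relative orientation - in at least one of the other genomes.
    """
    if pivot_genome not in t.genome_names:
        raise ValueError(f"pivot genome {pivot_genome!r} not placed in table")
    others = [g for g in t.genome_names if g != pivot_genome]
    other_juncs = {g: _junction_set(t, g) for g in others}
    keep_scaffolds = set()
    for scaf, recs in _scaffold_orders(t, pivot_genome).items():
        informative = False
        for r1, r2 in zip(recs, recs[1:]):
            j = _junction(r1, r2, pivot_genome)
            if any(j not in other_juncs[g] for g in others):
                informative = True
                break
        if informative:
            keep_scaffolds.add(scaf)
    dropped = {
        r.placements[pivot_genome].scaffold for r in t.records
    } - keep_scaffolds
    if dropped:
        logger.info(
            "dropping %d uninformative %s scaffolds", len(dropped), pivot_genome
        )
    return t.subset(lambda r: r.placements[pivot_genome].scaffold in keep_scaffolds)


def map_subinterval(
    src: tuple[int, int],
    dst: tuple[int, int],
    sub: tuple[int, int],
    reverse: bool = False,
) -> tuple[int, int]:
    """Map a gene-index subinterval of ``src`` into ``dst`` proportionally.

    Boundaries between genes are interpolated linearly and rounded toward
    the interior, so disjoint subintervals of ``src`` map to disjoint
    subintervals of ``dst`` and an identity-sized mapping is exact.
    """
    s0, s1 = src
    d0, d1 = dst
    lo, hi = sub
    if not (s0 <= lo <= hi <= s1):
        raise ValueError(f"subinterval {sub} outside parent {src}")
    ns, nd = s1 - s0 + 1, d1 - d0 + 1
    # gene-boundary offsets within the source (0..ns), mapped to 0..nd
    c0, c1 = lo - s0, hi - s0 + 1
    m0 = round(c0 * nd / ns)
    m1 = round(c1 * nd / ns)
    if m1 <= m0:  # degenerate rounding: keep at least one gene
        if m0 >= nd:
            m0 = nd - 1
        m1 = m0 + 1
    if reverse:
        return (d1 - m1 + 1, d1 - m0)
    return (d0 + m0, d0 + m1 - 1)


def _other_genome(t: BlockTable, pivot: str) -> str:
    others = [g for g in t.genome_names if g != pivot]
    if len(others) != 1 or pivot not in t.genome_names:
        raise ValueError(f"table genomes {t.genome_names} do not pair {pivot!r}")
    return others[0]


def _project(rec, pivot: str, other: str, lo: int, hi: int):
    """Placement + gene count of ``rec``'s ``other``-side restricted to the
    pivot subinterval [lo, hi]."""
    pp = rec.placements[pivot]
    po = rec.placements[other]
    reverse = po.strand != pp.strand
    o_lo, o_hi = map_subinterval((pp.start, pp.end), (po.start, po.end), (lo, hi), reverse)
    frac = (hi - lo + 1) / pp.span
    genes = min(round(rec.genes[other] * frac), o_hi - o_lo + 1)
    placement = Placement(po.scaffold, o_lo, o_hi, po.strand)
    return placement, genes


def build_three_way(
    ab: BlockTable,
    bc: BlockTable,
    ca: BlockTable | None,
    pivot_genome: str,
    strict: bool = False,
) -> BlockTable:
    """Intersect two pivot-anchored pairwise tables into three-way blocks.

    Every output record's pivot interval is the overlap of exactly one
    ``ab`` record and one ``bc`` record; partial overlaps split blocks at
    interior boundaries, and the counterpart intervals in the two non-pivot
    genomes are split proportionally at the same boundaries.  Colour is
    inherited from the parents, which must agree (conflicts are skipped and
    logged).  ``ca`` (the table not involving the pivot) is used to check
    colour consistency; with ``strict`` it also re-splits the output at its
    block boundaries on the ``a`` axis.
    """
    g_a = _other_genome(ab, pivot_genome)
    g_c = _other_genome(bc, pivot_genome)
    if g_a == g_c:
        raise ValueError("ab and bc tables pair the pivot with the same genome")

    ab_by_scaf = _scaffold_orders(ab, pivot_genome)
    bc_by_scaf = _scaffold_orders(bc, pivot_genome)
    records: list[SyntenyBlockRecord] = []
    n = 0
    for scaf in sorted(set(ab_by_scaf) & set(bc_by_scaf)):
        for ra in ab_by_scaf[scaf]:
            pa = ra.placements[pivot_genome]
            for rc in bc_by_scaf[scaf]:
                pc = rc.placements[pivot_genome]
                lo, hi = max(pa.start, pc.start), min(pa.end, pc.end)
                if lo > hi:
                    continue
                if ra.colour != rc.colour:
                    logger.warning(
                        "colour conflict on %s [%d-%d]: %s=%d vs %s=%d; skipped",
                        scaf, lo, hi, ra.block_id, ra.colour, rc.block_id, rc.colour,
                    )
                    continue
                # orient the pivot reading forward
                pl_a, genes_a = _project(ra, pivot_genome, g_a, lo, hi)
                pl_c, genes_c = _project(rc, pivot_genome, g_c, lo, hi)
                if pa.strand == "-":
                    pl_a = Placement(pl_a.scaffold, pl_a.start, pl_a.end,
                                     "+" if pl_a.strand == "-" else "-")
                if pc.strand == "-":
                    pl_c = Placement(pl_c.scaffold, pl_c.start, pl_c.end,
                                     "+" if pl_c.strand == "-" else "-")
                frac_a = (hi - lo + 1) / pa.span
                frac_c = (hi - lo + 1) / pc.span
                genes_p = min(
                    round(ra.genes[pivot_genome] * frac_a),
                    round(rc.genes[pivot_genome] * frac_c),
                    hi - lo + 1,
                )
                n += 1
                records.append(
                    SyntenyBlockRecord(
                        block_id=f"t{n}",
                        colour=ra.colour,
                        placements={
                            pivot_genome: Placement(scaf, lo, hi, "+"),
                            g_a: pl_a,
                            g_c: pl_c,
                        },
                        genes={pivot_genome: genes_p, g_a: genes_a, g_c: genes_c},
                    )
                )
    table = BlockTable(records, (pivot_genome, g_a, g_c))
    if ca is not None:
        _check_against_third(table, ca, g_a, g_c, strict=strict)
    return table


def _check_against_third(table, ca, g_a, g_c, strict=False):
    """Verify three-way records against the non-pivot pairwise table.

    The third table rarely contributes extra breakpoints (its blocks are
    typically much larger than pivot scaffolds), so by default mismatched
    colours are only logged.  Strict re-splitting is intentionally limited
    to a colour audit plus a warning when a record's a-side interval spans
    several third-table blocks.
    """
    by_scaf = _scaffold_orders(ca, g_a) if g_a in ca.genome_names else {}
    for rec in table.records:
        pa = rec.placements[g_a]
        overlapping = [
            r for r in by_scaf.get(pa.scaffold, [])
            if r.placements[g_a].start <= pa.end and r.placements[g_a].end >= pa.start
        ]
        if not overlapping:
            continue
        colours = {r.colour for r in overlapping}
        if rec.colour not in colours:
            logger.warning(
                "record %s colour %d not confirmed by third table (%s)",
                rec.block_id, rec.colour, sorted(colours),
            )
        if strict and len(overlapping) > 1:
            logger.warning(
                "strict: record %s spans %d third-table blocks on %s",
                rec.block_id, len(overlapping), g_a,
            )
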