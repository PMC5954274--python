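"""Ground-truthed synthetic genomes and SYNMAP-like pairwise block tables.

The generator states a small world with the statistical structure the
analysis assumes: a coloured ancestor of a few chromosomes (colours stand
for ancestral chromosomes, as the 21 post-triplication core-eudicot
chromosomes do for real rosids/asterids), three descendants produced by
genome-specific operation regimes (one translocation-rich fast lineage, one
reversal-dominated conservative lineage, one conservative outgroup),
fractionation-style gene erosion at block ends, and scaffold fragmentation
of the pivot genome.  Pairwise tables emulate what a synteny mapper reports:
maximal runs of blocks adjacent in both genomes become single blocks with
gene-index coordinates, strands and per-genome gene counts.

Every experiment is reproducible from one integer seed; sub-streams are
spawned deterministically so components can be re-run in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _adjacency as adj
from .model import BlockTable, Placement, SignedBlockGenome, SyntenyBlockRecord
from .rearrangement import dcj_distance

__all__ = [
    "BranchConfig",
    "SimulationConfig",
    "GroundTruth",
    "SimulationResult",
    "random_genome",
    "generate_ancestor",
    "evolve",
    "emit_pairwise_tables",
    "simulate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BranchConfig:
    """Operation count and type mix for one branch of the three-leaf star."""

    n_ops: int
    reversal: float = 0.5
    translocation: float = 0.3
    fusion: float = 0.1
    fission: float = 0.1
    #: inversions are predominantly local: the reversed segment's gene
    #: content is exponential with this mean, so most reversals flip one or
    #: two small blocks and become invisible once those blocks fall below
    #: the resolution threshold - translocations, by contrast, move whole
    #: chromosome ends and stay visible at any granularity
    reversal_genes_mean: float = 60.0

    def __post_init__(self) -> None:
        total = self.reversal + self.translocation + self.fusion + self.fission
        if abs(total - 1.0) > 1e-9:
            raise ValueError("operation type probabilities must sum to 1")

    @property
    def mix(self) -> tuple[float, float, float, float]:
        return (self.reversal, self.translocation, self.fusion, self.fission)


#: Default regime: a fast, translocation-rich pivot lineage; a conservative,
#: reversal-dominated sister; a conservative outgroup on a longer time span.
#: Branch regimes follow the shape of the real three-genome comparison the
#: generator emulates: the pivot lineage is fastest and translocation-rich,
#: the sister lineage is slow and almost entirely small-inversion-driven,
#: and the outgroup branch (a longer time span) is intermediate.  Only a
#: minority of each lineage's operations are chromosome-scale, which is what
#: makes most of the signal evaporate as resolution coarsens.
DEFAULT_BRANCHES = {
    "rhazya": BranchConfig(n_ops=13, reversal=0.55, translocation=0.35, fusion=0.05, fission=0.05),
    "coffee": BranchConfig(n_ops=7, reversal=0.85, translocation=0.05, fusion=0.10, fission=0.00),
    "grape": BranchConfig(n_ops=10, reversal=0.60, translocation=0.30, fusion=0.05, fission=0.05),
}


@dataclass(frozen=True)
class SimulationConfig:
    """The stated world of the default synthetic experiment.

    Sizes are a desk-scale stand-in for a real three-genome comparison
    (hundreds of blocks, ~70 genes per block, colours from a handful of
    ancestral chromosomes, tens of pivot scaffolds); see the methods note
    for the rationale behind each default.
    """

    n_blocks: int = 60
    n_chromosomes: int = 5
    colour_count: int = 21
    branches: dict = field(default_factory=lambda: dict(DEFAULT_BRANCHES))
    pivot: str = "rhazya"
    gene_count_min: int = 5
    gene_count_median: int = 70
    gene_count_max: int = 400
    gene_count_sigma: float = 0.9
    erosion_mean: float = 2.0
    pivot_break_prob: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks < self.n_chromosomes:
            raise ValueError("need at least one block per chromosome")
        if self.pivot not in self.branches:
            raise ValueError("pivot must be one of the branch genomes")

    @property
    def genome_names(self) -> tuple[str, ...]:
        return tuple(self.branches)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    ancestor: SignedBlockGenome
    leaves: dict[str, SignedBlockGenome]
    scenarios: dict[str, list]
    colours: dict[int, int]
    gene_counts: dict[int, int]
    eroded_counts: dict[str, dict[int, int]]
    distances: dict[tuple[str, str], int]


@dataclass
class SimulationResult:
    truth: GroundTruth
    tables: dict[tuple[str, str], BlockTable]
    config: SimulationConfig


def random_genome(
    n_blocks: int,
    n_chromosomes: int,
    rng: np.random.Generator,
    name: str = "random",
) -> SignedBlockGenome:
    """Uniformly shuffled signed genome: random order, signs, chromosome breaks."""
    order = rng.permutation(np.arange(1, n_blocks + 1))
    signs = rng.choice([-1, 1], size=n_blocks)
    seq = list(order * signs)
    if n_chromosomes > 1:
        breaks = sorted(
            rng.choice(np.arange(1, n_blocks), size=n_chromosomes - 1, replace=False)
        )
    else:
        breaks = []
    chroms, prev = [], 0
    for b in list(breaks) + [n_blocks]:
        chroms.append(tuple(int(x) for x in seq[prev:b]))
        prev = b
    return SignedBlockGenome(name, tuple(chroms))


def generate_ancestor(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[SignedBlockGenome, dict[int, int], dict[int, int]]:
    """Ancestor genome, block colours (by chromosome of origin), gene counts.

    Blocks 1..n are laid contiguously on the chromosomes; gene counts are
    drawn log-normally around the configured median and clipped to the
    configured range, mimicking the long-tailed block sizes synteny mappers
    report.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    sizes = [cfg.n_blocks // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_blocks % cfg.n_chromosomes):
        sizes[i] += 1
    chroms, colours = [], {}
    nxt = 1
    for ci, size in enumerate(sizes):
        chrom = tuple(range(nxt, nxt + size))
        for b in chrom:
            colours[b] = (ci % cfg.colour_count) + 1
        chroms.append(chrom)
        nxt += size
    counts = {}
    for b in range(1, cfg.n_blocks + 1):
        draw = rng.lognormal(mean=np.log(cfg.gene_count_median), sigma=cfg.gene_count_sigma)
        counts[b] = int(np.clip(round(draw), cfg.gene_count_min, cfg.gene_count_max))
    return SignedBlockGenome("ancestor", tuple(chroms)), colours, counts


def _pick_weighted_chrom(chroms, weights, rng):
    w = np.asarray(weights, dtype=float)
    return int(rng.choice(len(chroms), p=w / w.sum()))


def evolve(
    genome: SignedBlockGenome,
    branch: BranchConfig,
    rng: np.random.Generator,
    name: str | None = None,
    gene_counts: dict[int, int] | None = None,
    length_weighted: bool = False,
) -> tuple[SignedBlockGenome, list]:
    """Apply the branch's operations; returns the leaf and realised scenario.

    Reversals pick a random within-chromosome interval; translocations
    exchange tails of two chromosomes at uniform cut points (optionally
    weighted by gene length, for estimator experiments); fusions concatenate
    and fissions split.  Operations impossible in the current state (e.g. a
    translocation with one chromosome) are resampled, so the realised
    scenario always has exactly ``branch.n_ops`` operations; circular
    products never arise by construction.
    """
    chroms = [list(c) for c in genome.chromosomes]
    scenario = []
    kinds = ("reversal", "translocation", "fusion", "fission")
    for _ in range(branch.n_ops):
        for _attempt in range(200):
            kind = kinds[int(rng.choice(4, p=branch.mix))]
            if kind == "reversal":
                if gene_counts:
                    # an inversion is representable at block scale only when
                    # its gene span covers whole blocks, so draw the span
                    # first and flip a maximal run of blocks fitting in it -
                    # small inversions (the typical case) therefore mark
                    # small blocks, the ones coarse resolution discards
                    target = rng.exponential(branch.reversal_genes_mean)
                    flat = [
                        (ci, bi)
                        for ci, c in enumerate(chroms)
                        for bi in range(len(c))
                        if gene_counts[abs(c[bi])] <= target
                    ]
                    if not flat:
                        continue
                    ci, i = flat[int(rng.integers(0, len(flat)))]
                    c = chroms[ci]
                    j = i
                    total = gene_counts[abs(c[i])]
                    while j + 1 < len(c) and total + gene_counts[abs(c[j + 1])] <= target:
                        j += 1
                        total += gene_counts[abs(c[j])]
                else:
                    cands = [i for i, c in enumerate(chroms) if len(c) >= 1]
                    ci = int(rng.choice(cands))
                    c = chroms[ci]
                    i = int(rng.integers(0, len(c)))
                    j = min(len(c) - 1, i + int(rng.geometric(0.5)) - 1)
                chroms[ci] = c[:i] + [-x for x in reversed(c[i:j + 1])] + c[j + 1:]
                scenario.append(("reversal", ci, i, j))
                break
            if kind == "translocation":
                if len(chroms) < 2:
                    continue
                if length_weighted and gene_counts:
                    weights = [sum(gene_counts[abs(x)] for x in c) for c in chroms]
                else:
                    weights = [len(c) for c in chroms]
                a = _pick_weighted_chrom(chroms, weights, rng)
                b = _pick_weighted_chrom(chroms, weights, rng)
                if a == b:
                    continue
                ca, cb = chroms[a], chroms[b]
                x = int(rng.integers(0, len(ca) + 1))
                y = int(rng.integers(0, len(cb) + 1))
                na, nb = ca[:x] + cb[y:], cb[:y] + ca[x:]
                if not na or not nb or (x == 0 and y == 0) or (x == len(ca) and y == len(cb)):
                    continue
                chroms[a], chroms[b] = na, nb
                scenario.append(("translocation", a, b, x, y))
                break
            if kind == "fusion":
                if len(chroms) < 2:
                    continue
                a, b = rng.choice(len(chroms), size=2, replace=False)
                a, b = int(a), int(b)
                merged = chroms[a] + chroms[b]
                chroms = [c for i, c in enumerate(chroms) if i not in (a, b)] + [merged]
                scenario.append(("fusion", a, b))
                break
            if kind == "fission":
                cands = [i for i, c in enumerate(chroms) if len(c) >= 2]
                if not cands:
                    continue
                ci = int(rng.choice(cands))
                c = chroms[ci]
                x = int(rng.integers(1, len(c)))
                chroms = chroms[:ci] + [c[:x], c[x:]] + chroms[ci + 1:]
                scenario.append(("fission", ci, x))
                break
        else:
            logger.warning("could not realise an operation; genome too degenerate")
    return SignedBlockGenome(name or genome.name, tuple(tuple(c) for c in chroms)), scenario


# ---------------------------------------------------------------------------
# refining evolution (used by simulate)
# ---------------------------------------------------------------------------


class _RefiningWorld:
    """Shared block universe in which operations create their own boundaries.

    Rearrangement breakpoints fall on gene positions; a breakpoint interior
    to a block splits that block - in the ancestor and every descendant at
    once, so block content stays identical across genomes.  Small blocks are
    therefore small *because* rearrangement cut them small, which is what
    couples resolution loss to evolutionary signal: the fine-scale events of
    a conservative, inversion-dominated lineage live entirely in blocks that
    a coarse analysis discards.
    """

    def __init__(self, ancestor: SignedBlockGenome, counts: dict[int, int], colours: dict[int, int]):
        self.genomes: dict[str, list[list[int]]] = {
            "ancestor": [list(c) for c in ancestor.chromosomes]
        }
        self.counts = counts
        self.colours = colours
        self.next_id = max(counts) + 1

    def add_leaf(self, name: str) -> None:
        self.genomes[name] = [list(c) for c in self.genomes["ancestor"]]

    def _split(self, b: int, left_genes: int) -> tuple[int, int]:
        """Split block ``b`` globally at ``left_genes`` (canonical reading)."""
        g = self.counts[b]
        assert 0 < left_genes < g
        b1, b2 = self.next_id, self.next_id + 1
        self.next_id += 2
        self.counts[b1], self.counts[b2] = left_genes, g - left_genes
        del self.counts[b]
        self.colours[b1] = self.colours[b2] = self.colours.pop(b)
        for chroms in self.genomes.values():
            for c in chroms:
                for i, x in enumerate(c):
                    if abs(x) == b:
                        c[i:i + 1] = [b1, b2] if x > 0 else [-b2, -b1]
                        break
                else:
                    continue
                break
        return b1, b2

    def _chrom_len(self, name: str, ci: int) -> int:
        return sum(self.counts[abs(x)] for x in self.genomes[name][ci])

    def _cut(self, name: str, ci: int, pos: int) -> int:
        """Turn gene position ``pos`` (0..chrom_len) into a block boundary
        index on chromosome ``ci``, splitting a block if needed."""
        c = self.genomes[name][ci]
        acc = 0
        for i, x in enumerate(c):
            g = self.counts[abs(x)]
            if pos == acc:
                return i
            if pos < acc + g:
                off = pos - acc  # genes left of the cut in reading order
                canon = off if x > 0 else g - off
                self._split(abs(x), canon)
                return i + 1
            acc += g
        return len(c)

    def reversal(self, name: str, rng, genes_mean: float) -> tuple:
        chroms = self.genomes[name]
        lens = [self._chrom_len(name, i) for i in range(len(chroms))]
        ci = _pick_weighted_chrom(chroms, lens, rng)
        total = lens[ci]
        start = int(rng.integers(0, total))
        span = max(1, int(round(rng.exponential(genes_mean))))
        end = min(total, start + span)
        if end == start:
            end = start + 1
        i = self._cut(name, ci, start)
        j = self._cut(name, ci, end)
        c = self.genomes[name][ci]
        if i == j:  # degenerate after clipping; flip one block
            j = min(i + 1, len(c))
        c[i:j] = [-x for x in reversed(c[i:j])]
        return ("reversal", ci, start, end)

    def translocation(self, name: str, rng) -> tuple | None:
        chroms = self.genomes[name]
        if len(chroms) < 2:
            return None
        lens = [self._chrom_len(name, i) for i in range(len(chroms))]
        a = _pick_weighted_chrom(chroms, lens, rng)
        b = _pick_weighted_chrom(chroms, lens, rng)
        if a == b:
            return None
        x = int(rng.integers(0, lens[a] + 1))
        y = int(rng.integers(0, lens[b] + 1))
        i = self._cut(name, a, x)
        j = self._cut(name, b, y)
        ca, cb = chroms[a], chroms[b]
        na, nb = ca[:i] + cb[j:], cb[:j] + ca[i:]
        if not na or not nb or (i == 0 and j == 0) or (i == len(ca) and j == len(cb)):
            return None
        chroms[a], chroms[b] = na, nb
        return ("translocation", a, b, x, y)

    def fusion(self, name: str, rng) -> tuple | None:
        chroms = self.genomes[name]
        if len(chroms) < 2:
            return None
        a, b = (int(v) for v in rng.choice(len(chroms), size=2, replace=False))
        merged = chroms[a] + chroms[b]
        self.genomes[name] = [c for i, c in enumerate(chroms) if i not in (a, b)] + [merged]
        return ("fusion", a, b)

    def fission(self, name: str, rng) -> tuple | None:
        chroms = self.genomes[name]
        cands = [i for i in range(len(chroms)) if len(chroms[i]) >= 1 and self._chrom_len(name, i) >= 2]
        if not cands:
            return None
        ci = int(rng.choice(cands))
        pos = int(rng.integers(1, self._chrom_len(name, ci)))
        i = self._cut(name, ci, pos)
        c = chroms[ci]
        if i == 0 or i == len(c):
            return None
        self.genomes[name] = chroms[:ci] + [c[:i], c[i:]] + chroms[ci + 1:]
        return ("fission", ci, pos)

    def evolve_branch(self, name: str, branch: BranchConfig, rng) -> list:
        self.add_leaf(name)
        scenario = []
        kinds = ("reversal", "translocation", "fusion", "fission")
        for _ in range(branch.n_ops):
            for _attempt in range(200):
                kind = kinds[int(rng.choice(4, p=branch.mix))]
                if kind == "reversal":
                    op = self.reversal(name, rng, branch.reversal_genes_mean)
                elif kind == "translocation":
                    op = self.translocation(name, rng)
                elif kind == "fusion":
                    op = self.fusion(name, rng)
                else:
                    op = self.fission(name, rng)
                if op is not None:
                    scenario.append(op)
                    break
            else:  # pragma: no cover - degenerate configuration
                logger.warning("could not realise an operation on %s", name)
        return scenario

    def genome(self, name: str) -> SignedBlockGenome:
        return SignedBlockGenome(
            name, tuple(tuple(c) for c in self.genomes[name] if c)
        )


# ---------------------------------------------------------------------------
# table emission
# ---------------------------------------------------------------------------


def _erode(counts, rng, mean):
    """Fractionation: remove a Poisson number of genes at each block end."""
    out = {}
    for b, n in counts.items():
        left = int(rng.poisson(mean))
        right = int(rng.poisson(mean))
        keep = max(1, n - left - right)
        out[b] = keep
    return out


def _layout(genome, full_counts, eroded, breaks):
    """Per-block (scaffold, start, end) with cumulative gene coordinates.

    ``breaks`` is a set of (chromosome index, boundary index) where the
    assembly splits a chromosome into scaffolds; coordinates restart at 1 on
    each scaffold.  The block span covers only the surviving (non-eroded)
    genes, so erosion opens gaps between neighbouring blocks.
    """
    placement = {}
    scaffold_of = {}
    for ci, chrom in enumerate(genome.chromosomes):
        part = 0
        cursor = 1
        for bi, x in enumerate(chrom):
            if bi > 0 and (ci, bi) in breaks:
                part += 1
                cursor = 1
            b = abs(x)
            full = full_counts[b]
            kept = eroded[b]
            pad_left = (full - kept) // 2
            scaf = f"{genome.name}_c{ci + 1}_{part}" if breaks else f"{genome.name}_c{ci + 1}"
            start = cursor + pad_left
            placement[b] = (scaf, start, start + kept - 1)
            scaffold_of[b] = (ci, part)
            cursor += full
    return placement, scaffold_of


def emit_pairwise_tables(
    leaf_a: SignedBlockGenome,
    leaf_b: SignedBlockGenome,
    gene_counts: dict[int, int],
    colours: dict[int, int],
    eroded_a: dict[int, int],
    eroded_b: dict[int, int],
    breaks_a: set | None = None,
    breaks_b: set | None = None,
) -> BlockTable:
    """SYNMAP-like pairwise blocks for two leaves sharing block content.

    Maximal runs of blocks that are contiguous in both genomes (same signed
    segment up to reversal, same colour, not interrupted by a scaffold
    break) are emitted as single blocks, the way a synteny mapper reports
    maximal collinear runs; each record carries both placements, strands
    (first genome reads '+') and summed eroded gene counts.
    """
    breaks_a = breaks_a or set()
    breaks_b = breaks_b or set()
    adj.check_same_content(leaf_a, leaf_b)
    lay_a, scaf_a = _layout(leaf_a, gene_counts, eroded_a, breaks_a)
    lay_b, scaf_b = _layout(leaf_b, gene_counts, eroded_b, breaks_b)

    # signed position of each block in leaf_b, for run extension tests
    pos_b: dict[int, tuple[int, int, int]] = {}
    for ci, chrom in enumerate(leaf_b.chromosomes):
        for bi, x in enumerate(chrom):
            pos_b[abs(x)] = (ci, bi, 1 if x > 0 else -1)

    def extends(x, y) -> bool:
        """Can signed blocks x,y (consecutive in A) stay in one run?

        Scaffold breaks are visible through the scaffold-part comparison,
        so a fragmented assembly splits runs exactly as it should.
        """
        bx, by = abs(x), abs(y)
        if colours[bx] != colours[by]:
            return False
        if scaf_a[bx] != scaf_a[by]:
            return False
        cbx, ibx, sbx = pos_b[bx]
        cby, iby, sby = pos_b[by]
        if cbx != cby or scaf_b[bx] != scaf_b[by]:
            return False
        sx, sy = (1 if x > 0 else -1), (1 if y > 0 else -1)
        # forward: B reads ...x y... with matching signs
        if iby == ibx + 1 and sbx == sx and sby == sy:
            return True
        # reversed: B reads ...-y -x...
        if iby == ibx - 1 and sbx == -sx and sby == -sy:
            return True
        return False

    records = []
    n = 0
    name_a, name_b = leaf_a.name, leaf_b.name
    for ci, chrom in enumerate(leaf_a.chromosomes):
        run: list[int] = []

        def flush(run):
            nonlocal n
            if not run:
                return
            n += 1
            ids = [abs(x) for x in run]
            sa = [lay_a[b] for b in ids]
            sb = [lay_b[b] for b in ids]
            first = abs(run[0])
            sign_first = 1 if run[0] > 0 else -1
            strand_b = "+" if pos_b[first][2] == sign_first else "-"
            records.append(
                SyntenyBlockRecord(
                    block_id=f"p{n}",
                    colour=colours[first],
                    placements={
                        name_a: Placement(
                            sa[0][0], min(s[1] for s in sa), max(s[2] for s in sa), "+"
                        ),
                        name_b: Placement(
                            sb[0][0], min(s[1] for s in sb), max(s[2] for s in sb), strand_b
                        ),
                    },
                    genes={
                        name_a: sum(eroded_a[b] for b in ids),
                        name_b: sum(eroded_b[b] for b in ids),
                    },
                )
            )

        for bi, x in enumerate(chrom):
            if run and extends(run[-1], x):
                run.append(x)
            else:
                flush(run)
                run = [x]
        flush(run)
    return BlockTable(records, (name_a, name_b))


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Full synthetic experiment: ancestor, three leaves, three pairwise tables."""
    root = np.random.SeedSequence(cfg.seed)
    streams = root.spawn(6)
    rng_anc = np.random.default_rng(streams[0])
    ancestor0, colours0, counts0 = generate_ancestor(cfg, rng_anc)

    # evolve in a shared refining world: breakpoints interior to a block
    # split it in every genome, so block sizes reflect rearrangement history
    world = _RefiningWorld(ancestor0, dict(counts0), dict(colours0))
    names = list(cfg.genome_names)
    scenarios = {}
    for i, name in enumerate(names):
        rng = np.random.default_rng(streams[1 + i])
        scenarios[name] = world.evolve_branch(name, cfg.branches[name], rng)
    ancestor = world.genome("ancestor")
    leaves = {name: world.genome(name) for name in names}
    colours = world.colours
    counts = world.counts

    rng_emit = np.random.default_rng(streams[4])
    eroded = {name: _erode(counts, rng_emit, cfg.erosion_mean) for name in names}

    rng_frag = np.random.default_rng(streams[5])
    pivot_leaf = leaves[cfg.pivot]
    breaks = set()
    for ci, chrom in enumerate(pivot_leaf.chromosomes):
        for bi in range(1, len(chrom)):
            if rng_frag.random() < cfg.pivot_break_prob:
                breaks.add((ci, bi))

    def table(a: str, b: str) -> BlockTable:
        return emit_pairwise_tables(
            leaves[a], leaves[b], counts, colours,
            eroded[a], eroded[b],
            breaks_a=breaks if a == cfg.pivot else None,
            breaks_b=breaks if b == cfg.pivot else None,
        )

    other = [n for n in names if n != cfg.pivot]
    tables = {
        (other[1], cfg.pivot): table(other[1], cfg.pivot),
        (cfg.pivot, other[0]): table(cfg.pivot, other[0]),
        (other[0], other[1]): table(other[0], other[1]),
    }
    distances = {}
    for i, x in enumerate(names):
        for y in names[i + 1:]:
            distances[(x, y)] = dcj_distance(leaves[x], leaves[y])
    truth = GroundTruth(
        ancestor=ancestor,
        leaves=leaves,
        scenarios=scenarios,
        colours=colours,
        gene_counts=counts,
        eroded_counts=eroded,
        distances=distances,
    )
    return SimulationResult(truth=truth, tables=tables, config=cfg)
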