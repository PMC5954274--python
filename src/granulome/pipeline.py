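"""End-to-end orchestration: simulate or ingest pairwise tables, build
three-way blocks, sweep resolution levels, and measure everything the
analysis cares about at each level - median distance profiles, breakpoint
totals, normalized scores, breakpoint reuse, translocation/reversal counts
under both priority modes, and model-based translocation estimates.

The single entry point is :func:`run`, driven by a configuration mapping
(or YAML file); results come back as a :class:`SweepSummary` holding one
table row per resolution level, optionally written - with every
intermediate artifact - to an output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .blocks import build_three_way, filter_informative_scaffolds
from .estimator import estimate_from_genomes
from .median import dcj_median, median_distance_profile
from .model import (
    UndefinedValueError,
    read_block_table,
    write_block_table,
    write_genome,
)
from .rearrangement import (
    breakpoint_distance,
    dcj_distance,
    normalized_total,
    reuse_rate,
    sort_scenario,
)
from .resolution import ResolutionSchedule, resolve_polarity, sweep
from .synthetic import BranchConfig, SimulationConfig, simulate

__all__ = ["SweepSummary", "TrendFit", "run", "reuse_trend", "load_config"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "levels": list(ResolutionSchedule().levels),
    "merge_gap": 250,
    "colour_rule": True,
    "filter_scaffolds": True,
    "median_cap": 50_000,
    "enumerate_medians": True,
    "scenarios": True,
    "estimator": {"variant": "eq7", "factor2_omitted": True},
    "outdir": None,
}


@dataclass
class SweepSummary:
    """One row per resolution level; columns mirror the per-level accounting
    (blocks/genes), the median analysis, and the derived statistics."""

    table: pd.DataFrame
    genome_names: tuple[str, ...]
    outdir: Path | None = None

    def row(self, level: int) -> pd.Series:
        return self.table.set_index("level").loc[level]


@dataclass
class TrendFit:
    slope: float
    intercept: float
    r_squared: float


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _sim_config(cfg: dict) -> SimulationConfig:
    sim = dict(cfg.get("simulation") or {})
    branches = sim.pop("branches", None)
    kwargs = dict(sim)
    if branches:
        kwargs["branches"] = {
            name: BranchConfig(**spec) for name, spec in branches.items()
        }
    kwargs.setdefault("seed", cfg.get("seed", 0))
    return SimulationConfig(**kwargs)


def run(config: dict | str | Path) -> SweepSummary:
    """Execute the full analysis described by ``config``.

    The configuration either names a simulation (key ``simulation``) or
    three pairwise block-table TSVs plus a pivot (key ``inputs`` with
    ``ab``, ``bc``, ``ca``, ``pivot``).  Deterministic given ``seed``; when
    ``outdir`` is set, every intermediate (three-way table, per-level tables,
    genomes, medians) is written beneath it.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = {**DEFAULT_CONFIG, **config}
    outdir = Path(cfg["outdir"]) if cfg["outdir"] else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    if cfg.get("inputs"):
        inputs = cfg["inputs"]
        pivot = inputs["pivot"]
        ab = read_block_table(inputs["ab"])
        bc = read_block_table(inputs["bc"])
        ca = read_block_table(inputs["ca"]) if inputs.get("ca") else None
        truth = None
    else:
        sim = simulate(_sim_config(cfg))
        pivot = sim.config.pivot
        (ab_key, bc_key, ca_key) = list(sim.tables)
        ab, bc, ca = sim.tables[ab_key], sim.tables[bc_key], sim.tables[ca_key]
        truth = sim.truth
        if outdir:
            for name, leaf in sim.truth.leaves.items():
                write_genome(leaf, outdir / f"leaf_{name}.grimm")
            write_genome(sim.truth.ancestor, outdir / "ancestor.grimm")
            for key, t in sim.tables.items():
                write_block_table(t, outdir / f"pairwise_{'_'.join(key)}.tsv")

    threeway = build_three_way(ab, bc, ca, pivot)
    if cfg["filter_scaffolds"]:
        threeway = filter_informative_scaffolds(threeway, pivot)
    if outdir:
        write_block_table(threeway, outdir / "threeway.tsv")

    schedule = ResolutionSchedule(
        levels=tuple(cfg["levels"]),
        merge_gap=cfg["merge_gap"],
        colour_rule=cfg["colour_rule"],
    )
    level_results = sweep(threeway, schedule, pivot=pivot)
    names = threeway.genome_names
    est_cfg = cfg["estimator"]

    rows = []
    for lr in level_results:
        rep = lr.report
        row: dict[str, object] = {
            "level": rep.level,
            "blocks_deleted": rep.blocks_deleted,
            "blocks_remaining": rep.blocks_remaining,
            "blocks_after_mergers": rep.blocks_after_mergers,
            "genes_not_included": rep.genes_not_included,
            "genes_remaining": rep.genes_remaining,
        }
        if not lr.genomes:
            rows.append(row)
            continue
        genomes = [lr.genomes[g] for g in names]
        if lr.indeterminate:
            _, _, genomes = resolve_polarity(genomes, lr.indeterminate)
        n_blocks = len(lr.table)
        for i, x in enumerate(names):
            for y in names[i + 1:]:
                gx, gy = genomes[i], genomes[names.index(y)]
                row[f"d_{x}_{y}"] = dcj_distance(gx, gy)
                try:
                    row[f"r_{x}_{y}"] = reuse_rate(gx, gy)
                except UndefinedValueError:
                    row[f"r_{x}_{y}"] = np.nan
        if n_blocks and n_blocks >= 1:
            med = dcj_median(
                *genomes,
                enumerate_all=cfg["enumerate_medians"],
                cap=cfg["median_cap"],
            )
            med.level = rep.level
            _, means = median_distance_profile(med, *genomes)
            row["median_total"] = med.total_score
            row["n_medians"] = med.n_medians
            row["medians_truncated"] = med.truncated
            row["median_normalized"] = normalized_total(med.total_score, n_blocks)
            m = med.representative
            bp_total = 0.0
            lengths = {
                lr.table.block_index()[r.block_id]: max(r.genes[pivot], 1)
                for r in lr.table.records
            }
            for i, x in enumerate(names):
                row[f"d_m_{x}"] = float(means[i])
                bp = breakpoint_distance(m, genomes[i])
                row[f"bp_m_{x}"] = bp
                bp_total += bp
                try:
                    est = estimate_from_genomes(
                        m, genomes[i], lengths,
                        variant=est_cfg.get("variant", "eq7"),
                        factor2_omitted=est_cfg.get("factor2_omitted", True),
                    )
                    row[f"t_hat_{x}"] = est.t_hat
                except UndefinedValueError as exc:
                    logger.debug("estimator undefined at level %d: %s", rep.level, exc)
                    row[f"t_hat_{x}"] = np.nan
                if cfg["scenarios"]:
                    for mode, tag in (
                        ("translocations-first", "tf"),
                        ("reversals-first", "rf"),
                    ):
                        scen = sort_scenario(m, genomes[i], mode)
                        row[f"transloc_{tag}_{x}"] = scen.count("translocation")
                        row[f"reversal_{tag}_{x}"] = scen.count("reversal")
                        row[f"fusion_{tag}_{x}"] = scen.count("fusion")
                        row[f"fission_{tag}_{x}"] = scen.count("fission")
            row["bp_total"] = bp_total
            if outdir:
                ldir = outdir / f"level_{rep.level:02d}"
                ldir.mkdir(exist_ok=True)
                write_block_table(lr.table, ldir / "blocks.tsv")
                for g in genomes:
                    write_genome(g, ldir / f"{g.name}.grimm")
                for i, mg in enumerate(med.medians[:200]):
                    write_genome(mg, ldir / f"median_{i:04d}.grimm")
        rows.append(row)

    table = pd.DataFrame(rows)
    summary = SweepSummary(table=table, genome_names=names, outdir=outdir)
    if outdir:
        table.to_csv(outdir / "summary.tsv", sep="\t", index=False)
        if truth is not None:
            meta = {
                "true_distances": {f"{a}-{b}": d for (a, b), d in truth.distances.items()},
                "n_ops": {g: len(s) for g, s in truth.scenarios.items()},
            }
            (outdir / "truth.json").write_text(json.dumps(meta, indent=2))
    return summary


def reuse_trend(summary: SweepSummary | pd.DataFrame) -> TrendFit:
    """Least-squares fit of pooled breakpoint reuse against resolution level.

    All defined per-pair ``r`` values are pooled; requires at least three
    (level, r) points.  A positive slope is the signature of genomes drifting
    toward mutual randomness as resolution coarsens.
    """
    df = summary.table if isinstance(summary, SweepSummary) else summary
    r_cols = [c for c in df.columns if c.startswith("r_")]
    xs, ys = [], []
    for _, row in df.iterrows():
        for c in r_cols:
            v = row[c]
            if pd.notna(v):
                xs.append(row["level"])
                ys.append(float(v))
    if len(xs) < 3:
        raise UndefinedValueError("need at least three defined r values")
    if float(np.var(ys)) == 0.0:
        return TrendFit(slope=0.0, intercept=float(ys[0]), r_squared=1.0)
    fit = stats.linregress(xs, ys)
    return TrendFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )
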