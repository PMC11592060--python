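"""End-to-end pipeline: QC → stability methods → consensus → validation.

Everything the command-line interface does funnels through
:func:`run_pipeline`, which reads (or simulates) a Ct table, runs the
enabled stability algorithms, aggregates them, and writes a deterministic
report bundle: per-method TSVs, the consensus TSV, the QC report, the
correlation matrix, an optional ΔΔCt validation table, and a JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd

from . import bestkeeper as bk
from . import pairwise
from .consensus import ConsensusRanking, aggregate_rankings
from .core_io import CtTable, read_ct_table, validate_ct_table, write_ct_table
from .ddct import compare_references
from .normfinder import GroupingScheme, coarse_grouping, fine_grouping, normfinder_stability
from .ranking import StabilityRanking
from .simulate import default_study_design, simulate_ct

log = logging.getLogger("refstab")

ALL_METHODS = ("bestkeeper", "delta_ct", "genorm", "normfinder")

FLOAT_FMT = "%.4f"


@dataclass
class PipelineConfig:
    """Inputs, method switches and output location of one pipeline run."""

    input_path: str | None = None  # None → simulate the default study design
    layout: str = "long"
    group_path: str | None = None
    methods: tuple[str, ...] = ALL_METHODS
    sd_mode: str = "mad"  # BestKeeper dispersion
    base: float = 2.0  # log base for the pairwise methods
    grouping: str = "fine"  # NormFinder preset: fine | coarse
    consensus: bool = True
    max_ct: float = 40.0
    validation: dict | None = None  # {target, references, control_group, case_group}
    outdir: str = "refstab_out"
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = [m for m in self.methods if m not in ALL_METHODS]
        if unknown:
            raise ValueError(f"unknown methods {unknown}; choose from {ALL_METHODS}")
        if self.consensus and len(self.methods) < 2:
            raise ValueError("consensus requires at least 2 enabled methods")

    @classmethod
    def from_mapping(cls, doc: Mapping[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(doc) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        doc = dict(doc)
        if "methods" in doc:
            doc["methods"] = tuple(doc["methods"])
        return cls(**doc)


def _load_table(config: PipelineConfig) -> CtTable:
    if config.input_path is None:
        log.info("no input given; simulating the default study design (seed=%d)", config.seed)
        design = default_study_design(seed=config.seed)
        table, _ = simulate_ct(design)
        return table
    return read_ct_table(config.input_path, layout=config.layout, group_map=config.group_path)


def _grouping(config: PipelineConfig, table: CtTable) -> GroupingScheme:
    if config.grouping == "fine":
        return fine_grouping(table)
    if config.grouping == "coarse":
        return coarse_grouping(table)
    raise ValueError(f"unknown grouping preset {config.grouping!r}")


def run_methods(
    table: CtTable,
    methods: Sequence[str] = ALL_METHODS,
    sd_mode: str = "mad",
    base: float = 2.0,
    grouping: GroupingScheme | None = None,
) -> dict[str, StabilityRanking]:
    """Run the selected stability algorithms on one table."""
    rankings: dict[str, StabilityRanking] = {}
    if "bestkeeper" in methods:
        stats = bk.descriptive_stats(table, sd_mode=sd_mode)
        rankings["bestkeeper"] = bk.rank_by_variation(stats)
    if "delta_ct" in methods:
        rankings["delta_ct"] = pairwise.delta_ct_stability(table)
    if "genorm" in methods:
        _, ranking = pairwise.genorm(table, base=base)
        rankings["genorm"] = ranking
    if "normfinder" in methods:
        _, ranking = normfinder_stability(table, grouping)
        rankings["normfinder"] = ranking
    return rankings


def rank_and_aggregate(
    table: CtTable,
    methods: Sequence[str] = ALL_METHODS,
    sd_mode: str = "mad",
    base: float = 2.0,
    grouping: GroupingScheme | None = None,
) -> tuple[dict[str, StabilityRanking], ConsensusRanking]:
    """Stability rankings plus their geometric-mean consensus."""
    rankings = run_methods(table, methods, sd_mode=sd_mode, base=base, grouping=grouping)
    cons = aggregate_rankings(list(rankings.values()))
    return rankings, cons


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns the machine-readable summary (also written as summary.json).
    Re-running with identical inputs and config is byte-identical.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = _load_table(config)
    if config.input_path is None:
        write_ct_table(table, outdir / "simulated_ct.csv", layout="long")

    qc = validate_ct_table(table, max_ct=config.max_ct)
    (outdir / "qc_report.json").write_text(json.dumps(qc.to_dict(), indent=2, sort_keys=True))
    log.info("QC: %d flagged cells, Ct range %.2f–%.2f", len(qc.flagged_cells), *qc.ct_range)

    grouping = _grouping(config, table)
    rankings = run_methods(
        table, config.methods, sd_mode=config.sd_mode, base=config.base, grouping=grouping
    )
    for name, ranking in rankings.items():
        ranking.to_frame().to_csv(outdir / f"{name}_stability.tsv", sep="\t", float_format=FLOAT_FMT)
    if "bestkeeper" in rankings:
        stats = bk.descriptive_stats(table, sd_mode=config.sd_mode)
        bk.bestkeeper_report(stats, rankings["bestkeeper"]).to_csv(
            outdir / "bestkeeper_report.tsv", sep="\t", float_format="%.2f"
        )
    if "genorm" in rankings:
        result, _ = pairwise.genorm(table, base=config.base)
        trace = pd.DataFrame(
            result.exclusion_order + [("/".join(result.final_pair), result.final_pair_m)],
            columns=["excluded_or_final_pair", "m_value"],
        )
        trace.to_csv(outdir / "genorm_trace.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    corr = pairwise.correlation_matrix(pairwise.linearize(table, base=config.base))
    corr.to_csv(outdir / "correlation_matrix.tsv", sep="\t", float_format=FLOAT_FMT)

    summary: dict[str, Any] = {
        "n_genes": len(table.genes),
        "n_samples": len(table.samples),
        "n_groups": qc.n_groups,
        "qc_flagged": len(qc.flagged_cells),
        "methods": list(rankings),
        "rankings": {
            name: {g: float(r.ranks[g]) for g in r.genes} for name, r in rankings.items()
        },
    }

    if config.consensus:
        cons = aggregate_rankings(list(rankings.values()))
        cons.to_frame().to_csv(outdir / "consensus.tsv", sep="\t", float_format=FLOAT_FMT)
        summary["consensus_order"] = cons.ordered_genes()
        summary["consensus_n_methods"] = len(rankings)
        log.info("consensus (over %d methods): %s", len(rankings), cons.ordered_genes())

    if config.validation:
        v = config.validation
        comparison = compare_references(
            table,
            target=v["target"],
            candidate_references=v["references"],
            control_group=v["control_group"],
            case_group=v["case_group"],
            base=config.base,
            threshold=float(v.get("threshold", 2.0)),
        )
        comparison.to_frame().to_csv(
            outdir / "ddct_validation.tsv", sep="\t", float_format=FLOAT_FMT
        )
        summary["validation"] = {
            "fold_changes": {
                "/".join(r.references): float(r.fold_change) for r in comparison.results
            },
            "divergence_ratio": comparison.divergence_ratio,
            "conclusion_flips": comparison.conclusion_flips,
            "outlier_reference": comparison.outlier_reference,
        }

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
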