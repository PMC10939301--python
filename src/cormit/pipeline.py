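"""Full pipeline orchestration: profiles -> strategies -> stats ->
selection-integration -> (optional) robustness, with a validated run
configuration and fixed output layout."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from cormit import data_io
from cormit.data_io import (
    ExpressionMatrix,
    FeatureSet,
    ModuleAssignment,
    MTPDatabase,
    read_expression_table,
    read_feature_list,
    read_module_assignment,
    read_mtp_database,
    write_results_tables,
)
from cormit.integration import (
    integrate_mtps,
    rank_strategies_per_mirna,
    select_top,
    selections_table,
)
from cormit.profiles import build_representatives, cpm_normalize
from cormit.robustness import RobustnessConfig, robustness_rankings
from cormit.stats import PairUniverse, evaluate_overall, evaluate_specific
from cormit.strategies import (
    candidate_pairs,
    detect_mtps,
    enumerate_strategies,
    pair_correlations,
    threshold_grid,
)

logger = logging.getLogger("cormit")


@dataclass
class RunConfig:
    """All inputs and toggles of one pipeline run."""

    genes: str
    mirnas: str
    gene_modules: str
    mirna_modules: str
    dems: str
    db: str
    out_dir: str
    degs: str | None = None
    corr_type: str = "lower"       # lower = anti-correlation, higher = positive
    mirna_set: str = "dem"         # dem | expressed
    gene_set: str = "expressed"    # expressed | deg
    alpha: float = 0.05
    zero_correction: bool = True
    lowercase_ids: bool = False
    normalized: bool = False       # inputs already CPM
    db_only: bool = False
    robustness: bool = False
    rob_fraction: float = 0.75
    rob_reps: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.corr_type not in ("lower", "higher"):
            raise ValueError(f"corr_type must be lower|higher, got {self.corr_type!r}")
        if self.mirna_set not in ("dem", "expressed"):
            raise ValueError(f"mirna_set must be dem|expressed, got {self.mirna_set!r}")
        if self.gene_set not in ("expressed", "deg"):
            raise ValueError(f"gene_set must be expressed|deg, got {self.gene_set!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.rob_fraction <= 1:
            raise ValueError("rob_fraction must be in (0, 1]")
        if self.rob_reps < 1:
            raise ValueError("rob_reps must be >= 1")
        if self.gene_set == "deg" and self.degs is None:
            raise ValueError("gene_set=deg requires a DEG list")


def validate_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    return RunConfig(**raw)


@dataclass
class RunInputs:
    """Validated in-memory inputs of one run."""

    genes: ExpressionMatrix
    mirnas: ExpressionMatrix
    gene_modules: ModuleAssignment
    mirna_modules: ModuleAssignment
    dems: FeatureSet
    db: MTPDatabase
    degs: FeatureSet | None = None


@dataclass
class RunResults:
    """Evaluation, selection, integration and robustness tables."""

    overall_eval: pd.DataFrame
    specific_eval: pd.DataFrame
    selection: pd.DataFrame
    integrated: pd.DataFrame
    robustness: pd.DataFrame | None = None
    detections: dict = field(default_factory=dict, repr=False)
    correlations: dict = field(default_factory=dict, repr=False)


def load_inputs(config: RunConfig) -> RunInputs:
    lc = config.lowercase_ids
    genes = read_expression_table(config.genes, "gene",
                                  normalized=config.normalized,
                                  lowercase_ids=lc)
    mirnas = read_expression_table(config.mirnas, "mirna",
                                   normalized=config.normalized,
                                   lowercase_ids=lc)
    if genes.sample_ids != mirnas.sample_ids:
        raise ValueError(
            "gene and miRNA matrices must share the same ordered sample set"
        )
    dems = read_feature_list(config.dems, "DEM", lowercase_ids=lc)
    dems = dems.restrict_to(mirnas.feature_ids)
    degs = None
    if config.degs is not None:
        degs = read_feature_list(config.degs, "DEG", lowercase_ids=lc)
        degs = degs.restrict_to(genes.feature_ids)
    return RunInputs(
        genes=genes,
        mirnas=mirnas,
        gene_modules=read_module_assignment(config.gene_modules, lowercase_ids=lc),
        mirna_modules=read_module_assignment(config.mirna_modules, lowercase_ids=lc),
        dems=dems,
        db=read_mtp_database(config.db, lowercase_ids=lc),
        degs=degs,
    )


def _evals_to_frame(evals, specific: bool) -> pd.DataFrame:
    rows = []
    for e in evals:
        row = {
            "strategy": e.strategy,
            "threshold": e.threshold,
            "a": e.table.a,
            "b": e.table.b,
            "S_d": e.table.s_d,
            "R": e.table.r,
            "odds_ratio": e.odds_ratio,
            "p_value": e.p_value,
        }
        if specific:
            row["mirna_id"] = e.scope
            row.update(precision=e.precision, recall=e.recall,
                       specificity=e.specificity, accuracy=e.accuracy)
        rows.append(row)
    cols = (data_io.SPECIFIC_COLUMNS if specific else data_io.OVERALL_COLUMNS)
    return pd.DataFrame(rows, columns=cols)


def run_core(inputs: RunInputs, config: RunConfig) -> RunResults:
    """Execute the pipeline on validated in-memory inputs."""
    genes = inputs.genes if inputs.genes.normalized else cpm_normalize(inputs.genes)
    mirnas = inputs.mirnas if inputs.mirnas.normalized else cpm_normalize(inputs.mirnas)

    expressed_genes = set(genes.feature_ids)
    expressed_mirnas = set(mirnas.feature_ids)
    cand_mirnas = (inputs.dems.ids if config.mirna_set == "dem"
                   else expressed_mirnas)
    cand_genes = (inputs.degs.ids if config.gene_set == "deg"
                  else expressed_genes)
    pairs = candidate_pairs(cand_mirnas, cand_genes)
    logger.info("candidate pairs: %d (%d miRNAs x %d genes)",
                len(pairs), len(cand_mirnas), len(cand_genes))

    gene_rep_maps = {
        kind: build_representatives(genes, inputs.gene_modules, kind)
        for kind in ("cpm_feature", "eigengene", "hub")
    }
    mirna_rep_maps = {
        kind: build_representatives(mirnas, inputs.mirna_modules, kind)
        for kind in ("cpm_feature", "eigengene", "hub")
    }

    grid = threshold_grid(config.corr_type)
    correlations: dict[str, pd.DataFrame] = {}
    detections: dict[tuple[str, float], object] = {}
    for strat in enumerate_strategies():
        corr = pair_correlations(
            gene_rep_maps[strat.gene_rep_kind],
            mirna_rep_maps[strat.mirna_rep_kind],
            pairs, strat,
        )
        correlations[strat.name] = corr
        for thr in grid:
            det = detect_mtps(corr, thr, config.corr_type)
            det.strategy = strat.name
            detections[(strat.name, thr)] = det
        n_det = {thr: len(detections[(strat.name, thr)].pairs) for thr in grid}
        logger.info("strategy %s: detections per threshold %s",
                    strat.name, n_det)

    universe = PairUniverse(expressed_mirnas, expressed_genes)
    overall = evaluate_overall(detections, inputs.db, universe,
                               zero_correction=config.zero_correction)

    specific = []
    rankings = {}
    for mirna_id in sorted(cand_mirnas):
        evals = evaluate_specific(
            detections, inputs.db, sorted(cand_genes), mirna_id,
            zero_correction=config.zero_correction,
        )
        specific.extend(evals)
        rankings[mirna_id] = rank_strategies_per_mirna(
            evals, alpha=config.alpha, direction=config.corr_type,
        )
    selections = select_top(rankings)
    no_targets = sorted(set(rankings) - set(selections))
    if no_targets:
        logger.info("no targets found for %d miRNA(s): %s",
                    len(no_targets), ", ".join(no_targets))
    logger.info("significant miRNAs: %d / %d", len(selections), len(rankings))

    integrated = integrate_mtps(selections, detections, correlations,
                                inputs.db, db_only=config.db_only)

    rob = None
    if config.robustness:
        rob = robustness_rankings(
            detections, inputs.db, sorted(cand_genes), selections,
            RobustnessConfig(fraction=config.rob_fraction,
                             n_reps=config.rob_reps,
                             base_seed=config.seed),
            alpha=config.alpha, direction=config.corr_type,
            zero_correction=config.zero_correction,
        )

    return RunResults(
        overall_eval=_evals_to_frame(overall, specific=False),
        specific_eval=_evals_to_frame(specific, specific=True),
        selection=selections_table(selections),
        integrated=integrated,
        robustness=rob,
        detections=detections,
        correlations=correlations,
    )


def run_pipeline(config: RunConfig) -> RunResults:
    """Load inputs, run the pipeline and write all result tables."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    try:
        inputs = load_inputs(config)
        results = run_core(inputs, config)
        write_results_tables(results, out_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return results
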