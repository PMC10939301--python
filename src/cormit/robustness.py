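"""Ranking stability under random subsampling of the pair database.

The per-miRNA ranking of strategy x threshold combinations depends on the
database of predicted/validated pairs, which changes across releases.  The
protocol draws a random subset (default 75%) of the database, recomputes the
specific odds ratios and rankings against it — correlations and detections
are unchanged, only the database varies — and records where the full-database
top combination lands.  This is repeated (default 40 replicates) with seeds
``base_seed + replicate`` so every replicate is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from cormit.data_io import MTPDatabase
from cormit.integration import RankedCombination, rank_strategies_per_mirna
from cormit.stats import evaluate_specific
from cormit.strategies import DetectionSet


@dataclass
class RobustnessConfig:
    fraction: float = 0.75
    n_reps: int = 40
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def subsample_database(
    db: MTPDatabase, fraction: float, seed: int
) -> MTPDatabase:
    """Uniform without-replacement sample of floor(fraction * |db|) pairs."""
    if not db.pairs:
        raise ValueError("cannot subsample an empty database")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ordered = sorted(db.pairs)
    k = int(np.floor(fraction * len(ordered)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ordered), size=k, replace=False)
    return MTPDatabase(pairs={ordered[i] for i in idx})


def robustness_rankings(
    detections: dict[tuple[str, float], DetectionSet],
    db: MTPDatabase,
    expressed_genes: Iterable[str],
    original_selections: dict[str, RankedCombination],
    config: RobustnessConfig,
    alpha: float = 0.05,
    direction: str = "lower",
    zero_correction: bool = True,
) -> pd.DataFrame:
    """Rank of each miRNA's original top combination across replicates.

    Returns a DataFrame (mirna_id, replicate, rank_of_original_top,
    was_significant); rank is NaN when the original top fell below the
    significance filter in that replicate.
    """
    genes = sorted(set(expressed_genes))
    rows = []
    for rep in range(1, config.n_reps + 1):
        sub = subsample_database(db, config.fraction, config.base_seed + rep)
        for mirna_id, sel in sorted(original_selections.items()):
            evals = evaluate_specific(
                detections, sub, genes, mirna_id,
                zero_correction=zero_correction,
            )
            ranking = rank_strategies_per_mirna(
                evals, alpha=alpha, direction=direction
            )
            rank = ranking.rank_of(sel.strategy, sel.threshold)
            rows.append({
                "mirna_id": mirna_id,
                "replicate": rep,
                "rank_of_original_top": np.nan if rank is None else rank,
                "was_significant": rank is not None,
            })
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "replicate", "rank_of_original_top",
                 "was_significant"],
    )
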