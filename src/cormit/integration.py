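"""Selection-integration: per-miRNA ranking of strategy x threshold
combinations by specific odds ratio, selection of the top combination and
emission of the integrated miRNA-target pair set.

Combinations whose exact test is not significant (p >= alpha) or whose
odds ratio is not finite are dropped before ranking.  Ties on the odds
ratio are broken by stricter threshold first, then canonical strategy
order, then smaller p-value — a deterministic total order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from cormit.data_io import MTPDatabase
from cormit.stats import StrategyEvaluation
from cormit.strategies import STRATEGY_ORDER, DetectionSet


@dataclass(frozen=True)
class RankedCombination:
    strategy: str
    threshold: float
    odds_ratio: float
    p_value: float
    n_detected: int
    n_overlap_db: int


@dataclass
class MirnaRanking:
    """Significant combinations for one miRNA, best first."""

    mirna_id: str
    entries: list[RankedCombination] = field(default_factory=list)
    alpha: float = 0.05

    def rank_of(self, strategy: str, threshold: float) -> int | None:
        """1-based rank of a combination, or None if not in the ranking."""
        for i, e in enumerate(self.entries, start=1):
            if e.strategy == strategy and math.isclose(e.threshold, threshold):
                return i
        return None


def _strictness_key(threshold: float, direction: str) -> float:
    # stricter = farther from zero in the detection direction
    return threshold if direction == "lower" else -threshold


def rank_strategies_per_mirna(
    evals: list[StrategyEvaluation],
    alpha: float = 0.05,
    direction: str = "lower",
) -> MirnaRanking:
    """Rank one miRNA's combinations by descending specific odds ratio."""
    if not evals:
        raise ValueError("no evaluations to rank")
    mirna_ids = {e.scope for e in evals}
    if len(mirna_ids) != 1:
        raise ValueError(f"evaluations span several scopes: {sorted(mirna_ids)}")
    mirna_id = mirna_ids.pop()
    strat_idx = {name: i for i, name in enumerate(STRATEGY_ORDER)}
    kept = [
        e for e in evals
        if math.isfinite(e.odds_ratio)
        and math.isfinite(e.p_value)
        and e.p_value < alpha
    ]
    kept.sort(key=lambda e: (
        -e.odds_ratio,
        _strictness_key(e.threshold, direction),
        strat_idx.get(e.strategy, len(strat_idx)),
        e.p_value,
    ))
    entries = [
        RankedCombination(
            strategy=e.strategy,
            threshold=e.threshold,
            odds_ratio=e.odds_ratio,
            p_value=e.p_value,
            n_detected=e.table.n_detected,
            n_overlap_db=e.table.a,
        )
        for e in kept
    ]
    return MirnaRanking(mirna_id=mirna_id, entries=entries, alpha=alpha)


def select_top(
    rankings: dict[str, MirnaRanking],
) -> dict[str, RankedCombination]:
    """Top combination per miRNA; miRNAs with empty rankings are omitted."""
    return {
        m: rk.entries[0]
        for m, rk in sorted(rankings.items())
        if rk.entries
    }


def selections_table(selections: dict[str, RankedCombination]) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": m,
            "strategy": sel.strategy,
            "threshold": sel.threshold,
            "odds_ratio": sel.odds_ratio,
            "p_value": sel.p_value,
            "n_detected": sel.n_detected,
            "n_overlap_db": sel.n_overlap_db,
        }
        for m, sel in sorted(selections.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "strategy", "threshold", "odds_ratio",
                 "p_value", "n_detected", "n_overlap_db"],
    )


def integrate_mtps(
    selections: dict[str, RankedCombination],
    detections: dict[tuple[str, float], DetectionSet],
    correlations: dict[str, pd.DataFrame],
    db: MTPDatabase,
    db_only: bool = False,
) -> pd.DataFrame:
    """Union of each miRNA's selected detection set, annotated per pair.

    Each integrated pair carries its Pearson r, the selecting strategy and
    threshold, and whether it is present in the database.  ``db_only``
    restricts the output to database-overlapping pairs (the subset used
    for downstream functional analysis).
    """
    rows = []
    for mirna_id, sel in sorted(selections.items()):
        key = (sel.strategy, sel.threshold)
        if key not in detections:
            raise KeyError(
                f"selection for {mirna_id} references missing detection set "
                f"{key!r}"
            )
        det = detections[key]
        corr = correlations[sel.strategy]
        r_lookup = dict(zip(
            zip(corr["mirna_id"], corr["gene_id"]), corr["r"]
        ))
        for m, g in sorted(det.pairs):
            if m != mirna_id:
                continue
            in_db = (m, g) in db.pairs
            if db_only and not in_db:
                continue
            rows.append({
                "mirna_id": m,
                "gene_id": g,
                "correlation": r_lookup.get((m, g)),
                "strategy": sel.strategy,
                "threshold": sel.threshold,
                "in_database": in_db,
            })
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "gene_id", "correlation", "strategy",
                 "threshold", "in_database"],
    )
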