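"""Odds ratios, exact over-representation tests and benchmark metrics.

Each (strategy, threshold) detection set is compared with the database of
predicted/validated miRNA-target pairs over a *pair universe*:

* overall scope — all expressed-miRNA x expressed-gene pairs, pooled;
* specific scope — one miRNA's pairs with the expressed genes.

The 2x2 table is (a = detected & in db, b = detected & not in db,
S_d = not detected & in db, R = not detected & not in db) and the odds
ratio is (a/b) / (S_d/R) = aR / (b S_d).  Over-representation is tested
one-sided with Fisher's exact test (P(X >= a) under the hypergeometric
null with fixed margins).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats as sps

from cormit.data_io import MTPDatabase
from cormit.strategies import STRATEGY_ORDER, DetectionSet


class PairUniverse:
    """The Cartesian product universe mirnas x genes, held implicitly.

    Behaves like a set of (mirna_id, gene_id) tuples for membership and
    size, without materializing the product.
    """

    def __init__(self, mirnas: Iterable[str], genes: Iterable[str]) -> None:
        self.mirnas = frozenset(mirnas)
        self.genes = frozenset(genes)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        m, g = pair
        return m in self.mirnas and g in self.genes

    def __len__(self) -> int:
        return len(self.mirnas) * len(self.genes)

    def filter_pairs(self, pairs: set[tuple[str, str]]) -> set[tuple[str, str]]:
        return {p for p in pairs if p in self}


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 detected-vs-database counts over a pair universe."""

    a: int    # detected and in database
    b: int    # detected, not in database
    s_d: int  # not detected, in database
    r: int    # not detected, not in database

    def __post_init__(self) -> None:
        for name in ("a", "b", "s_d", "r"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.a + self.b + self.s_d + self.r

    @property
    def n_detected(self) -> int:
        return self.a + self.b

    @property
    def n_db(self) -> int:
        return self.a + self.s_d


def build_contingency(
    detected: DetectionSet | set[tuple[str, str]],
    db: MTPDatabase | set[tuple[str, str]],
    universe,
) -> ContingencyTable:
    """Count the 2x2 overlap of a detection set with the database.

    Database pairs outside the universe (unexpressed genes or miRNAs) are
    excluded before counting.  ``universe`` may be an explicit pair set or
    a :class:`PairUniverse`.
    """
    det = detected.pairs if isinstance(detected, DetectionSet) else detected
    db_pairs = db.pairs if isinstance(db, MTPDatabase) else db
    outside = {p for p in det if p not in universe}
    if outside:
        raise ValueError(
            f"{len(outside)} detected pair(s) outside the universe, "
            f"e.g. {sorted(outside)[0]!r}"
        )
    if isinstance(universe, PairUniverse):
        dbu = universe.filter_pairs(db_pairs)
        n_universe = len(universe)
    else:
        dbu = db_pairs & set(universe)
        n_universe = len(set(universe))
    a = len(det & dbu)
    b = len(det) - a
    s_d = len(dbu) - a
    r = n_universe - a - b - s_d
    return ContingencyTable(a=a, b=b, s_d=s_d, r=r)


def odds_ratio(t: ContingencyTable, zero_correction: bool = False) -> float:
    """Cross-product odds ratio aR / (b S_d).

    With ``zero_correction`` the Haldane-Anscombe 0.5 is added to every
    cell when any cell is zero, keeping the ratio finite.  NaN is returned
    for degenerate tables: empty universe, or no database pair inside the
    universe (a + S_d = 0), where over-representation is undefined.
    """
    if t.total == 0 or t.n_db == 0:
        return np.nan
    a, b, s_d, r = float(t.a), float(t.b), float(t.s_d), float(t.r)
    if zero_correction and min(a, b, s_d, r) == 0:
        a, b, s_d, r = a + 0.5, b + 0.5, s_d + 0.5, r + 0.5
    num, den = a * r, b * s_d
    if den == 0:
        return np.inf if num > 0 else np.nan
    return num / den


def fisher_exact_greater(t: ContingencyTable) -> float:
    """One-sided exact over-representation p-value, P(X >= a).

    The null is hypergeometric with the table's margins.  Degenerate
    (empty-universe) tables return NaN; a = 0 always gives p = 1.
    """
    if t.total == 0:
        return np.nan
    _or, p = sps.fisher_exact(
        [[t.a, t.b], [t.s_d, t.r]], alternative="greater"
    )
    return float(p)


def benchmark_metrics(
    t: ContingencyTable,
) -> tuple[float, float, float, float]:
    """(precision, recall, specificity, accuracy); any 0/0 gives NaN."""
    def _ratio(num: int, den: int) -> float:
        return num / den if den else np.nan

    precision = _ratio(t.a, t.a + t.b)
    recall = _ratio(t.a, t.a + t.s_d)
    specificity = _ratio(t.r, t.b + t.r)
    accuracy = _ratio(t.a + t.r, t.total)
    return precision, recall, specificity, accuracy


@dataclass
class StrategyEvaluation:
    """Odds ratio, exact p and benchmark metrics for one combination."""

    scope: str  # "overall" or a mirna_id
    strategy: str
    threshold: float
    table: ContingencyTable
    odds_ratio: float
    p_value: float
    precision: float
    recall: float
    specificity: float
    accuracy: float


def _evaluate_one(
    scope: str,
    strategy: str,
    threshold: float,
    detected: set[tuple[str, str]],
    db,
    universe,
    zero_correction: bool,
) -> StrategyEvaluation:
    t = build_contingency(detected, db, universe)
    prec, rec, spec, acc = benchmark_metrics(t)
    return StrategyEvaluation(
        scope=scope,
        strategy=strategy,
        threshold=threshold,
        table=t,
        odds_ratio=odds_ratio(t, zero_correction=zero_correction),
        p_value=fisher_exact_greater(t),
        precision=prec, recall=rec, specificity=spec, accuracy=acc,
    )


def evaluate_overall(
    detections: dict[tuple[str, float], DetectionSet],
    db: MTPDatabase,
    universe: PairUniverse,
    zero_correction: bool = True,
) -> list[StrategyEvaluation]:
    """One evaluation per (strategy, threshold) over the pooled universe."""
    out = []
    for (strategy, threshold), det in _ordered_items(detections):
        out.append(_evaluate_one(
            "overall", strategy, threshold, det.pairs, db, universe,
            zero_correction,
        ))
    return out


def evaluate_specific(
    detections: dict[tuple[str, float], DetectionSet],
    db: MTPDatabase,
    expressed_genes: Iterable[str],
    mirna_id: str,
    zero_correction: bool = True,
) -> list[StrategyEvaluation]:
    """Per-(strategy, threshold) evaluations restricted to one miRNA.

    The universe is {mirna} x expressed genes, so the same miRNA appears in
    numerator and denominator of the odds ratio, removing the bias from
    unequal database representation across miRNAs.
    """
    universe = PairUniverse([mirna_id], expressed_genes)
    out = []
    for (strategy, threshold), det in _ordered_items(detections):
        mine = {p for p in det.pairs if p[0] == mirna_id}
        out.append(_evaluate_one(
            mirna_id, strategy, threshold, mine, db, universe,
            zero_correction,
        ))
    return out


def _ordered_items(detections):
    """Iterate detections in (canonical strategy, ascending threshold) order."""
    idx = {name: i for i, name in enumerate(STRATEGY_ORDER)}
    return sorted(
        detections.items(),
        key=lambda kv: (idx.get(kv[0][0], len(idx)), kv[0][1]),
    )
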