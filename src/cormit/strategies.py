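"""The seven correlation strategies, pair correlations and threshold detection.

A strategy pairs a gene representative (Cg = gene CPM, Eg = gene-module
eigengene, Hg = gene-module hub) with a miRNA representative (Cm, Em, Hm).
The two combinations that would correlate miRNA modules against individual
gene CPM profiles (Cg_Em, Cg_Hm) are excluded, leaving seven strategies.

Detection applies a Pearson threshold grid: anti-correlation mode keeps
pairs with r below thresholds -0.90 ... -0.50 (step 0.05); positive mode
keeps pairs with r above 0.50 ... 0.90.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cormit.profiles import RepresentativeMap

_REP_KIND = {
    "Cg": "cpm_feature", "Eg": "eigengene", "Hg": "hub",
    "Cm": "cpm_feature", "Em": "eigengene", "Hm": "hub",
}

#: canonical strategy order used everywhere results are reported or ties broken
STRATEGY_ORDER = ("Cg_Cm", "Eg_Cm", "Hg_Cm", "Eg_Em", "Eg_Hm", "Hg_Em", "Hg_Hm")

FORBIDDEN = {("Cg", "Em"), ("Cg", "Hm")}


@dataclass(frozen=True)
class StrategySpec:
    """One (gene representative, miRNA representative) combination."""

    gene_rep: str   # Cg | Eg | Hg
    mirna_rep: str  # Cm | Em | Hm

    def __post_init__(self) -> None:
        if self.gene_rep not in ("Cg", "Eg", "Hg"):
            raise ValueError(f"bad gene representative {self.gene_rep!r}")
        if self.mirna_rep not in ("Cm", "Em", "Hm"):
            raise ValueError(f"bad miRNA representative {self.mirna_rep!r}")
        if (self.gene_rep, self.mirna_rep) in FORBIDDEN:
            raise ValueError(
                f"{self.gene_rep}_{self.mirna_rep} is not a valid strategy"
            )

    @property
    def name(self) -> str:
        return f"{self.gene_rep}_{self.mirna_rep}"

    @property
    def gene_rep_kind(self) -> str:
        return _REP_KIND[self.gene_rep]

    @property
    def mirna_rep_kind(self) -> str:
        return _REP_KIND[self.mirna_rep]


def enumerate_strategies() -> list[StrategySpec]:
    """The seven valid strategies in canonical order."""
    return [StrategySpec(*name.split("_")) for name in STRATEGY_ORDER]


def threshold_grid(direction: str) -> list[float]:
    """Threshold values for a detection direction.

    ``lower`` (anti-correlation): -0.90 ... -0.50 step 0.05, ascending.
    ``higher`` (positive): 0.50 ... 0.90 step 0.05, ascending.
    """
    if direction == "lower":
        return [round(-0.90 + 0.05 * i, 2) for i in range(9)]
    if direction == "higher":
        return [round(0.50 + 0.05 * i, 2) for i in range(9)]
    raise ValueError(f"direction must be 'lower' or 'higher', got {direction!r}")


def candidate_pairs(
    mirnas: set[str] | list[str], genes: set[str] | list[str]
) -> set[tuple[str, str]]:
    """Cartesian product of candidate miRNAs x genes."""
    mirnas, genes = set(mirnas), set(genes)
    if not mirnas:
        raise ValueError(
            "empty candidate miRNA set (no DEMs?); "
            "consider --mirna-set expressed"
        )
    if not genes:
        raise ValueError("empty candidate gene set")
    return {(m, g) for m in mirnas for g in genes}


@dataclass
class DetectionSet:
    """Pairs detected by one (strategy, threshold) combination."""

    strategy: str
    threshold: float
    direction: str
    pairs: set[tuple[str, str]] = field(default_factory=set)


def _zscore_or_none(values: np.ndarray) -> np.ndarray | None:
    """Centered profile scaled to unit sum of squares; None if constant."""
    c = values - values.mean()
    ss = float((c ** 2).sum())
    if ss == 0:
        return None
    return c / np.sqrt(ss)


def pair_correlations(
    gene_reps: RepresentativeMap,
    mirna_reps: RepresentativeMap,
    pairs: set[tuple[str, str]],
    strategy: StrategySpec,
) -> pd.DataFrame:
    """Pearson correlation for every candidate pair under one strategy.

    Correlations are computed once per unique (gene representative, miRNA
    representative) combination and broadcast to all member pairs, so the
    pair (g, m) under a module strategy receives the correlation of g's
    module representative with m's representative.  r is NaN when either
    representative is missing (unassigned feature under a module strategy)
    or has zero variance.

    Returns a DataFrame with columns mirna_id, gene_id, strategy, r, sorted
    by (mirna_id, gene_id).
    """
    sample_order: tuple[str, ...] | None = None
    for rep_map in (gene_reps, mirna_reps):
        for prof in rep_map.values():
            if sample_order is None:
                sample_order = prof.sample_ids
            elif prof.sample_ids != sample_order:
                raise ValueError(
                    "gene and miRNA matrices must share the same ordered "
                    "sample set"
                )
            break  # all profiles in one map share the matrix sample order

    sorted_pairs = sorted(pairs)
    # unique representative vectors keyed by origin
    cache: dict[tuple[str, str], float] = {}
    gene_z: dict[str, np.ndarray | None] = {}
    mirna_z: dict[str, np.ndarray | None] = {}
    r_values = np.full(len(sorted_pairs), np.nan)
    for i, (m, g) in enumerate(sorted_pairs):
        gp = gene_reps.get(g)
        mp = mirna_reps.get(m)
        if gp is None or mp is None:
            continue
        key = (gp.origin, mp.origin)
        if key not in cache:
            if gp.origin not in gene_z:
                gene_z[gp.origin] = _zscore_or_none(gp.values)
            if mp.origin not in mirna_z:
                mirna_z[mp.origin] = _zscore_or_none(mp.values)
            zg, zm = gene_z[gp.origin], mirna_z[mp.origin]
            cache[key] = np.nan if zg is None or zm is None \
                else float(np.dot(zg, zm))
        r_values[i] = cache[key]
    return pd.DataFrame({
        "mirna_id": [m for m, _ in sorted_pairs],
        "gene_id": [g for _, g in sorted_pairs],
        "strategy": strategy.name,
        "r": np.clip(r_values, -1.0, 1.0),
    })


def detect_mtps(
    corr: pd.DataFrame, threshold: float, direction: str
) -> DetectionSet:
    """Threshold a correlation table into a detection set.

    ``lower`` keeps pairs with r strictly below the threshold, ``higher``
    strictly above; NaN correlations are never detected.
    """
    if direction not in ("lower", "higher"):
        raise ValueError(f"direction must be 'lower' or 'higher', got {direction!r}")
    r = corr["r"].to_numpy()
    if direction == "lower":
        mask = r < threshold
    else:
        mask = r > threshold
    mask &= np.isfinite(r)
    hit = corr.loc[mask]
    strategy = str(corr["strategy"].iloc[0]) if len(corr) else ""
    return DetectionSet(
        strategy=strategy,
        threshold=threshold,
        direction=direction,
        pairs=set(zip(hit["mirna_id"], hit["gene_id"])),
    )
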