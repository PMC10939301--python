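"""Tabular input/output with strict validation.

All inputs are plain TSV (tab-separated, UTF-8, ``#`` comment lines ignored,
no quoting).  Every reader returns a validated in-memory structure so the
downstream modules never have to re-check shapes, duplicates or ranges.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("cormit")

#: module id used for features that belong to no co-expression module
#: (the WGCNA "grey" equivalent)
UNASSIGNED_MODULE = "0"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Features x samples expression table (raw counts or CPM).

    Parameters
    ----------
    values
        DataFrame indexed by feature id with sample ids as columns.
        All entries must be finite and non-negative.
    kind
        ``"gene"`` or ``"mirna"``.
    normalized
        True when the values are already library-size normalized (CPM).
    """

    values: pd.DataFrame
    kind: str
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "mirna"):
            raise ValueError(f"kind must be 'gene' or 'mirna', got {self.kind!r}")
        dup_f = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_f):
            raise ValueError(f"duplicate feature IDs: {sorted(map(str, dup_f))}")
        dup_s = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_s):
            raise ValueError(f"duplicate sample IDs: {sorted(map(str, dup_s))}")
        if self.values.shape[1] < 3:
            raise ValueError(
                f"at least 3 samples required for Pearson correlation, "
                f"got {self.values.shape[1]}"
            )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ModuleAssignment:
    """Map feature id -> module id; module "0" means unassigned."""

    feature_to_module: dict[str, str] = field(default_factory=dict)

    def module_of(self, feature_id: str) -> str:
        """Module of a feature; features absent from the map are unassigned."""
        return self.feature_to_module.get(feature_id, UNASSIGNED_MODULE)

    def members(self, module_id: str) -> list[str]:
        """Sorted member ids of one module."""
        return sorted(
            f for f, m in self.feature_to_module.items() if m == module_id
        )

    def module_ids(self) -> list[str]:
        """Sorted real module ids (excludes the unassigned sentinel)."""
        return sorted(
            {m for m in self.feature_to_module.values() if m != UNASSIGNED_MODULE}
        )


@dataclass
class FeatureSet:
    """A named set of feature ids (DEGs, DEMs, or expressed features)."""

    ids: set[str]
    role: str  # DEG | DEM | expressed

    def restrict_to(self, universe: set[str] | list[str]) -> "FeatureSet":
        """Drop ids outside *universe*, warning about each dropped id."""
        uni = set(universe)
        missing = sorted(self.ids - uni)
        if missing:
            logger.warning(
                "%s list: %d id(s) not in the expression matrix, dropped: %s",
                self.role, len(missing), ", ".join(missing[:10]),
            )
        return FeatureSet(ids=self.ids & uni, role=self.role)


@dataclass
class MTPDatabase:
    """De-duplicated set of (mirna_id, gene_id) predicted/validated pairs."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for m, g in self.pairs:
            if not m or not g:
                raise ValueError(f"empty ID in database pair {(m, g)!r}")

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv_rows(path: str | Path) -> list[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment non-blank lines."""
    rows = []
    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n").rstrip("\r")
            if not stripped or stripped.startswith("#"):
                continue
            rows.append((lineno, stripped.split("\t")))
    return rows


def read_expression_table(
    path: str | Path,
    kind: str,
    normalized: bool = False,
    lowercase_ids: bool = False,
) -> ExpressionMatrix:
    """Read a features x samples TSV (header = sample ids, col 0 = feature id)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(
        path, sep="\t", index_col=0, comment="#",
        quoting=csv.QUOTE_NONE, dtype=str,
    )
    df.index = df.index.astype(str)
    if lowercase_ids:
        df.index = df.index.str.lower()
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise ValueError(
            f"{path.name}: duplicated feature row(s): {sorted(map(str, dup))}"
        )
    try:
        vals = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path.name}: non-numeric cell: {exc}") from exc
    return ExpressionMatrix(values=vals, kind=kind, normalized=normalized)


def read_module_assignment(
    path: str | Path, lowercase_ids: bool = False
) -> ModuleAssignment:
    """Read a two-column (feature_id, module_id) TSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    mapping: dict[str, str] = {}
    for lineno, fields in _read_tsv_rows(path):
        if len(fields) != 2:
            raise ValueError(
                f"{path.name}:{lineno}: expected 2 columns, got {len(fields)}"
            )
        fid, mod = fields
        if lowercase_ids:
            fid = fid.lower()
        if fid in mapping and mapping[fid] != mod:
            raise ValueError(
                f"{path.name}:{lineno}: feature {fid!r} assigned to both "
                f"{mapping[fid]!r} and {mod!r}"
            )
        mapping[fid] = mod
    return ModuleAssignment(feature_to_module=mapping)


def read_feature_list(
    path: str | Path, role: str, lowercase_ids: bool = False
) -> FeatureSet:
    """Read a one-id-per-line list (DEG or DEM)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    ids: set[str] = set()
    for _lineno, fields in _read_tsv_rows(path):
        fid = fields[0].strip()
        if fid:
            ids.add(fid.lower() if lowercase_ids else fid)
    return FeatureSet(ids=ids, role=role)


def read_mtp_database(
    path: str | Path, lowercase_ids: bool = False
) -> MTPDatabase:
    """Read a two-column (mirna_id, gene_id) pair table; duplicates dropped."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    pairs: set[tuple[str, str]] = set()
    n_rows = 0
    for lineno, fields in _read_tsv_rows(path):
        if len(fields) != 2:
            raise ValueError(
                f"{path.name}:{lineno}: expected 2 columns, got {len(fields)}"
            )
        m, g = (f.strip() for f in fields)
        if lowercase_ids:
            m, g = m.lower(), g.lower()
        n_rows += 1
        pairs.add((m, g))
    dropped = n_rows - len(pairs)
    if dropped:
        logger.info("%s: dropped %d duplicate pair(s)", path.name, dropped)
    return MTPDatabase(pairs=pairs)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

OVERALL_COLUMNS = ["strategy", "threshold", "a", "b", "S_d", "R",
                   "odds_ratio", "p_value"]
SPECIFIC_COLUMNS = ["mirna_id", "strategy", "threshold", "a", "b", "S_d", "R",
                    "odds_ratio", "p_value",
                    "precision", "recall", "specificity", "accuracy"]
SELECTION_COLUMNS = ["mirna_id", "strategy", "threshold", "odds_ratio",
                     "p_value", "n_detected", "n_overlap_db"]
INTEGRATED_COLUMNS = ["mirna_id", "gene_id", "correlation", "strategy",
                      "in_database"]
ROBUSTNESS_COLUMNS = ["mirna_id", "replicate", "rank_of_original_top",
                      "was_significant"]


def _write_tsv(df: pd.DataFrame, columns: list[str], path: Path) -> None:
    out = df if len(df) else pd.DataFrame(columns=columns)
    out = out.loc[:, columns]
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_results_tables(results, out_dir: str | Path) -> dict[str, Path]:
    """Write the evaluation/selection/integration/robustness TSVs.

    *results* is any object exposing ``overall_eval``, ``specific_eval``,
    ``selection``, ``integrated`` and (optionally None) ``robustness``
    DataFrames with the canonical column sets.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    specs = [
        ("overall_eval.tsv", results.overall_eval, OVERALL_COLUMNS),
        ("specific_eval.tsv", results.specific_eval, SPECIFIC_COLUMNS),
        ("selection.tsv", results.selection, SELECTION_COLUMNS),
        ("integrated_mtps.tsv", results.integrated, INTEGRATED_COLUMNS),
    ]
    rob = getattr(results, "robustness", None)
    if rob is not None:
        specs.append(("robustness.tsv", rob, ROBUSTNESS_COLUMNS))
    for name, df, cols in specs:
        p = out_dir / name
        _write_tsv(df, cols, p)
        written[name] = p
    return written


# -- write helpers used by the simulator and tests --------------------------

def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="feature_id",
                         float_format="%.10g")


def write_module_assignment(assign: ModuleAssignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for fid in sorted(assign.feature_to_module):
            fh.write(f"{fid}\t{assign.feature_to_module[fid]}\n")


def write_feature_list(fs: FeatureSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for fid in sorted(fs.ids):
            fh.write(fid + "\n")


def write_mtp_database(db: MTPDatabase, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m, g in sorted(db.pairs):
            fh.write(f"{m}\t{g}\n")
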