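"""Seeded synthetic datasets with planted miRNA-target regulation.

The generator emulates the statistical structure the correlation strategies
assume: co-expressed gene and miRNA modules driven by shared latent sample
factors, a handful of regulator miRNAs (the DEM set) whose planted targets
are coupled to them with a configurable Pearson correlation, and a
partially overlapping pair database (a configurable fraction of the planted
pairs plus random decoys).

Two regulatory architectures are supported:

``individual``
    each target's own profile is coupled to its regulator; targets are left
    unassigned to modules, so individual-profile strategies (Cg_Cm) carry
    the signal;
``module``
    each regulator's targets form one dedicated gene module whose *latent
    factor* is coupled to the regulator while individual member profiles
    are noisy; the module eigengene then tracks the regulator better than
    any single member, so eigengene strategies (Eg_Cm) carry the signal.

Expression values are scaled log-normal ("count-like"): latent Gaussian
profiles are exponentiated around a per-feature baseline.  The downstream
method consumes CPM correlations, so correlation structure — not the
marginal count distribution — is what matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cormit.data_io import (
    ExpressionMatrix,
    FeatureSet,
    ModuleAssignment,
    MTPDatabase,
    write_expression_table,
    write_feature_list,
    write_module_assignment,
    write_mtp_database,
)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_samples: int = 12
    n_genes: int = 500
    n_mirnas: int = 60
    n_gene_modules: int = 6
    n_mirna_modules: int = 4
    n_regulator_mirnas: int = 3
    targets_per_regulator: int = 15
    coupling: float = -0.9          # Pearson target on the latent scale
    db_truth_fraction: float = 0.8  # share of planted pairs in the database
    db_decoy_count: int = 150       # random non-planted pairs added
    direction: str = "anti"         # anti | positive | mixed
    architecture: str = "individual"  # individual | module
    within_module_corr: float = 0.7   # background module coherence
    target_module_corr: float = 0.55  # member coherence, module architecture
    log_sigma: float = 0.3            # log-scale dispersion of counts
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_mirnas,
               self.n_regulator_mirnas, self.targets_per_regulator) < 1:
            raise ValueError("all size parameters must be positive")
        if abs(self.coupling) > 1:
            raise ValueError("|coupling| must be <= 1")
        if not 0 <= self.db_truth_fraction <= 1:
            raise ValueError("db_truth_fraction must be in [0, 1]")
        if self.db_decoy_count < 0:
            raise ValueError("db_decoy_count must be >= 0")
        if self.direction not in ("anti", "positive", "mixed"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.architecture not in ("individual", "module"):
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.n_regulator_mirnas > self.n_mirnas:
            raise ValueError("more regulators than miRNAs")
        if self.n_regulator_mirnas * self.targets_per_regulator > self.n_genes:
            raise ValueError("targets_per_regulator x regulators exceeds n_genes")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    planted_pairs: set[tuple[str, str, int]] = field(default_factory=set)
    regulators: list[str] = field(default_factory=list)
    architecture: str = "individual"

    @property
    def pairs(self) -> set[tuple[str, str]]:
        return {(m, g) for m, g, _s in self.planted_pairs}

    def targets_of(self, mirna_id: str) -> set[str]:
        return {g for m, g, _s in self.planted_pairs if m == mirna_id}


@dataclass
class SyntheticDataset:
    genes: ExpressionMatrix
    mirnas: ExpressionMatrix
    gene_modules: ModuleAssignment
    mirna_modules: ModuleAssignment
    degs: FeatureSet
    dems: FeatureSet
    db: MTPDatabase
    truth: SyntheticTruth
    config: SyntheticConfig


def _coupling_signs(config: SyntheticConfig) -> list[int]:
    if config.direction == "anti":
        return [-1] * config.n_regulator_mirnas
    if config.direction == "positive":
        return [1] * config.n_regulator_mirnas
    return [(-1) ** j for j in range(config.n_regulator_mirnas)]


def _mix(latent: np.ndarray, weight: float, noise: np.ndarray) -> np.ndarray:
    """weight-correlated blend of a latent factor with independent noise."""
    return np.sqrt(weight) * latent + np.sqrt(1.0 - weight) * noise


def _to_counts(latent_rows: np.ndarray, baselines: np.ndarray,
               sigma: float) -> np.ndarray:
    """Exponentiate latent profiles around per-feature log baselines."""
    return np.exp(baselines[:, None] + sigma * latent_rows)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full coherent input bundle; deterministic given the seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    gene_ids = [f"g{i:04d}" for i in range(1, config.n_genes + 1)]
    mirna_ids = [f"mir-{i:03d}" for i in range(1, config.n_mirnas + 1)]
    sample_ids = [f"s{j:02d}" for j in range(1, n + 1)]

    c = abs(config.coupling)
    signs = _coupling_signs(config)
    regulators = mirna_ids[: config.n_regulator_mirnas]

    # --- regulator latents and planted targets -----------------------------
    reg_latent = rng.standard_normal((config.n_regulator_mirnas, n))
    n_targets = config.n_regulator_mirnas * config.targets_per_regulator
    target_blocks = [
        gene_ids[j * config.targets_per_regulator:
                 (j + 1) * config.targets_per_regulator]
        for j in range(config.n_regulator_mirnas)
    ]

    gene_latent = np.empty((config.n_genes, n))
    gene_modules: dict[str, str] = {}
    planted: set[tuple[str, str, int]] = set()

    if c > 0:
        for j, block in enumerate(target_blocks):
            for g in block:
                planted.add((regulators[j], g, signs[j]))

    # planted target profiles
    for j, block in enumerate(target_blocks):
        u = reg_latent[j]
        if config.architecture == "module" and c > 0:
            # dedicated module whose latent is coupled to the regulator;
            # members are only loosely coupled individually
            z = _mix(signs[j] * u, c ** 2, rng.standard_normal(n)) \
                if c < 1 else signs[j] * u
            for g in block:
                gi = gene_ids.index(g)
                gene_latent[gi] = _mix(z, config.target_module_corr,
                                       rng.standard_normal(n))
                gene_modules[g] = f"GR{j + 1}"
        else:
            for g in block:
                gi = gene_ids.index(g)
                if c > 0:
                    gene_latent[gi] = _mix(signs[j] * u, c ** 2,
                                           rng.standard_normal(n))
                else:
                    gene_latent[gi] = rng.standard_normal(n)
                # individual architecture: targets stay unassigned so the
                # signal lives only at the individual-profile level

    # --- background genes: co-expression modules + unassigned tail --------
    background = gene_ids[n_targets:]
    n_unassigned = max(1, len(background) // 10)
    module_genes = background[: len(background) - n_unassigned]
    per_module = np.array_split(np.arange(len(module_genes)),
                                config.n_gene_modules)
    w = config.within_module_corr
    for k, idxs in enumerate(per_module):
        z = rng.standard_normal(n)
        for i in idxs:
            g = module_genes[i]
            gi = gene_ids.index(g)
            gene_latent[gi] = _mix(z, w, rng.standard_normal(n))
            gene_modules[g] = f"GM{k + 1}"
    for g in background[len(module_genes):]:
        gene_latent[gene_ids.index(g)] = rng.standard_normal(n)

    # --- miRNAs: regulators unassigned, background in modules -------------
    mirna_latent = np.empty((config.n_mirnas, n))
    mirna_modules: dict[str, str] = {}
    for j in range(config.n_regulator_mirnas):
        mirna_latent[j] = reg_latent[j]
    bg_mirnas = mirna_ids[config.n_regulator_mirnas:]
    n_un_mir = max(1, len(bg_mirnas) // 5)
    mod_mirnas = bg_mirnas[: len(bg_mirnas) - n_un_mir]
    per_mod = np.array_split(np.arange(len(mod_mirnas)),
                             config.n_mirna_modules)
    for k, idxs in enumerate(per_mod):
        z = rng.standard_normal(n)
        for i in idxs:
            m = mod_mirnas[i]
            mi = mirna_ids.index(m)
            mirna_latent[mi] = _mix(z, w, rng.standard_normal(n))
            mirna_modules[m] = f"MM{k + 1}"
    for m in bg_mirnas[len(mod_mirnas):]:
        mirna_latent[mirna_ids.index(m)] = rng.standard_normal(n)

    # --- exponentiate to count-like values ---------------------------------
    gene_base = rng.normal(np.log(200.0), 1.0, size=config.n_genes)
    mirna_base = rng.normal(np.log(200.0), 1.0, size=config.n_mirnas)
    genes = ExpressionMatrix(
        values=pd.DataFrame(
            _to_counts(gene_latent, gene_base, config.log_sigma),
            index=gene_ids, columns=sample_ids,
        ),
        kind="gene", normalized=False,
    )
    mirnas = ExpressionMatrix(
        values=pd.DataFrame(
            _to_counts(mirna_latent, mirna_base, config.log_sigma),
            index=mirna_ids, columns=sample_ids,
        ),
        kind="mirna", normalized=False,
    )

    # --- database: sampled truth + decoys ----------------------------------
    truth_pairs = sorted((m, g) for m, g, _s in planted)
    n_true_in_db = int(np.floor(config.db_truth_fraction * len(truth_pairs)))
    db_pairs: set[tuple[str, str]] = set()
    if truth_pairs and n_true_in_db:
        chosen = rng.choice(len(truth_pairs), size=n_true_in_db, replace=False)
        db_pairs.update(truth_pairs[i] for i in chosen)
    planted_set = set(truth_pairs)
    if config.db_decoy_count:
        total = config.n_mirnas * config.n_genes
        decoys_added = 0
        for flat in rng.permutation(total):
            pair = (mirna_ids[flat // config.n_genes],
                    gene_ids[flat % config.n_genes])
            if pair in planted_set or pair in db_pairs:
                continue
            db_pairs.add(pair)
            decoys_added += 1
            if decoys_added == config.db_decoy_count:
                break

    truth = SyntheticTruth(
        planted_pairs=planted,
        regulators=list(regulators),
        architecture=config.architecture,
    )
    return SyntheticDataset(
        genes=genes,
        mirnas=mirnas,
        gene_modules=ModuleAssignment(feature_to_module=gene_modules),
        mirna_modules=ModuleAssignment(feature_to_module=mirna_modules),
        degs=FeatureSet(ids={g for _m, g, _s in planted}, role="DEG"),
        dems=FeatureSet(ids=set(regulators), role="DEM"),
        db=MTPDatabase(pairs=db_pairs),
        truth=truth,
        config=config,
    )


def null_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Dataset with no planted association (requires coupling == 0)."""
    if config.coupling != 0:
        raise ValueError("null_dataset requires coupling == 0")
    return generate_dataset(config)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write all input TSVs plus the ground truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_table(dataset.genes, out / "genes.tsv")
    write_expression_table(dataset.mirnas, out / "mirnas.tsv")
    write_module_assignment(dataset.gene_modules, out / "gene_modules.tsv")
    write_module_assignment(dataset.mirna_modules, out / "mirna_modules.tsv")
    write_feature_list(dataset.degs, out / "degs.txt")
    write_feature_list(dataset.dems, out / "dems.txt")
    write_mtp_database(dataset.db, out / "mtp_db.tsv")
    with open(out / "truth.tsv", "w", encoding="utf-8") as fh:
        fh.write("mirna_id\tgene_id\tsign\n")
        for m, g, s in sorted(dataset.truth.planted_pairs):
            fh.write(f"{m}\t{g}\t{s}\n")
    return {p.name: p for p in sorted(out.iterdir())}
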