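import numpy as np
import pandas as pd
import pytest

from cormit.data_io import ExpressionMatrix, ModuleAssignment
from cormit.pipeline import RunConfig, RunInputs, run_core
from cormit.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def small_expr():
    """5 genes x 6 samples with two planted co-expression patterns."""
    rng = np.random.default_rng(42)
    base = rng.normal(size=6)
    values = pd.DataFrame(
        {
            f"s{j}": col
            for j, col in enumerate(
                np.column_stack([
                    10 + 2 * base,
                    20 + 4 * base + rng.normal(scale=0.1, size=6),
                    5 - base,
                    rng.uniform(1, 10, size=6),
                    rng.uniform(1, 10, size=6),
                ])
            )
        },
        index=["g1", "g2", "g3", "g4", "g5"],
    )
    values = values.clip(lower=0.0)
    return ExpressionMatrix(values=values, kind="gene", normalized=True)


@pytest.fixture
def small_modules():
    return ModuleAssignment({"g1": "M1", "g2": "M1", "g3": "M1",
                             "g4": "M2", "g5": "0"})


def run_synthetic(seed=0, architecture="individual", robustness=False,
                  mirna_set="dem", zero_correction=True, corr_type="lower",
                  **overrides):
    """Full in-memory pipeline run on one synthetic dataset."""
    ds = generate_dataset(
        SyntheticConfig(seed=seed, architecture=architecture, **overrides)
    )
    inputs = RunInputs(
        genes=ds.genes, mirnas=ds.mirnas,
        gene_modules=ds.gene_modules, mirna_modules=ds.mirna_modules,
        dems=ds.dems, db=ds.db, degs=ds.degs,
    )
    config = RunConfig(
        genes="-", mirnas="-", gene_modules="-", mirna_modules="-",
        dems="-", db="-", out_dir="-", robustness=robustness,
        rob_reps=10 if robustness else 40, seed=seed,
        mirna_set=mirna_set, zero_correction=zero_correction,
        corr_type=corr_type,
    )
    return ds, run_core(inputs, config)


@pytest.fixture(scope="session")
def default_run():
    """One shared default-architecture pipeline run (seed 1)."""
    return run_synthetic(seed=1)
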