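import itertools

import numpy as np
import pandas as pd
import pytest

from cormit.data_io import ExpressionMatrix, ModuleAssignment
from cormit.profiles import build_representatives
from cormit.strategies import (
    StrategySpec,
    candidate_pairs,
    detect_mtps,
    enumerate_strategies,
    pair_correlations,
    threshold_grid,
)


def expr(rows, index, kind="gene", columns=None):
    arr = np.asarray(rows, dtype=float)
    cols = columns or [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(arr, index=index, columns=cols),
        kind=kind, normalized=True,
    )


class TestEnumeration:
    def test_exactly_seven_in_canonical_order(self):
        names = [s.name for s in enumerate_strategies()]
        assert names == ["Cg_Cm", "Eg_Cm", "Hg_Cm", "Eg_Em",
                         "Eg_Hm", "Hg_Em", "Hg_Hm"]

    def test_mirna_module_vs_gene_cpm_combinations_forbidden(self):
        names = {s.name for s in enumerate_strategies()}
        assert "Cg_Em" not in names and "Cg_Hm" not in names
        for bad in (("Cg", "Em"), ("Cg", "Hm")):
            with pytest.raises(ValueError):
                StrategySpec(*bad)

    def test_forbidden_pairs_are_the_only_exclusions(self):
        valid = {f"{g}_{m}" for g, m in
                 itertools.product(["Cg", "Eg", "Hg"], ["Cm", "Em", "Hm"])}
        assert {s.name for s in enumerate_strategies()} \
            == valid - {"Cg_Em", "Cg_Hm"}


class TestThresholdGrid:
    def test_anti_grid(self):
        g = threshold_grid("lower")
        assert g == [-0.90, -0.85, -0.80, -0.75, -0.70,
                     -0.65, -0.60, -0.55, -0.50]

    def test_positive_grid(self):
        assert threshold_grid("higher") == [0.50, 0.55, 0.60, 0.65, 0.70,
                                            0.75, 0.80, 0.85, 0.90]

    def test_unknown_direction(self):
        with pytest.raises(ValueError):
            threshold_grid("sideways")


class TestCandidatePairs:
    def test_cartesian_product(self):
        pairs = candidate_pairs({"m1", "m2", "m3"},
                                {f"g{i}" for i in range(100)})
        assert len(pairs) == 300

    def test_single_pair(self):
        assert candidate_pairs({"m"}, {"g"}) == {("m", "g")}

    def test_empty_mirna_set_advises_flag(self):
        with pytest.raises(ValueError, match="--mirna-set expressed"):
            candidate_pairs(set(), {"g"})


class TestPairCorrelations:
    def _maps(self, gvals, mvals):
        g = expr(gvals, [f"g{i}" for i in range(len(gvals))])
        m = expr(mvals, [f"m{i}" for i in range(len(mvals))], kind="mirna")
        return (build_representatives(g, ModuleAssignment({}), "cpm_feature"),
                build_representatives(m, ModuleAssignment({}), "cpm_feature"))

    def test_perfect_anticorrelation(self):
        gr, mr = self._maps([[1, 2, 3, 4]], [[4, 3, 2, 1]])
        out = pair_correlations(gr, mr, {("m0", "g0")},
                                StrategySpec("Cg", "Cm"))
        assert np.isclose(out["r"].iloc[0], -1.0)

    def test_identical_profiles(self):
        gr, mr = self._maps([[1, 2, 3, 4]], [[2, 4, 6, 8]])
        out = pair_correlations(gr, mr, {("m0", "g0")},
                                StrategySpec("Cg", "Cm"))
        assert np.isclose(out["r"].iloc[0], 1.0)

    def test_matches_textbook_pearson_formula(self):
        x, y = np.array([1., 2, 3, 4]), np.array([2., 1, 4, 3])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        expected = cov / (x.std() * y.std())
        gr, mr = self._maps([x], [y])
        out = pair_correlations(gr, mr, {("m0", "g0")},
                                StrategySpec("Cg", "Cm"))
        assert np.isclose(out["r"].iloc[0], expected)

    def test_missing_representative_gives_na(self):
        g = expr([[1, 2, 3, 4]], ["g0"])
        m = expr([[4, 3, 2, 1]], ["m0"], kind="mirna")
        # unassigned gene has no eigengene representative
        gr = build_representatives(g, ModuleAssignment({"g0": "0"}),
                                   "eigengene")
        mr = build_representatives(m, ModuleAssignment({}), "cpm_feature")
        out = pair_correlations(gr, mr, {("m0", "g0")},
                                StrategySpec("Eg", "Cm"))
        assert np.isnan(out["r"].iloc[0])

    def test_zero_variance_profile_gives_na(self):
        gr, mr = self._maps([[5, 5, 5, 5]], [[1, 2, 3, 4]])
        out = pair_correlations(gr, mr, {("m0", "g0")},
                                StrategySpec("Cg", "Cm"))
        assert np.isnan(out["r"].iloc[0])

    def test_sample_order_mismatch_errors(self):
        g = expr([[1, 2, 3]], ["g0"], columns=["a", "b", "c"])
        m = expr([[1, 2, 3]], ["m0"], kind="mirna", columns=["c", "b", "a"])
        gr = build_representatives(g, ModuleAssignment({}), "cpm_feature")
        mr = build_representatives(m, ModuleAssignment({}), "cpm_feature")
        with pytest.raises(ValueError, match="sample"):
            pair_correlations(gr, mr, {("m0", "g0")},
                              StrategySpec("Cg", "Cm"))

    def test_invariant_to_shared_sample_permutation(self):
        rng = np.random.default_rng(5)
        gvals = rng.uniform(1, 10, size=(3, 6))
        mvals = rng.uniform(1, 10, size=(2, 6))
        perm = rng.permutation(6)
        base = self._corr_all(gvals, mvals)
        permuted = self._corr_all(gvals[:, perm], mvals[:, perm])
        pd.testing.assert_series_equal(base["r"], permuted["r"],
                                       check_exact=False, rtol=1e-9)

    def _corr_all(self, gvals, mvals):
        gr, mr = self._maps(gvals, mvals)
        pairs = candidate_pairs(set(mr), set(gr))
        return pair_correlations(gr, mr, pairs, StrategySpec("Cg", "Cm"))

    def test_module_correlation_broadcast_to_members(self):
        rng = np.random.default_rng(9)
        gvals = rng.uniform(1, 10, size=(4, 6))
        g = expr(gvals, ["g0", "g1", "g2", "g3"])
        m = expr(rng.uniform(1, 10, size=(1, 6)), ["m0"], kind="mirna")
        assign = ModuleAssignment({g_: "M1" for g_ in ["g0", "g1", "g2", "g3"]})
        gr = build_representatives(g, assign, "eigengene")
        mr = build_representatives(m, ModuleAssignment({}), "cpm_feature")
        pairs = candidate_pairs({"m0"}, {"g0", "g1", "g2", "g3"})
        out = pair_correlations(gr, mr, pairs, StrategySpec("Eg", "Cm"))
        assert out["r"].nunique() == 1  # one module -> one broadcast value


class TestDetection:
    def _table(self, rs):
        return pd.DataFrame({
            "mirna_id": [f"m{i}" for i in range(len(rs))],
            "gene_id": [f"g{i}" for i in range(len(rs))],
            "strategy": "Cg_Cm",
            "r": rs,
        })

    def test_strictly_lower_than_threshold(self):
        det = detect_mtps(self._table([-0.95, -0.85, -0.90]), -0.90, "lower")
        assert det.pairs == {("m0", "g0")}  # boundary -0.90 excluded

    def test_higher_direction(self):
        det = detect_mtps(self._table([0.95, 0.85]), 0.90, "higher")
        assert det.pairs == {("m0", "g0")}

    def test_na_never_detected(self):
        det = detect_mtps(self._table([np.nan, -0.99]), -0.5, "lower")
        assert det.pairs == {("m1", "g1")}

    def test_nested_across_grid(self):
        rng = np.random.default_rng(2)
        table = self._table(rng.uniform(-1, 1, size=200))
        grid = threshold_grid("lower")
        sets = [detect_mtps(table, t, "lower").pairs for t in grid]
        for strict, loose in zip(sets, sets[1:]):
            assert strict <= loose


class TestSingletonModuleEquivalence:
    def test_cg_cm_equals_eg_cm_when_every_feature_is_own_module(self):
        """With singleton modules the eigengene is the z-scored feature
        profile, so correlations (and hence detections) coincide with the
        individual-CPM strategy, including sign."""
        rng = np.random.default_rng(21)
        gvals = rng.uniform(1, 100, size=(6, 8))
        mvals = rng.uniform(1, 100, size=(3, 8))
        gids = [f"g{i}" for i in range(6)]
        mids = [f"m{i}" for i in range(3)]
        g = expr(gvals, gids)
        m = expr(mvals, mids, kind="mirna")
        singleton = ModuleAssignment({gid: f"S_{gid}" for gid in gids})
        pairs = candidate_pairs(set(mids), set(gids))
        mr = build_representatives(m, ModuleAssignment({}), "cpm_feature")
        cg = pair_correlations(
            build_representatives(g, ModuleAssignment({}), "cpm_feature"),
            mr, pairs, StrategySpec("Cg", "Cm"))
        eg = pair_correlations(
            build_representatives(g, singleton, "eigengene"),
            mr, pairs, StrategySpec("Eg", "Cm"))
        np.testing.assert_allclose(cg["r"], eg["r"], atol=1e-9)
        for t in threshold_grid("lower"):
            assert detect_mtps(cg, t, "lower").pairs \
                == detect_mtps(eg, t, "lower").pairs
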