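"""Normalization, differential statistics and group quantitation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from glutenquant.quantitation import (
    NormalizedMatrix,
    PipelineConfig,
    differential,
    group_abundance,
    net_gluten_ratio,
    normalize,
    peptide_area,
    validate_quant_table,
    welch_test,
)

REPS = ["GW_1", "GW_2", "GW_3", "GW_4", "MW_1", "MW_2", "MW_3", "MW_4"]
SAMPLE_OF = {r: r[:2] for r in REPS}


def _matrix(rows: dict) -> NormalizedMatrix:
    return NormalizedMatrix(pd.DataFrame(rows, index=REPS).T, dict(SAMPLE_OF))


def _quant_df(rows):
    return pd.DataFrame(rows, columns=["peptide", "protease", "replicate",
                                       "sample", "transition", "area"])


class TestLoadValidation:
    GOOD = [["PEPA", "trypsin", "GW_1", "GW", "t1", 100.0],
            ["PEPA", "trypsin", "MW_1", "MW", "t1", 200.0]]

    def test_well_formed_passes(self):
        assert len(validate_quant_table(_quant_df(self.GOOD))) == 2

    def test_missing_column(self):
        df = _quant_df(self.GOOD).drop(columns=["transition"])
        with pytest.raises(ValueError, match="transition"):
            validate_quant_table(df)

    def test_negative_area(self):
        df = _quant_df(self.GOOD + [["PEPB", "trypsin", "GW_1", "GW", "t1", -5.0]])
        with pytest.raises(ValueError, match="negative"):
            validate_quant_table(df)

    def test_unknown_sample_label_lists_allowed(self):
        df = _quant_df(self.GOOD + [["PEPB", "trypsin", "R1", "XX", "t1", 5.0]])
        with pytest.raises(ValueError, match="GW.*MW"):
            validate_quant_table(df)

    def test_duplicate_transition_row(self):
        df = _quant_df(self.GOOD + [self.GOOD[0]])
        with pytest.raises(ValueError, match="duplicate"):
            validate_quant_table(df)

    def test_replicate_shared_across_samples(self):
        df = _quant_df(self.GOOD + [["PEPA", "trypsin", "GW_1", "MW", "t2", 1.0]])
        with pytest.raises(ValueError, match="both samples"):
            validate_quant_table(df)


class TestPeptideArea:
    def test_transitions_sum(self):
        df = _quant_df([["PEPA", "trypsin", "GW_1", "GW", f"t{i}", a]
                        for i, a in enumerate([100.0, 200.0, 300.0], 1)]
                       + [["PEPA", "trypsin", "MW_1", "MW", "t1", 50.0]])
        mat = peptide_area(df)
        assert mat.values.loc["PEPA", "GW_1"] == 600.0
        assert mat.values.loc["PEPA", "MW_1"] == 50.0

    def test_missing_cells_masked(self):
        rows = [["PEPA", "trypsin", r, SAMPLE_OF[r], "t1", 10.0] for r in REPS[:7]]
        rows += [["PEPB", "trypsin", r, SAMPLE_OF[r], "t1", 5.0] for r in REPS]
        mat = peptide_area(_quant_df(rows))
        assert np.isnan(mat.values.loc["PEPA", "MW_4"])
        assert mat.values.loc["PEPA"].notna().sum() == 7


class TestNormalize:
    def test_example_halves_and_sesquis(self):
        mat = _matrix({"PEPA": [3, 3, 3, 3, 1, 1, 1, 1]})
        out = normalize(mat).values.loc["PEPA"]
        assert list(out[:4]) == [1.5] * 4 and list(out[4:]) == [0.5] * 4

    def test_constant_peptide_is_all_ones(self):
        out = normalize(_matrix({"PEPA": [5.0] * 8})).values
        assert np.allclose(out, 1.0)

    def test_one_sided_peptide_normalizes_over_observed_only(self):
        mat = _matrix({"PEPA": [2, 2, 2, 2] + [np.nan] * 4})
        out = normalize(mat).values.loc["PEPA"]
        assert np.allclose(out[:4], 1.0) and out[4:].isna().all()

    def test_all_zero_peptide_dropped_with_warning(self):
        mat = _matrix({"PEPA": [0.0] * 8, "PEPB": [1.0] * 8})
        with pytest.warns(UserWarning, match="all-zero"):
            out = normalize(mat)
        assert list(out.values.index) == ["PEPB"]

    def test_mean_one_invariant_and_idempotence(self):
        rng = np.random.default_rng(7)
        mat = _matrix({f"P{i}": rng.lognormal(10, 1, 8) for i in range(20)})
        once = normalize(mat)
        assert np.allclose(once.values.mean(axis=1), 1.0, atol=1e-9)
        twice = normalize(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(c=st.floats(1e-3, 1e3), seed=st.integers(0, 10_000))
    def test_scale_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        base = rng.lognormal(8, 0.5, 8)
        a = normalize(_matrix({"P": base})).values
        b = normalize(_matrix({"P": base * c})).values
        assert np.allclose(a, b, rtol=1e-9)


def welch_oracle(x, y):
    """Welch test from first principles (statistic + Satterthwaite df)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return 2 * stats.t.sf(abs(t), df)


class TestDifferential:
    def test_identical_groups_null(self):
        mat = _matrix({"P": [1.0, 1.1, 0.9, 1.0, 1.0, 1.1, 0.9, 1.0]})
        res = differential(mat)
        assert res.loc["P", "log2_fold_change"] == pytest.approx(0.0)
        assert not res.loc["P", "significant"]

    def test_exact_doubling_zero_variance_flagged(self):
        mat = _matrix({"P": [2.0] * 4 + [1.0] * 4})
        res = differential(mat)
        assert res.loc["P", "log2_fold_change"] == pytest.approx(1.0)
        assert np.isnan(res.loc["P", "p_value"])
        assert res.loc["P", "flag"] == "degenerate-variance"
        assert not res.loc["P", "significant"]

    def test_one_sided_presence_flagged(self):
        mat = _matrix({"P": [2.0] * 4 + [np.nan] * 4})
        res = differential(mat)
        assert res.loc["P", "flag"] == "one-sided presence"
        assert np.isnan(res.loc["P", "p_value"])

    def test_welch_p_matches_independent_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x, y = rng.normal(0, 1, 4), rng.normal(0.8, 1.5, 4)
            assert welch_test(x, y) == pytest.approx(welch_oracle(x, y), abs=1e-9)

    def test_significance_needs_both_fold_change_and_p(self):
        rng = np.random.default_rng(0)
        big = 4 * (1 + rng.normal(0, 0.01, 4))
        small = 1 + rng.normal(0, 0.01, 4)
        mat = _matrix({"UP": np.concatenate([big, small]),
                       "FLAT": np.concatenate([small * 1.05, small])})
        res = differential(mat, PipelineConfig(fc_threshold=2, p_threshold=0.01))
        assert bool(res.loc["UP", "significant"])
        assert not res.loc["FLAT", "significant"]


class TestGroupAbundance:
    def test_two_peptide_cancellation(self):
        mat = _matrix({"A": [1.5] * 4 + [0.5] * 4, "B": [0.5] * 4 + [1.5] * 4})
        res = group_abundance(mat, {"A": "hmw_gs", "B": "hmw_gs"})
        assert res.loc["hmw_gs", "ratio_gw_mw"] == pytest.approx(1.0)
        assert res.loc["hmw_gs", "mean_gw"] == pytest.approx(2.0)

    def test_singleton_group_equals_peptide(self):
        mat = _matrix({"A": [1.5] * 4 + [0.5] * 4})
        res = group_abundance(mat, {"A": "ati"})
        assert res.loc["ati", "ratio_gw_mw"] == pytest.approx(3.0)

    def test_partition_conservation(self):
        """Sum over groups of per-replicate group sums equals the sum of
        all allocated peptides' normalized values, per replicate."""
        rng = np.random.default_rng(3)
        mat = normalize(_matrix({f"P{i}": rng.lognormal(8, 1, 8) for i in range(12)}))
        alloc = {f"P{i}": ["alpha_gliadin", "lmw_gs", "ati"][i % 3] for i in range(12)}
        res = group_abundance(mat, alloc)
        total_gw = mat.values[[c for c in REPS if c.startswith("GW")]].sum().mean()
        total_mw = mat.values[[c for c in REPS if c.startswith("MW")]].sum().mean()
        assert res["mean_gw"].sum() == pytest.approx(total_gw, rel=1e-12)
        assert res["mean_mw"].sum() == pytest.approx(total_mw, rel=1e-12)

    def test_unallocated_peptide_rejected(self):
        mat = _matrix({"A": [1.0] * 8})
        with pytest.raises(KeyError):
            group_abundance(mat, {})


class TestNetGlutenRatio:
    def _results(self, rows):
        return pd.DataFrame(rows).set_index("group")

    def test_single_group_doubling(self):
        res = self._results([{"group": "hmw_gs", "mean_gw": 2.0, "mean_mw": 1.0}])
        with pytest.warns(UserWarning):  # four canonical groups absent
            assert net_gluten_ratio(res) == pytest.approx(200.0)

    def test_balanced_groups_are_100_percent(self):
        rows = [{"group": g, "mean_gw": 1.0, "mean_mw": 1.0}
                for g in ("alpha_gliadin", "gamma_gliadin", "omega_gliadin",
                          "lmw_gs", "hmw_gs")]
        assert net_gluten_ratio(self._results(rows)) == pytest.approx(100.0)

    def test_non_canonical_groups_excluded(self):
        rows = [{"group": g, "mean_gw": 1.0, "mean_mw": 1.0}
                for g in ("alpha_gliadin", "gamma_gliadin", "omega_gliadin",
                          "lmw_gs", "hmw_gs")]
        rows.append({"group": "ati", "mean_gw": 50.0, "mean_mw": 1.0})
        assert net_gluten_ratio(self._results(rows)) == pytest.approx(100.0)

    def test_zero_denominator_rejected(self):
        rows = [{"group": "hmw_gs", "mean_gw": 1.0, "mean_mw": 0.0}]
        with pytest.raises(ZeroDivisionError), pytest.warns(UserWarning):
            net_gluten_ratio(self._results(rows))
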