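"""Imputation engine: draws, monotone path, VIF reduction, Rubin pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from misens import (
    CohortConfig,
    ConfigurationError,
    ImputationSpec,
    MisensError,
    NonMonotoneError,
    PredictorReductionError,
    UnimputableVariableError,
    assemble_wide,
    generate_cohort,
    impute,
    monotone_impute,
    pool_estimates,
    reduce_predictors,
    variance_inflation_factors,
)


def _mcar_wide(n=300, rate=0.2, seed=0):
    """Wide table from a synthetic cohort with MCAR-deleted post values."""
    cohort = generate_cohort(CohortConfig(n_subjects=n, seed=seed))
    wide = assemble_wide(cohort).cases
    rng = np.random.default_rng(seed + 1)
    mask = rng.random(len(wide)) < rate
    truth = wide["post_oq"].copy()
    wide = wide.copy()
    wide.loc[mask, "post_oq"] = np.nan
    wide["M"] = mask.astype(int)
    return wide, truth, mask


class TestImpute:
    def test_no_missing_returns_identical_copies(self, cohort260):
        wide = assemble_wide(cohort260).cases
        res = impute(wide, ImputationSpec(m=3, seed=0))
        assert res.m == 3
        for ds in res.datasets:
            pd.testing.assert_frame_equal(ds, wide)

    def test_observed_cells_preserved_bit_exact(self):
        wide, _, mask = _mcar_wide(n=200, seed=3)
        res = impute(wide, ImputationSpec(m=4, seed=7))
        for ds in res.datasets:
            assert ds["post_oq"].notna().all()
            obs_cols = [c for c in wide.columns if c != "post_oq"]
            pd.testing.assert_frame_equal(ds[obs_cols], wide[obs_cols])
            assert ds.loc[~mask, "post_oq"].equals(wide.loc[~mask, "post_oq"])

    def test_determinism_under_seed(self):
        wide, _, _ = _mcar_wide(n=120, seed=5)
        a = impute(wide, ImputationSpec(m=3, seed=42))
        b = impute(wide, ImputationSpec(m=3, seed=42))
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da, db)

    def test_mcar_parameter_recovery(self):
        """Pooled post mean within 3 pooled SEs of the pre-deletion mean."""
        wide, truth, _ = _mcar_wide(n=500, rate=0.2, seed=1)
        res = impute(wide, ImputationSpec(m=10, seed=2))
        n = len(wide)
        means = [ds["post_oq"].mean() for ds in res.datasets]
        variances = [ds["post_oq"].var(ddof=1) / n for ds in res.datasets]
        pooled = pool_estimates(means, variances)
        assert abs(pooled.estimate - truth.mean()) < 3 * pooled.se

    def test_zero_observed_target_rejected(self):
        wide, _, _ = _mcar_wide(n=60, seed=2)
        wide["post_oq"] = np.nan
        with pytest.raises(UnimputableVariableError):
            impute(wide, ImputationSpec(m=2, seed=0))

    def test_single_target_uses_monotone_path(self):
        wide, _, _ = _mcar_wide(n=100, seed=9)
        res = impute(wide, ImputationSpec(m=2, seed=0))
        assert res.diagnostics["monotone"] is True

    def test_more_imputations_do_not_increase_mc_variance(self):
        """Monte-Carlo variance of the pooled mean shrinks (or holds) as m grows."""
        wide, _, _ = _mcar_wide(n=80, rate=0.3, seed=4)
        est = {2: [], 10: []}
        for m in est:
            for seed in range(60):
                res = impute(wide, ImputationSpec(m=m, seed=seed))
                est[m].append(np.mean([ds["post_oq"].mean() for ds in res.datasets]))
        assert np.var(est[10]) <= np.var(est[2]) * 1.15

    def test_agrees_with_statsmodels_mice(self):
        """Independent engine (statsmodels MICE) lands on the same pooled mean."""
        from statsmodels.imputation import mice

        wide, truth, _ = _mcar_wide(n=300, rate=0.2, seed=6)
        cols = ["pre_oq", "oq_total_last", "oq_total_penult", "post_oq"]
        data = wide[cols].copy()
        res = impute(data, ImputationSpec(m=10, seed=3))
        ours = np.mean([ds["post_oq"].mean() for ds in res.datasets])

        md = mice.MICEData(data.rename(columns={c: c.replace("_", "") for c in cols}))
        theirs = []
        for _ in range(10):
            md.update_all()
            theirs.append(md.data["postoq"].mean())
        sd = truth.std(ddof=1) / np.sqrt(len(truth))
        assert abs(ours - np.mean(theirs)) < 4 * sd


class TestMonotonePath:
    def _monotone_toy(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n)
        y1 = x + rng.normal(0, 1, n)
        y2 = 0.8 * y1 + rng.normal(0, 0.6, n)
        df = pd.DataFrame({"x": x, "y1": y1, "y2": y2})
        truth_corr = np.corrcoef(y1, y2)[0, 1]
        # nested missing sets: y2 missing wherever y1 is, plus more
        miss1 = rng.random(n) < 0.15
        miss2 = miss1 | (rng.random(n) < 0.15)
        df.loc[miss1, "y1"] = np.nan
        df.loc[miss2, "y2"] = np.nan
        return df, truth_corr

    def test_monotone_block_recovers_correlation(self):
        df, truth_corr = self._monotone_toy(seed=8)
        res = impute(df, ImputationSpec(m=10, seed=1))
        assert res.diagnostics["monotone"] is True
        corrs = [np.corrcoef(ds["y1"], ds["y2"])[0, 1] for ds in res.datasets]
        assert np.mean(corrs) == pytest.approx(truth_corr, abs=0.1)

    def test_non_monotone_block_rejected(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=["x", "y1", "y2"])
        df.loc[:9, "y1"] = np.nan
        df.loc[40:, "y2"] = np.nan  # disjoint missing sets: not monotone
        with pytest.raises(NonMonotoneError, match="chained"):
            monotone_impute(df, {"y1": ["x"], "y2": ["x"]}, ImputationSpec(m=2))

    def test_non_monotone_handled_by_chained_path(self):
        rng = np.random.default_rng(1)
        n = 150
        x = rng.normal(0, 1, n)
        df = pd.DataFrame({"x": x, "y1": x + rng.normal(0, 1, n), "y2": x + rng.normal(0, 1, n)})
        df.loc[:19, "y1"] = np.nan
        df.loc[n - 20 :, "y2"] = np.nan
        res = impute(df, ImputationSpec(m=3, n_iterations=8, seed=2))
        assert res.diagnostics["monotone"] is False
        for ds in res.datasets:
            assert ds.notna().all().all()

    def test_single_variable_block_completes(self):
        df, _ = self._monotone_toy(seed=3)
        df["y2"] = 0.0  # only y1 missing
        out = monotone_impute(df, {"y1": ["x"]}, ImputationSpec(m=2, seed=5))
        assert out["y1"].notna().all()
        assert out.loc[df["y1"].notna(), "y1"].equals(df.loc[df["y1"].notna(), "y1"])


class TestReducePredictors:
    def _data(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(0, 1, n)
        x2 = rng.normal(0, 1, n)
        x3 = rng.normal(0, 1, n)
        y = 2 * x1 - x2 + rng.normal(0, 1, n)
        return pd.DataFrame({"y": y, "x1": x1, "x2": x2, "x3": x3})

    def test_orthogonal_predictors_unchanged(self):
        data = self._data()
        reduced, hist = reduce_predictors("y", ["x1", "x2", "x3"], data, ImputationSpec())
        assert reduced == ["x1", "x2", "x3"]
        assert max(hist[0]["vif"].values()) < 2

    def test_vif_matches_brute_force_oracle(self):
        """VIF equals 1/(1-R^2) from statsmodels auxiliary regressions."""
        import statsmodels.api as sm

        data = self._data(seed=5)
        data["x4"] = 0.9 * data["x1"] + 0.1 * np.random.default_rng(77).normal(0, 1, len(data))
        preds = ["x1", "x2", "x3", "x4"]
        vifs = variance_inflation_factors(data, preds)
        for j, name in enumerate(preds):
            others = [p for p in preds if p != name]
            fit = sm.OLS(data[name], sm.add_constant(data[others])).fit()
            assert vifs[name] == pytest.approx(1.0 / (1.0 - fit.rsquared), rel=1e-8)

    def test_duplicated_predictor_removed(self):
        data = self._data(seed=2)
        data["x1_copy"] = data["x1"]
        reduced, _ = reduce_predictors("y", ["x1", "x1_copy", "x2"], data, ImputationSpec())
        assert sorted(reduced) in (["x1", "x2"], ["x1_copy", "x2"])
        assert len(reduced) == 2

    def test_highest_p_member_of_collinear_pair_dropped(self):
        """Of two collinear predictors the one irrelevant to the target goes first."""
        rng = np.random.default_rng(11)
        n = 300
        x2 = rng.normal(0, 1, n)
        x1 = x2 + rng.normal(0, 0.2, n)  # collinear pair, VIF >> 10
        x3 = rng.normal(0, 1, n)
        y = 3 * x2 + rng.normal(0, 1, n)  # target driven by x2 only
        data = pd.DataFrame({"y": y, "x1": x1, "x2": x2, "x3": x3})
        reduced, _ = reduce_predictors("y", ["x1", "x2", "x3"], data, ImputationSpec())
        assert "x2" in reduced and "x1" not in reduced and "x3" in reduced

    def test_fallback_threshold_is_stricter(self):
        rng = np.random.default_rng(3)
        n = 300
        x1 = rng.normal(0, 1, n)
        x2 = x1 + rng.normal(0, 0.45, n)  # VIF ~ 6: passes 10, fails 5
        y = x1 + rng.normal(0, 1, n)
        data = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        spec = ImputationSpec()
        loose, _ = reduce_predictors("y", ["x1", "x2"], data, spec)
        strict, _ = reduce_predictors("y", ["x1", "x2"], data, spec, enforce_fallback=True)
        assert loose == ["x1", "x2"]
        assert len(strict) == 1

    def test_all_predictors_removed_is_an_error(self):
        data = pd.DataFrame({"y": np.random.default_rng(0).normal(size=50), "x1": np.ones(50)})
        with pytest.raises(PredictorReductionError):
            reduce_predictors("y", ["x1"], data, ImputationSpec())


class TestPoolEstimates:
    def test_hand_computed_example(self):
        pooled = pool_estimates([1.0, 1.2, 1.1], [0.04, 0.04, 0.04])
        assert pooled.estimate == pytest.approx(1.1)
        assert pooled.between == pytest.approx(0.01)
        assert pooled.variance == pytest.approx(0.04 + (4.0 / 3.0) * 0.01)

    def test_identical_estimates(self):
        pooled = pool_estimates([0.5, 0.5, 0.5], [0.02, 0.02, 0.02])
        assert pooled.estimate == 0.5
        assert pooled.between == 0.0
        assert pooled.variance == pytest.approx(0.02)
        assert np.isinf(pooled.df)

    def test_too_few_estimates(self):
        with pytest.raises(MisensError):
            pool_estimates([1.0], [0.1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        q=st.lists(st.floats(-5, 5), min_size=2, max_size=12),
        seed=st.integers(0, 2**16),
    )
    def test_total_variance_never_below_within(self, q, seed):
        rng = np.random.default_rng(seed)
        u = rng.uniform(0.01, 1.0, size=len(q)).tolist()
        pooled = pool_estimates(q, u)
        assert pooled.variance >= pooled.within - 1e-12
        assert min(q) - 1e-12 <= pooled.estimate <= max(q) + 1e-12


def test_spec_validation():
    with pytest.raises(ConfigurationError):
        ImputationSpec(m=1).validate()
    with pytest.raises(ConfigurationError):
        ImputationSpec(vif_fallback_threshold=12.0).validate()
    with pytest.raises(ConfigurationError):
        ImputationSpec(n_iterations=0).validate()
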