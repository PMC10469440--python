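"""Censored hierarchical model: contracts, recovery, spline basis, batching."""

import numpy as np
import pandas as pd
import pytest

from metaboicc import FeatureSpec, StudyDesign, simulate_study
from metaboicc.model import (
    MCMCSettings,
    ModelSpec,
    build_age_smooth,
    fit_censored_model,
    run_feature_batch,
)

from conftest import make_table


def _feature_arrays(table, meta, j=0):
    vals = table.intensities.iloc[:, j].to_numpy()
    det = np.isfinite(vals)
    lod = float(np.log(np.nanmin(vals)))
    y = np.where(det, np.log(np.where(det, vals, 1.0)), np.nan)
    return y, lod, meta["subject_id"].to_numpy(), meta["center_id"].to_numpy()


class TestContracts:
    def test_all_censored_rejected(self):
        y = np.full(8, np.nan)
        subj = np.repeat(["a", "b", "c", "d"], 2)
        cent = np.repeat(["c1", "c2"], 4)
        with pytest.raises(ValueError, match="censored"):
            fit_censored_model(y, 0.0, subj, cent)

    def test_no_replicates_rejected(self):
        y = np.random.default_rng(0).normal(size=6)
        subj = [f"s{i}" for i in range(6)]
        cent = ["c1", "c1", "c1", "c2", "c2", "c2"]
        with pytest.raises(ValueError, match="replicate"):
            fit_censored_model(y, -np.inf, subj, cent)

    def test_non_nested_labels_rejected(self):
        y = np.random.default_rng(0).normal(size=6)
        subj = ["a", "a", "b", "b", "c", "c"]
        cent = ["c1", "c2", "c1", "c1", "c2", "c2"]  # subject a spans centers
        with pytest.raises(ValueError, match="nested"):
            fit_censored_model(y, -np.inf, subj, cent)

    def test_three_level_needs_two_centers(self):
        y = np.random.default_rng(0).normal(size=6)
        subj = ["a", "a", "b", "b", "c", "c"]
        cent = ["c1"] * 6
        with pytest.raises(ValueError, match="centers"):
            fit_censored_model(y, -np.inf, subj, cent)

    def test_degenerate_constant_data_flagged(self, fast_mcmc):
        y = np.zeros(12) + 5.0
        subj = np.repeat([f"s{i}" for i in range(6)], 2)
        cent = np.repeat(["c1", "c2"], 6)
        draws, report = fit_censored_model(y, -np.inf, subj, cent, mcmc=fast_mcmc)
        assert report.degenerate
        assert not report.passed
        # variances collapse toward the prior's lower range
        assert np.median(draws.stacked("sigma2_within")) < 1e-2


class TestRecovery:
    def test_two_level_posterior_matches_moment_oracle(self):
        """Uncensored balanced one-center data: posterior medians track the
        classical one-way ANOVA variance-component estimator."""
        rng = np.random.default_rng(5)
        n_sub, reps = 150, 2
        s_b, s_w = 1.0, 0.5
        u = rng.normal(0, np.sqrt(s_b), n_sub)
        y = (u[:, None] + rng.normal(0, np.sqrt(s_w), (n_sub, reps))).ravel() + 10.0
        subj = np.repeat(np.arange(n_sub), reps)
        # method-of-moments (balanced one-way ANOVA)
        ybar = y.reshape(n_sub, reps).mean(axis=1)
        msb = reps * np.sum((ybar - y.mean()) ** 2) / (n_sub - 1)
        msw = np.sum((y.reshape(n_sub, reps) - ybar[:, None]) ** 2) / (n_sub * (reps - 1))
        mom_b, mom_w = (msb - msw) / reps, msw
        draws, _ = fit_censored_model(
            y, -np.inf, subj, spec=ModelSpec(levels=2),
            mcmc=MCMCSettings(iterations=2000, chains=2, seed=1),
        )
        post_w = np.median(draws.stacked("sigma2_within"))
        post_b = np.median(draws.stacked("sigma2_subject"))
        assert abs(post_w - mom_w) / mom_w < 0.15
        assert abs(post_b - mom_b) / mom_b < 0.15

    def test_two_level_matches_three_level_with_null_center_variance(self):
        """On multicenter data with sigma2_center = 0, the two-level fit and the
        three-level fit agree on the shared variance components."""
        design = StudyDesign(center_sizes=(40, 40), repeat_fraction=1.0)
        spec = FeatureSpec(
            n_features=1, sigma2_within=0.6, sigma2_subject=0.6,
            sigma2_center=0.0, detection_rate=1.0,
        )
        table, meta, _ = simulate_study(design, spec, seed=6)
        y, lod, subj, cent = _feature_arrays(table, meta)
        mc = MCMCSettings(iterations=2000, chains=2, seed=2)
        d3, _ = fit_censored_model(y, lod, subj, cent, spec=ModelSpec(levels=3), mcmc=mc)
        d2, _ = fit_censored_model(y, lod, subj, None, spec=ModelSpec(levels=2), mcmc=mc)
        for name in ("sigma2_within", "sigma2_subject"):
            m3 = np.median(d3.stacked(name))
            m2 = np.median(d2.stacked(name))
            assert abs(m3 - m2) < 0.1

    def test_censored_fit_recovers_truth(self):
        design = StudyDesign(center_sizes=(50, 50, 50, 50), repeat_fraction=1.0)
        spec = FeatureSpec(
            n_features=1, sigma2_within=1.0, sigma2_subject=1.0,
            sigma2_center=0.25, detection_rate=0.7,
        )
        table, meta, truth = simulate_study(design, spec, seed=1)
        y, lod, subj, cent = _feature_arrays(table, meta)
        draws, report = fit_censored_model(
            y, lod, subj, cent, mcmc=MCMCSettings(iterations=2000, chains=4, seed=1)
        )
        from metaboicc.icc import icc_three_level

        res = icc_three_level(draws)
        assert abs(res.icc - truth["icc"].iloc[0]) < 0.10
        assert np.all(draws.stacked("sigma2_within") >= 0)
        assert np.all(draws.stacked("sigma2_center") >= 0)

    def test_seeded_chains_are_reproducible(self, small_study, fast_mcmc):
        table, meta, _ = small_study
        y, lod, subj, cent = _feature_arrays(table, meta)
        d1, _ = fit_censored_model(y, lod, subj, cent, mcmc=fast_mcmc)
        d2, _ = fit_censored_model(y, lod, subj, cent, mcmc=fast_mcmc)
        for name in d1.names:
            np.testing.assert_array_equal(d1.params[name], d2.params[name])


class TestAgeSmooth:
    ages = np.random.default_rng(3).uniform(50, 70, size=120)

    def test_df1_is_centered_linear_term(self):
        basis = build_age_smooth(self.ages, df=1)
        assert basis.shape == (120, 1)
        np.testing.assert_allclose(basis[:, 0], self.ages - self.ages.mean())

    def test_columns_are_centered(self):
        basis = build_age_smooth(self.ages, df=4)
        assert basis.shape == (120, 4)
        np.testing.assert_allclose(basis.mean(axis=0), 0.0, atol=1e-12)

    def test_basis_reproduces_cubic_polynomial(self):
        """A cubic lies in the cubic-spline space: regression on the basis
        (plus intercept) must fit it exactly."""
        x = self.ages
        target = 0.5 * x**3 - 2 * x**2 + x - 7
        basis = build_age_smooth(x, df=5)
        design = np.column_stack([np.ones_like(x), basis])
        coef, res, *_ = np.linalg.lstsq(design, target, rcond=None)
        fitted = design @ coef
        np.testing.assert_allclose(fitted, target, rtol=1e-8)

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            build_age_smooth(np.full(10, 60.0), df=3)
        with pytest.raises(ValueError, match="distinct"):
            build_age_smooth(np.array([1.0, 2.0, 1.0, 2.0]), df=3)


class TestBatch:
    def test_batch_returns_row_per_feature_and_is_reproducible(self, fast_mcmc):
        design = StudyDesign(center_sizes=(15, 15), repeat_fraction=1.0)
        spec = FeatureSpec(n_features=5, detection_rate=1.0)
        table, meta, _ = simulate_study(design, spec, seed=10)
        r1, f1 = run_feature_batch(table, meta, mcmc=fast_mcmc)
        r2, f2 = run_feature_batch(table, meta, mcmc=fast_mcmc)
        assert len(r1) == 5 and not f1
        pd.testing.assert_frame_equal(r1, r2)

    def test_batch_matches_single_feature_fit(self, small_study, fast_mcmc):
        table, meta, _ = small_study
        res, _ = run_feature_batch(table, meta, mcmc=fast_mcmc, features=[table.feature_ids[1]])
        y, lod, subj, cent = _feature_arrays(table, meta, j=1)
        # run_feature_batch numbers streams by position in the requested list
        draws, _ = fit_censored_model(y, lod, subj, cent, mcmc=fast_mcmc, stream=0)
        from metaboicc.icc import icc_three_level

        assert res["icc"].iloc[0] == pytest.approx(icc_three_level(draws).icc)

    def test_all_missing_feature_isolated_not_fatal(self, fast_mcmc):
        design = StudyDesign(center_sizes=(15, 15), repeat_fraction=1.0)
        spec = FeatureSpec(n_features=3, detection_rate=1.0)
        table, meta, _ = simulate_study(design, spec, seed=11)
        ints = table.intensities.copy()
        ints["F0002"] = np.nan
        table = make_table(ints.to_numpy(), feature_ids=list(ints.columns),
                           sample_ids=list(ints.index))
        res, failures = run_feature_batch(table, meta, mcmc=fast_mcmc)
        assert set(failures) == {"F0002"}
        assert len(res) == 2

    def test_metadata_mismatch_rejected_before_fitting(self, small_study, fast_mcmc):
        table, meta, _ = small_study
        with pytest.raises(ValueError, match="metadata"):
            run_feature_batch(table, meta.iloc[:-3], mcmc=fast_mcmc)
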