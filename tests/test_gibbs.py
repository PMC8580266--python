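import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bayimp as bi
from bayimp.gibbs import McmcSettings, sample_truncated_normal

from conftest import small_dataset


class TestTruncatedNormal:
    def test_half_normal_moment(self):
        rng = np.random.default_rng(1)
        d = sample_truncated_normal(np.zeros(10**5), 1.0, "above", rng)
        assert abs(d.mean() - np.sqrt(2 / np.pi)) < 0.01

    def test_deep_tail_is_finite_and_on_side(self):
        rng = np.random.default_rng(2)
        d = sample_truncated_normal(np.full(2000, -6.0), 1.0, "above", rng)
        assert np.all(np.isfinite(d)) and np.all(d > 0)
        d = sample_truncated_normal(np.full(2000, 8.0), 1.0, "below", rng)
        assert np.all(np.isfinite(d)) and np.all(d < 0)

    def test_sides_are_mirror_images(self):
        above = sample_truncated_normal(
            np.zeros(20000), 1.0, "above", np.random.default_rng(3)
        )
        below = sample_truncated_normal(
            np.zeros(20000), 1.0, "below", np.random.default_rng(4)
        )
        assert stats.ks_2samp(above, -below).pvalue > 0.01

    def test_matches_scipy_truncnorm_quantiles(self):
        # independent oracle for the shifted case
        rng = np.random.default_rng(5)
        d = sample_truncated_normal(np.full(40000, 1.5), 2.0, "above", rng)
        qs = np.quantile(d, [0.1, 0.5, 0.9])
        ref = stats.truncnorm.ppf([0.1, 0.5, 0.9], a=-0.75, b=np.inf, loc=1.5, scale=2.0)
        assert np.allclose(qs, ref, atol=0.05)

    def test_bad_sd_raises(self):
        with pytest.raises(ValueError):
            sample_truncated_normal(0.0, 0.0, "above", np.random.default_rng(0))


def intercept_only_fit(seed=0, fixed_tau=None, loc_sd=10.0, **kw):
    rng = np.random.default_rng(seed)
    J, n_per = 2, 50
    z = rng.standard_normal(J * n_per)
    frame = pd.DataFrame(
        {"g": np.repeat([1, 2], n_per), "y": z, "d": np.zeros(J * n_per)}
    )
    frame["y"] += kw.pop("shift", 0.0)
    ds = bi.assign_roles(
        bi.MultilevelDataset.from_frame(frame.drop(columns="d")),
        "g",
        {"y": "continuous"},
    )
    spec = bi.AnalysisSpec("y", "continuous", covariates=[], intercept="random")
    return ds, spec


class TestConjugateCorrectness:
    def test_hierarchical_normal_normal_matches_analytic(self):
        """2-cluster normal-normal model with known variances: the Gibbs
        posterior for the hyper-mean must match exact Gaussian algebra."""
        rng = np.random.default_rng(8)
        n_per, sigma, tau, s0 = 50, 1.0, 1.0, 10.0
        y1 = rng.standard_normal(n_per) + 1.0
        y2 = rng.standard_normal(n_per) - 0.5
        frame = pd.DataFrame(
            {"g": np.repeat([1, 2], n_per), "y": np.concatenate([y1, y2])}
        )
        ds = bi.assign_roles(
            bi.MultilevelDataset.from_frame(frame), "g", {"y": "continuous"}
        )
        spec = bi.AnalysisSpec("y", "continuous", covariates=[], intercept="random")
        fit = bi.fit_model(
            ds, spec, imputation_spec=None,
            settings=McmcSettings(burn_in=500, updates=4000, n_chains=2, seed=1),
            priors=bi.PriorConfig(location_sd=s0),
            standardize=False,
            fixed_residual_sd=sigma,
            fixed_intercept_sd=tau,
        )
        # exact posterior over (alpha0, alpha_1, alpha_2): Gaussian precision algebra
        prec = np.array(
            [
                [1 / s0**2 + 2 / tau**2, -1 / tau**2, -1 / tau**2],
                [-1 / tau**2, 1 / tau**2 + n_per / sigma**2, 0.0],
                [-1 / tau**2, 0.0, 1 / tau**2 + n_per / sigma**2],
            ]
        )
        b = np.array([0.0, y1.sum() / sigma**2, y2.sum() / sigma**2])
        cov = np.linalg.inv(prec)
        mean = cov @ b
        s = fit.summary("alpha0")
        assert abs(s.estimate - mean[0]) < 3 * s.mcse
        assert abs(s.se - np.sqrt(cov[0, 0])) < 0.1 * np.sqrt(cov[0, 0])


class TestRunMcmc:
    def test_chain_dimensions_and_determinism(self, small_ds, small_spec):
        st = McmcSettings(burn_in=50, updates=100, n_chains=2, seed=9)
        a = bi.run_mcmc(
            bi.build_joint_model(
                *bi.standardize_dataset(small_ds, small_spec, None)[:1],
                small_spec, None,
            ),
            st,
        )
        for p in a.param_names:
            assert a.draws[p].shape == (2, 100)
        b = bi.run_mcmc(
            bi.build_joint_model(
                *bi.standardize_dataset(small_ds, small_spec, None)[:1],
                small_spec, None,
            ),
            st,
        )
        for p in a.param_names:
            np.testing.assert_array_equal(a.draws[p], b.draws[p])

    def test_thinning_changes_retained_count(self, small_ds, small_spec):
        std, _ = bi.standardize_dataset(small_ds, small_spec, None)
        model = bi.build_joint_model(std, small_spec, None)
        ch = bi.run_mcmc(model, McmcSettings(burn_in=20, updates=200, thin=2,
                                             n_chains=1, seed=0))
        assert ch.draws["alpha0"].shape == (1, 100)

    def test_sd_draws_positive_and_binary_fit_runs(self):
        ds = small_dataset(seed=6, miss_rate=0.1)
        spec = bi.AnalysisSpec(
            "y", "continuous",
            [bi.Covariate("x1", "random"), bi.Covariate("x2", "random")],
        )
        fit = bi.fit_model(
            ds, spec, settings=McmcSettings(burn_in=100, updates=200, n_chains=1, seed=2)
        )
        assert np.all(fit.chains.draws["tau_x1"] > 0)
        assert np.all(fit.chains.draws["sigma_y"] > 0)

    def test_row_permutation_leaves_posterior_unchanged(self):
        ds = small_dataset(seed=12)
        spec = bi.AnalysisSpec(
            "y", "continuous", [bi.Covariate("x1", "fixed"), bi.Covariate("x2", "fixed")]
        )
        st = McmcSettings(burn_in=200, updates=1500, n_chains=1, seed=4)
        fit1 = bi.fit_model(ds, spec, imputation_spec=None, settings=st)
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n_rows)
        ds2 = ds.copy()
        ds2.values = ds.values.iloc[perm].reset_index(drop=True)
        ds2.mask = ds.mask.iloc[perm].reset_index(drop=True)
        ds2.cluster_codes = ds.cluster_codes[perm]
        fit2 = bi.fit_model(ds2, spec, imputation_spec=None, settings=st)
        for p in ("beta_x1", "beta_x2", "sigma_y"):
            a, b = fit1.summary(p), fit2.summary(p)
            assert abs(a.estimate - b.estimate) < 3 * np.hypot(a.mcse, b.mcse)


class TestPosteriorSummary:
    @staticmethod
    def chains_of(arr2d):
        from bayimp.gibbs import ChainSet

        arr2d = np.atleast_2d(np.asarray(arr2d, float))
        return ChainSet(
            draws={"p": arr2d},
            iterations=np.arange(1, arr2d.shape[1] + 1),
            settings=McmcSettings(burn_in=0, updates=max(100, arr2d.shape[1])),
            param_names=["p"],
        )

    def test_mean_and_median(self):
        ch = self.chains_of(np.tile([1.0, 2.0, 3.0, 4.0], 50))
        s = bi.posterior_summary(ch, "p")
        assert s.estimate == pytest.approx(2.5)
        assert s.median == pytest.approx(2.5)

    def test_constant_draws(self):
        ch = self.chains_of(np.full(200, 3.25))
        s = bi.posterior_summary(ch, "p")
        assert (s.cri_low, s.cri_high) == (3.25, 3.25)
        assert s.se == 0.0 and s.mcse == 0.0
        assert s.rhat_degenerate

    def test_normal_quantiles(self):
        rng = np.random.default_rng(10)
        ch = self.chains_of(rng.standard_normal(10**5))
        s = bi.posterior_summary(ch, "p")
        assert abs(s.cri_low + 1.96) < 0.05
        assert abs(s.cri_high - 1.96) < 0.05

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            bi.posterior_summary(self.chains_of(np.ones((1, 50))), "p")


class TestSettingsValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"burn_in": -1},
            {"updates": 50},
            {"n_chains": 0},
            {"thin": 0},
        ],
    )
    def test_invalid_settings(self, kw):
        with pytest.raises(ValueError):
            McmcSettings(**kw)
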