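import numpy as np
import pandas as pd
import pytest

import bayimp as bi
from bayimp.data_model import ValidationError
from bayimp.gibbs import ChainSet, McmcSettings
from bayimp.model_build import DegenerateModelError, SpecError


def make_ds(frame, types, cluster="g"):
    return bi.assign_roles(bi.MultilevelDataset.from_frame(frame), cluster, types)


@pytest.fixture()
def mixed_ds():
    rng = np.random.default_rng(0)
    n = 40
    frame = pd.DataFrame(
        {
            "g": np.repeat([1, 2], n // 2),
            "xc": rng.standard_normal(n) * 2 + 5,
            "xb": (rng.random(n) < 0.4).astype(float),
            "y": rng.standard_normal(n),
        }
    )
    frame.loc[3, "xc"] = np.nan
    frame.loc[5, "xb"] = np.nan
    return make_ds(
        frame, {"xc": "continuous", "xb": "binary", "y": "continuous"}
    )


@pytest.fixture()
def mixed_spec():
    return bi.AnalysisSpec(
        outcome="y",
        outcome_family="continuous",
        covariates=[bi.Covariate("xc", "random"), bi.Covariate("xb", "random")],
    )


class TestStandardize:
    def test_observed_moments_zero_one(self, mixed_ds, mixed_spec):
        ispec = bi.ImputationSpec.auto(mixed_ds, mixed_spec)
        std, rec = bi.standardize_dataset(mixed_ds, mixed_spec, ispec)
        col = std.values["xc"].to_numpy()
        obs = col[~np.isnan(col)]
        assert abs(obs.mean()) < 1e-10
        assert abs(obs.std(ddof=1) - 1) < 1e-10

    def test_binary_target_untouched(self, mixed_ds, mixed_spec):
        ispec = bi.ImputationSpec.auto(mixed_ds, mixed_spec)
        std, rec = bi.standardize_dataset(mixed_ds, mixed_spec, ispec)
        pd.testing.assert_series_equal(std.values["xb"], mixed_ds.values["xb"])
        assert "xb" in rec.skipped
        assert rec.mean_sd("xb") == (0.0, 1.0)

    def test_fully_observed_binary_covariate_is_standardized(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(
            {
                "g": np.repeat([1, 2], 10),
                "xb": (rng.random(20) < 0.5).astype(float),
                "y": rng.standard_normal(20),
            }
        )
        ds = make_ds(frame, {"xb": "binary", "y": "continuous"})
        spec = bi.AnalysisSpec("y", "continuous", [bi.Covariate("xb")])
        std, rec = bi.standardize_dataset(ds, spec, None)
        assert "xb" in rec.stats
        assert abs(std.values["xb"].mean()) < 1e-10

    def test_constant_column_raises(self):
        frame = pd.DataFrame(
            {"g": [1, 1, 2, 2], "xc": [5.0] * 4, "y": [1.0, 2.0, 3.0, 4.0]}
        )
        ds = make_ds(frame, {"xc": "continuous", "y": "continuous"})
        spec = bi.AnalysisSpec("y", "continuous", [bi.Covariate("xc")])
        with pytest.raises(ValidationError, match="xc"):
            bi.standardize_dataset(ds, spec, None)


class TestImputationSpecAuto:
    def test_targets_are_covariates_with_missing(self, mixed_ds, mixed_spec):
        ispec = bi.ImputationSpec.auto(mixed_ds, mixed_spec)
        assert sorted(ispec.target_names) == ["xb", "xc"]
        for t in ispec.targets:
            names = [p.name for p in t.predictors]
            assert t.name not in names
            assert "y" not in names  # outcome linked through the joint fit
            assert "xc" not in names and "xb" not in names

    def test_include_outcome_flag(self, mixed_ds, mixed_spec):
        ispec = bi.ImputationSpec.auto(mixed_ds, mixed_spec, include_outcome=True)
        assert all("y" in [p.name for p in t.predictors] for t in ispec.targets)


class TestBuildJointModel:
    def test_mixed_targets_and_analysis_columns(self, mixed_ds, mixed_spec):
        ispec = bi.ImputationSpec.auto(mixed_ds, mixed_spec)
        std, _ = bi.standardize_dataset(mixed_ds, mixed_spec, ispec)
        model = bi.build_joint_model(std, mixed_spec, ispec)
        assert model.n_targets == 2
        kinds = {t.name: t.vtype for t in model.targets}
        assert kinds == {"xc": "continuous", "xb": "binary"}
        assert {t.analysis_col for t in model.targets} == {0, 1}

    def test_all_fixed_effects_have_no_taus(self, mixed_ds):
        spec = bi.AnalysisSpec(
            "y", "continuous",
            [bi.Covariate("xc", "fixed"), bi.Covariate("xb", "fixed")],
            intercept="fixed",
        )
        ispec = bi.ImputationSpec.auto(mixed_ds, spec)
        std, _ = bi.standardize_dataset(mixed_ds, spec, ispec)
        model = bi.build_joint_model(std, spec, ispec)
        assert not any(p.startswith("tau") for p in model.monitored)

    def test_random_everything_counts_sds(self, desk_data, desk_analysis_spec):
        ds, _ = desk_data
        std, _ = bi.standardize_dataset(ds, desk_analysis_spec, None)
        model = bi.build_joint_model(std, desk_analysis_spec, None)
        taus = [p for p in model.monitored if p.startswith("tau")]
        assert len(taus) == 6  # intercept + 5 covariate slopes

    def test_zero_targets_is_degenerate(self, mixed_ds, mixed_spec):
        std, _ = bi.standardize_dataset(mixed_ds, mixed_spec, None)
        with pytest.raises(DegenerateModelError, match="analysis model alone"):
            bi.build_joint_model(std, mixed_spec, bi.ImputationSpec(targets=[]))

    def test_target_as_own_predictor_rejected(self):
        with pytest.raises(SpecError, match="own predictor"):
            bi.ImputationTarget(
                "xc", "continuous", predictors=[bi.Covariate("xc")]
            )

    def test_missing_covariate_without_target_rejected(self, mixed_ds, mixed_spec):
        std, _ = bi.standardize_dataset(mixed_ds, mixed_spec, None)
        with pytest.raises(SpecError, match="not an\n?.*imputation target|imputation target"):
            bi.build_joint_model(std, mixed_spec, None)


class TestUnstandardize:
    @staticmethod
    def chainset(draws):
        n = len(next(iter(draws.values())))
        return ChainSet(
            draws={k: np.asarray(v, float).reshape(1, -1) for k, v in draws.items()},
            iterations=np.arange(1, n + 1),
            settings=McmcSettings(burn_in=0, updates=max(100, n)),
            param_names=list(draws),
        )

    def test_identity_when_all_unit(self):
        from bayimp.model_build import StandardizationRecord

        rec = StandardizationRecord(
            stats={"x": (0.0, 1.0), "y": (0.0, 1.0)},
            skipped=set(), outcome="y", outcome_family="continuous",
        )
        spec = bi.AnalysisSpec("y", "continuous", [bi.Covariate("x")])
        ch = self.chainset({"alpha0": [0.3, -0.1], "beta_x": [1.0, 2.0]})
        out = bi.unstandardize_draws(ch, rec, spec)
        np.testing.assert_allclose(out.draws["alpha0"], ch.draws["alpha0"])
        np.testing.assert_allclose(out.draws["beta_x"], ch.draws["beta_x"])

    def test_scale_formula(self):
        from bayimp.model_build import StandardizationRecord

        rec = StandardizationRecord(
            stats={"x": (0.0, 4.0), "y": (0.0, 2.0)},
            skipped=set(), outcome="y", outcome_family="continuous",
        )
        spec = bi.AnalysisSpec("y", "continuous", [bi.Covariate("x")])
        ch = self.chainset({"alpha0": [0.0], "beta_x": [1.0], "tau_x": [1.0],
                            "sigma_y": [1.0]})
        out = bi.unstandardize_draws(ch, rec, spec)
        assert out.draws["beta_x"][0, 0] == pytest.approx(0.5)
        assert out.draws["tau_x"][0, 0] == pytest.approx(0.5)
        assert out.draws["sigma_y"][0, 0] == pytest.approx(2.0)

    def test_least_squares_oracle_round_trip(self):
        # frozen 20-point toy set: back-transformed standardized OLS must
        # reproduce the raw OLS fit exactly (same quadratic objective)
        rng = np.random.default_rng(42)
        x = rng.uniform(10, 30, 20)
        y = 3.0 - 0.4 * x + rng.standard_normal(20)
        frame = pd.DataFrame({"g": [1, 2] * 10, "x": x, "y": y})
        ds = make_ds(frame, {"x": "continuous", "y": "continuous"})
        spec = bi.AnalysisSpec("y", "continuous", [bi.Covariate("x")])
        std, rec = bi.standardize_dataset(ds, spec, None)

        def ols(xv, yv):
            A = np.column_stack([np.ones_like(xv), xv])
            return np.linalg.lstsq(A, yv, rcond=None)[0]

        a_raw, b_raw = ols(x, y)
        a_std, b_std = ols(std.values["x"].to_numpy(), std.values["y"].to_numpy())
        ch = self.chainset({"alpha0": [a_std], "beta_x": [b_std]})
        out = bi.unstandardize_draws(ch, rec, spec)
        assert out.draws["alpha0"][0, 0] == pytest.approx(a_raw, abs=1e-8)
        assert out.draws["beta_x"][0, 0] == pytest.approx(b_raw, abs=1e-8)

    def test_missing_record_entry_raises(self):
        from bayimp.model_build import StandardizationRecord

        rec = StandardizationRecord(
            stats={"y": (0.0, 1.0)}, skipped=set(),
            outcome="y", outcome_family="continuous",
        )
        spec = bi.AnalysisSpec("y", "continuous", [bi.Covariate("x")])
        ch = self.chainset({"alpha0": [0.0], "beta_x": [1.0]})
        with pytest.raises(KeyError):
            bi.unstandardize_draws(ch, rec, spec)


class TestInitialValues:
    def test_neutral_start_and_latent_signs(self, mixed_ds, mixed_spec):
        ispec = bi.ImputationSpec.auto(mixed_ds, mixed_spec)
        std, _ = bi.standardize_dataset(mixed_ds, mixed_spec, ispec)
        model = bi.build_joint_model(std, mixed_spec, ispec)
        st = bi.default_initial_values(model, chain_index=1, seed=7)
        assert not st["b"].any() and not st["bf"].any() and not st["mu"].any()
        assert np.all(st["tau"] == 1.0)
        for d, t in enumerate(model.targets):
            if t.vtype == "binary":
                w = st["W"][t.obs, d]
                x = t.x_obs[t.obs]
                assert np.all((w > 0) == (x > 0.5))
                assert np.all(np.abs(w) == 0.5)

    def test_deterministic_and_dispersed(self, mixed_ds, mixed_spec):
        ispec = bi.ImputationSpec.auto(mixed_ds, mixed_spec)
        std, _ = bi.standardize_dataset(mixed_ds, mixed_spec, ispec)
        model = bi.build_joint_model(std, mixed_spec, ispec)
        a = bi.default_initial_values(model, chain_index=2, seed=7)
        b = bi.default_initial_values(model, chain_index=2, seed=7)
        np.testing.assert_array_equal(a["b"], b["b"])
        np.testing.assert_array_equal(a["W"], b["W"])
        c = bi.default_initial_values(model, chain_index=3, seed=7)
        assert not np.array_equal(a["b"], c["b"])
        assert c["b"].any()  # jittered away from zero
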