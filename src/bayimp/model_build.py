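"""Model declaration, standardization and the joint hierarchical model.

The analysis of interest is a hierarchical regression of an outcome on a set
of covariates, with per-cluster intercepts and (optionally) per-cluster
slopes.  Covariates with missing values are imputed *inside the same model*:
the vector of imputation targets for each subject follows a multivariate
normal distribution whose per-target means are themselves hierarchical
regressions on the fully observed covariates and the outcome.  Binary
targets are represented by latent normals through a probit link (x = 1{w>0},
unit variance for identifiability), so imputation of mixed binary/continuous
variables stays within one joint normal model.

On the standardized scale used for sampling, all location parameters get
vague normal priors and all standard deviations get uniform priors on
(0, sd_upper); the free correlations of the target covariance get a jointly
uniform prior over valid correlation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    BINARY,
    CONTINUOUS,
    MultilevelDataset,
    ValidationError,
)

FIXED = "fixed"
RANDOM = "random"


class SpecError(ValueError):
    """Analysis/imputation specification inconsistent with the data."""


class DegenerateModelError(SpecError):
    """No imputation targets: fit the analysis model alone instead."""


@dataclass(frozen=True)
class Covariate:
    name: str
    effect: str = RANDOM  # fixed | random

    def __post_init__(self):
        if self.effect not in (FIXED, RANDOM):
            raise SpecError(f"effect must be 'fixed' or 'random', got {self.effect!r}")


@dataclass
class AnalysisSpec:
    """Outcome, covariates and their fixed/random effect choices."""

    outcome: str
    outcome_family: str  # continuous | binary
    covariates: list[Covariate]
    intercept: str = RANDOM

    def __post_init__(self):
        if self.outcome_family not in (CONTINUOUS, BINARY):
            raise SpecError(f"unknown outcome family {self.outcome_family!r}")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise SpecError("covariate names must be unique")
        if self.outcome in names:
            raise SpecError("outcome cannot appear among the covariates")
        if self.intercept not in (FIXED, RANDOM):
            raise SpecError("intercept must be 'fixed' or 'random'")

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.covariates]


@dataclass
class ImputationTarget:
    name: str
    vtype: str  # continuous | binary
    predictors: list[Covariate] = field(default_factory=list)
    intercept: str = RANDOM

    def __post_init__(self):
        if self.name in [p.name for p in self.predictors]:
            raise SpecError(f"target {self.name!r} listed among its own predictors")


@dataclass
class ImputationSpec:
    """Which variables are imputed and from which predictors.

    By default every variable with any missing value becomes a target, with
    mean-model predictors = all fully observed covariates; other targets are
    excluded from the mean model (their dependence is carried by the residual
    covariance of the joint normal).  The outcome informs the imputations
    through the jointly fitted analysis likelihood, so it is *not* placed in
    the mean model as well: that would count the outcome-target association
    twice (the model graph would contain the cycle y -> x -> y) and
    measurably biases the residual SD and attenuates coefficients.  Pass
    ``include_outcome=True`` to add it anyway, e.g. to emulate a two-step
    workflow without feedback.
    """

    targets: list[ImputationTarget]

    def __post_init__(self):
        names = [t.name for t in self.targets]
        if len(set(names)) != len(names):
            raise SpecError("duplicate imputation targets")

    @property
    def target_names(self) -> list[str]:
        return [t.name for t in self.targets]

    @classmethod
    def auto(
        cls,
        ds: MultilevelDataset,
        analysis_spec: AnalysisSpec,
        predictor_effect: str = RANDOM,
        include_outcome: bool = False,
    ) -> "ImputationSpec":
        """Build the default spec: targets = analysis covariates with missing cells."""
        missing = [
            c.name
            for c in analysis_spec.covariates
            if not ds.mask[c.name].all()
        ]
        complete = [
            c.name
            for c in analysis_spec.covariates
            if c.name not in missing
        ]
        targets = []
        for name in missing:
            preds = [Covariate(p, predictor_effect) for p in complete]
            if include_outcome:
                preds.append(Covariate(analysis_spec.outcome, predictor_effect))
            targets.append(
                ImputationTarget(name=name, vtype=ds.var_types[name], predictors=preds)
            )
        return cls(targets=targets)


@dataclass
class PriorConfig:
    """Vague priors on the standardized scale (BUGS-style conventions)."""

    location_sd: float = 10.0  # Normal(0, location_sd^2) for all locations
    sd_upper: float = 10.0     # Uniform(0, sd_upper) for all SDs


@dataclass
class StandardizationRecord:
    """Sample means/SDs used to standardize, for exact back-transformation."""

    stats: dict[str, tuple[float, float]]  # name -> (mean, sd) over observed values
    skipped: set[str]                      # left on the original scale
    outcome: str
    outcome_family: str

    def mean_sd(self, name: str) -> tuple[float, float]:
        if name in self.skipped:
            return 0.0, 1.0
        if name not in self.stats:
            raise KeyError(f"no standardization record for {name!r}")
        return self.stats[name]


def standardize_dataset(
    ds: MultilevelDataset,
    analysis_spec: AnalysisSpec,
    imputation_spec: ImputationSpec | None,
) -> tuple[MultilevelDataset, StandardizationRecord]:
    """Center and scale all model variables to observed mean 0, SD 1.

    Binary imputation targets (imputed as zeros and ones through the probit
    latent) and a binary outcome are left untouched; everything else,
    including fully observed binary covariates, is standardized to speed
    MCMC convergence.  Returns the transformed dataset and the record needed
    to map posterior draws back to the original scale.
    """
    binary_targets = set()
    if imputation_spec is not None:
        binary_targets = {t.name for t in imputation_spec.targets if t.vtype == BINARY}
    model_vars = set(analysis_spec.covariate_names) | {analysis_spec.outcome}
    if imputation_spec is not None:
        for t in imputation_spec.targets:
            model_vars.add(t.name)
            model_vars.update(p.name for p in t.predictors)

    skipped = set(binary_targets)
    if analysis_spec.outcome_family == BINARY:
        skipped.add(analysis_spec.outcome)

    out = ds.copy()
    stats: dict[str, tuple[float, float]] = {}
    for name in sorted(model_vars - skipped):
        col = out.values[name].to_numpy()
        obs = col[~np.isnan(col)]
        m = float(obs.mean())
        s = float(obs.std(ddof=1))
        if not np.isfinite(s) or s <= 0.0:
            raise ValidationError(
                f"variable {name!r} is constant among observed values; "
                "cannot standardize"
            )
        out.values[name] = (col - m) / s
        stats[name] = (m, s)
    return out, StandardizationRecord(
        stats=stats,
        skipped=skipped,
        outcome=analysis_spec.outcome,
        outcome_family=analysis_spec.outcome_family,
    )


# ---------------------------------------------------------------------------
# Joint model container


@dataclass
class TargetModel:
    """Prepared arrays for one imputation target's latent-normal equation."""

    name: str
    vtype: str
    x_obs: np.ndarray            # (n,) observed values, NaN at missing
    obs: np.ndarray              # (n,) bool
    analysis_col: int | None     # column of this target in the analysis design
    Zp: np.ndarray               # (n, 1+P) predictor design, col 0 = intercept
    pred_names: list[str]
    rand_idx: np.ndarray         # columns of Zp with random (per-cluster) coefs
    fix_idx: np.ndarray


@dataclass
class JointModel:
    """The full generative specification, with data prepared for sampling."""

    y: np.ndarray                # (n,) outcome on the sampling scale
    family: str
    cluster: np.ndarray          # (n,) 0-based codes
    J: int
    rows_by_cluster: list[np.ndarray]
    X_obs: np.ndarray            # (n, K) covariates, NaN at missing
    cov_names: list[str]
    cov_types: list[str]
    cov_random: np.ndarray       # (K,) bool
    intercept_random: bool
    targets: list[TargetModel]
    priors: PriorConfig
    fixed_residual_sd: float | None = None
    fixed_intercept_sd: float | None = None

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def monitored(self) -> list[str]:
        names = ["alpha0"]
        names += [f"beta_{c}" for c in self.cov_names]
        if self.intercept_random:
            names.append("tau_alpha")
        names += [f"tau_{c}" for c, r in zip(self.cov_names, self.cov_random) if r]
        if self.family == CONTINUOUS:
            names.append("sigma_y")
        return names


def build_joint_model(
    ds_std: MultilevelDataset,
    analysis_spec: AnalysisSpec,
    imputation_spec: ImputationSpec | None,
    priors: PriorConfig | None = None,
    fixed_residual_sd: float | None = None,
    fixed_intercept_sd: float | None = None,
) -> JointModel:
    """Assemble the joint hierarchical model from data and specs.

    Pass ``imputation_spec=None`` to build the analysis model alone (used for
    complete data, and for the naive analysis).  An imputation spec with zero
    targets raises :class:`DegenerateModelError` directing the caller to the
    analysis-only route.
    """
    priors = priors or PriorConfig()
    if imputation_spec is not None and not imputation_spec.targets:
        raise DegenerateModelError(
            "no imputation targets declared; fit the analysis model alone "
            "(imputation_spec=None)"
        )
    for name in [analysis_spec.outcome] + analysis_spec.covariate_names:
        if name not in ds_std.variables:
            raise SpecError(f"variable {name!r} not present in the dataset")

    y = ds_std.values[analysis_spec.outcome].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise SpecError(
            "outcome has missing values; exclude those rows first "
            "(see data_model.drop_missing_outcome)"
        )
    X = ds_std.values[analysis_spec.covariate_names].to_numpy(dtype=float)
    target_names = [] if imputation_spec is None else imputation_spec.target_names

    for k, name in enumerate(analysis_spec.covariate_names):
        if np.isnan(X[:, k]).any() and name not in target_names:
            raise SpecError(
                f"covariate {name!r} has missing values but is not an "
                "imputation target"
            )

    targets: list[TargetModel] = []
    if imputation_spec is not None:
        for t in imputation_spec.targets:
            if t.name not in ds_std.variables:
                raise SpecError(f"imputation target {t.name!r} not in the dataset")
            if t.name in [p.name for p in t.predictors]:
                raise SpecError(f"target {t.name!r} is its own predictor")
            for p in t.predictors:
                if p.name in target_names:
                    raise SpecError(
                        f"target {p.name!r} cannot predict target {t.name!r}: "
                        "targets are linked through the residual covariance"
                    )
                if p.name not in ds_std.variables:
                    raise SpecError(f"predictor {p.name!r} not in the dataset")
                if not ds_std.mask[p.name].all():
                    raise SpecError(
                        f"predictor {p.name!r} of target {t.name!r} has missing "
                        "values; only fully observed predictors are allowed"
                    )
            x_obs = ds_std.values[t.name].to_numpy(dtype=float)
            cols = [np.ones(len(x_obs))]
            cols += [ds_std.values[p.name].to_numpy(dtype=float) for p in t.predictors]
            Zp = np.column_stack(cols)
            rand = [t.intercept == RANDOM] + [p.effect == RANDOM for p in t.predictors]
            rand = np.asarray(rand, dtype=bool)
            try:
                acol = analysis_spec.covariate_names.index(t.name)
            except ValueError:
                acol = None
            targets.append(
                TargetModel(
                    name=t.name,
                    vtype=t.vtype,
                    x_obs=x_obs,
                    obs=~np.isnan(x_obs),
                    analysis_col=acol,
                    Zp=Zp,
                    pred_names=[p.name for p in t.predictors],
                    rand_idx=np.flatnonzero(rand),
                    fix_idx=np.flatnonzero(~rand),
                )
            )

    J = ds_std.n_clusters
    rows_by_cluster = [ds_std.rows_of_cluster(j) for j in range(J)]
    return JointModel(
        y=y,
        family=analysis_spec.outcome_family,
        cluster=ds_std.cluster_codes.copy(),
        J=J,
        rows_by_cluster=rows_by_cluster,
        X_obs=X,
        cov_names=list(analysis_spec.covariate_names),
        cov_types=[ds_std.var_types[c] for c in analysis_spec.covariate_names],
        cov_random=np.asarray(
            [c.effect == RANDOM for c in analysis_spec.covariates], dtype=bool
        ),
        intercept_random=analysis_spec.intercept == RANDOM,
        targets=targets,
        priors=priors,
        fixed_residual_sd=fixed_residual_sd,
        fixed_intercept_sd=fixed_intercept_sd,
    )


# ---------------------------------------------------------------------------
# Initial values


def default_initial_values(model: JointModel, chain_index: int, seed: int) -> dict:
    """Deterministic starting state for one chain.

    Chain 1 starts at the neutral point (coefficients 0, SDs 1, identity
    correlation, missing continuous cells at their cluster means, latents at
    +-0.5 consistent with observed binaries); higher chain indices apply a
    seeded jitter so chains start dispersed.
    """
    rng = np.random.default_rng([int(seed) % (2**31), int(chain_index)])
    K = model.X_obs.shape[1]
    R = int(model.intercept_random) + int(model.cov_random.sum())
    F = (1 + K) - R
    state: dict = {
        "b": np.zeros((model.J, R)),
        "bf": np.zeros(F),
        "mu": np.zeros(R),
        "tau": np.ones(R),
        "sigma_y": 1.0,
    }
    if model.fixed_residual_sd is not None:
        state["sigma_y"] = float(model.fixed_residual_sd)
    if model.fixed_intercept_sd is not None and model.intercept_random:
        state["tau"][0] = float(model.fixed_intercept_sd)

    # current covariate matrix: missing continuous cells at cluster means
    X = model.X_obs.copy()
    for k in range(K):
        col = X[:, k]
        miss = np.isnan(col)
        if not miss.any():
            continue
        grand = np.nanmean(col) if np.isfinite(np.nanmean(col)) else 0.0
        for j, rows in enumerate(model.rows_by_cluster):
            cm = miss[rows]
            if not cm.any():
                continue
            obs_vals = col[rows][~cm]
            fill = obs_vals.mean() if obs_vals.size else grand
            if model.cov_types[k] == BINARY:
                fill = float(fill >= 0.5) if np.isfinite(fill) else 0.0
            X[rows[cm], k] = fill
    state["X"] = X

    D = model.n_targets
    W = np.zeros((model.n, D))
    g_blocks = []
    for d, t in enumerate(model.targets):
        if t.vtype == CONTINUOUS:
            w = np.where(t.obs, np.nan_to_num(t.x_obs), 0.0)
            if t.analysis_col is not None:
                w = np.where(t.obs, w, X[:, t.analysis_col])
        else:
            w = np.where(np.nan_to_num(t.x_obs) > 0.5, 0.5, -0.5)
            w = np.where(t.obs, w, rng.standard_normal(model.n))
        W[:, d] = w
        Rd, Fd = t.rand_idx.size, t.fix_idx.size
        g_blocks.append(
            {
                "b": np.zeros((model.J, Rd)),
                "bf": np.zeros(Fd),
                "mu": np.zeros(Rd),
                "tau": np.ones(Rd),
            }
        )
    state["W"] = W
    state["g"] = g_blocks
    state["Sigma_scale"] = np.array(
        [1.0 for t in model.targets]
    )  # binary scales stay fixed at 1
    state["Sigma_corr"] = np.eye(D)

    if model.family == BINARY:
        state["u"] = np.where(model.y > 0.5, 0.5, -0.5)

    if chain_index > 1:
        for key in ("b", "bf", "mu"):
            state[key] = state[key] + rng.normal(0.0, 0.5, size=np.shape(state[key]))
        for blk in state["g"]:
            for key in ("b", "bf", "mu"):
                blk[key] = blk[key] + rng.normal(0.0, 0.5, size=np.shape(blk[key]))
        jitter = np.exp(rng.normal(0.0, 0.3, size=state["tau"].shape))
        free = np.ones_like(state["tau"], dtype=bool)
        if model.fixed_intercept_sd is not None and model.intercept_random:
            free[0] = False
        state["tau"] = np.where(free, np.clip(state["tau"] * jitter, 0.05, 9.5),
                                state["tau"])
        if model.fixed_residual_sd is None:
            state["sigma_y"] = float(
                np.clip(state["sigma_y"] * np.exp(rng.normal(0.0, 0.3)), 0.05, 9.5)
            )
    return state


# ---------------------------------------------------------------------------
# Back-transformation of posterior draws


def unstandardize_draws(chains, record: StandardizationRecord, analysis_spec):
    """Map posterior draws from the standardized scale back to the original.

    Applied draw by draw (never to summaries): with outcome mean/SD
    (ybar, s_y) and covariate stats (xbar_k, s_k) -- both taken as (0, 1)
    for variables left unstandardized --

    continuous outcome:
        beta_k  = beta*_k * s_y / s_k
        alpha0  = ybar + s_y * alpha0* - sum_k beta_k * xbar_k
        sigma_y = sigma*_y * s_y ;  tau_k = tau*_k * s_y / s_k ;
        tau_alpha = tau*_alpha * s_y
    binary outcome:
        beta_k = beta*_k / s_k ;  tau_k = tau*_k / s_k ;
        alpha0 = alpha0* - sum_k beta_k * xbar_k
    """
    from .gibbs import ChainSet  # local import to avoid a cycle

    if record.outcome_family == CONTINUOUS:
        ybar, s_y = record.mean_sd(record.outcome)
    else:
        ybar, s_y = 0.0, 1.0

    draws = {name: arr.copy() for name, arr in chains.draws.items()}
    names = [c.name for c in analysis_spec.covariates]
    alpha = draws["alpha0"]
    shift = np.zeros_like(alpha)
    for name in names:
        key = f"beta_{name}"
        if key not in draws:
            raise KeyError(f"draws are missing parameter {key!r}")
        xbar, s_k = record.mean_sd(name)
        draws[key] = draws[key] * (s_y / s_k)
        shift = shift + draws[key] * xbar
        tkey = f"tau_{name}"
        if tkey in draws:
            draws[tkey] = draws[tkey] * (s_y / s_k)
    draws["alpha0"] = ybar + s_y * alpha - shift
    if "tau_alpha" in draws:
        draws["tau_alpha"] = draws["tau_alpha"] * s_y
    if "sigma_y" in draws:
        draws["sigma_y"] = draws["sigma_y"] * s_y
    return ChainSet(
        draws=draws,
        iterations=chains.iterations.copy(),
        settings=chains.settings,
        param_names=list(chains.param_names),
    )
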