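"""Synthetic multilevel data with known ground truth.

Emulates the structure of a multicentre epidemiological study: ~10 centres
of several hundred subjects each, a continuous outcome (e.g. a lung-function
ratio) regressed on a mix of binary and continuous covariates, with
between-centre heterogeneity in every intercept and slope.  Covariates are
drawn from a Gaussian copula so the cross-variable dependence that the joint
multivariate-normal imputation model exploits is under explicit control.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .data_model import BINARY, CONTINUOUS, MultilevelDataset, assign_roles

DEFAULT_CLUSTER_VAR = "centre"


@dataclass
class CovariateTruth:
    """Generating law for one covariate and its effect on the outcome."""

    name: str
    vtype: str                 # continuous | binary
    beta: float                # fixed-effect mean on the outcome (original units)
    tau: float = 0.0           # SD of the per-cluster slope around beta
    mean: float = 0.0          # continuous: grand mean
    sd: float = 1.0            # continuous: within-cluster SD
    between_sd: float = 0.0    # continuous: SD of per-cluster mean shifts
    prevalence: float = 0.5    # binary: grand prevalence
    prevalence_logit_sd: float = 0.0  # binary: SD of per-cluster logit shifts


@dataclass
class SimulationTruth:
    """Complete generative specification of a multilevel dataset."""

    J: int
    cluster_sizes: list[int]
    alpha0: float
    tau_alpha: float
    sigma_y: float
    covariates: list[CovariateTruth]
    correlation: np.ndarray    # copula correlation of the covariates (K x K)
    outcome: str = "y"
    cluster_var: str = DEFAULT_CLUSTER_VAR
    seed: int = 0

    def validate(self) -> None:
        K = len(self.covariates)
        if self.J < 2:
            raise ValueError("need at least 2 clusters")
        if len(self.cluster_sizes) != self.J:
            raise ValueError("cluster_sizes must have length J")
        if self.tau_alpha < 0 or self.sigma_y < 0:
            raise ValueError("SDs must be >= 0")
        for c in self.covariates:
            if c.tau < 0:
                raise ValueError(f"{c.name}: tau must be >= 0")
            if c.vtype == BINARY and not (0.0 < c.prevalence < 1.0):
                raise ValueError(f"{c.name}: prevalence must be in (0,1)")
            if c.vtype == CONTINUOUS and c.sd <= 0:
                raise ValueError(f"{c.name}: sd must be > 0")
        R = np.asarray(self.correlation, dtype=float)
        if R.shape != (K, K):
            raise ValueError("correlation matrix shape mismatch")
        if not np.allclose(R, R.T):
            raise ValueError("correlation matrix must be symmetric")
        if np.min(np.linalg.eigvalsh(R)) <= 0:
            raise ValueError("correlation matrix must be positive-definite")

    def to_json_dict(self) -> dict:
        d = asdict(self)
        d["correlation"] = np.asarray(self.correlation).tolist()
        return d


def simulate_multilevel(truth: SimulationTruth):
    """Generate one complete dataset plus the realized per-cluster effects.

    Cluster intercepts and slopes are drawn from their stated normals, the
    covariates from the Gaussian copula (binaries thresholded at the
    cluster-specific prevalence), and the outcome from the linear model with
    residual SD sigma_y.  Slope heterogeneity acts around the covariate
    grand means,

        y = alpha_j + sum_k beta_k x_k + sum_k (beta_kj - beta_k)(x_k - m_k) + e,

    so that tau_alpha alone controls the spread of cluster-mean outcomes (a
    raw-slope parameterization would let slope deviations on uncentered
    covariates dwarf it).  Returns ``(dataset, realized)`` where ``realized``
    carries alpha_j and beta_kj for recovery testing.
    """
    truth.validate()
    rng = np.random.default_rng(int(truth.seed) % (2**31))
    K = len(truth.covariates)
    L = np.linalg.cholesky(np.asarray(truth.correlation, dtype=float))

    alpha_j = truth.alpha0 + truth.tau_alpha * rng.standard_normal(truth.J)
    beta_jk = np.empty((truth.J, K))
    for k, c in enumerate(truth.covariates):
        beta_jk[:, k] = c.beta + c.tau * rng.standard_normal(truth.J)
    shifts = np.empty((truth.J, K))
    for k, c in enumerate(truth.covariates):
        if c.vtype == CONTINUOUS:
            shifts[:, k] = c.between_sd * rng.standard_normal(truth.J)
        else:
            shifts[:, k] = expit(
                logit(c.prevalence)
                + c.prevalence_logit_sd * rng.standard_normal(truth.J)
            )

    grand_mean = np.array(
        [c.mean if c.vtype == CONTINUOUS else c.prevalence for c in truth.covariates]
    )
    beta_mean = np.array([c.beta for c in truth.covariates])
    frames = []
    for j in range(truth.J):
        n_j = int(truth.cluster_sizes[j])
        Z = rng.standard_normal((n_j, K)) @ L.T
        X = np.empty((n_j, K))
        for k, c in enumerate(truth.covariates):
            if c.vtype == CONTINUOUS:
                X[:, k] = c.mean + shifts[j, k] + c.sd * Z[:, k]
            else:
                X[:, k] = (norm.cdf(Z[:, k]) < shifts[j, k]).astype(float)
        y = (
            alpha_j[j]
            + X @ beta_mean
            + (X - grand_mean) @ (beta_jk[j] - beta_mean)
            + truth.sigma_y * rng.standard_normal(n_j)
        )
        frame = pd.DataFrame(X, columns=[c.name for c in truth.covariates])
        frame[truth.outcome] = y
        frame[truth.cluster_var] = j + 1
        frames.append(frame)
    full = pd.concat(frames, ignore_index=True)

    types = {c.name: c.vtype for c in truth.covariates}
    types[truth.outcome] = CONTINUOUS
    ds = assign_roles(
        MultilevelDataset.from_frame(full), cluster_var=truth.cluster_var, types=types
    )
    realized = {
        "alpha_j": alpha_j,
        "beta_jk": beta_jk,
        "covariates": [c.name for c in truth.covariates],
    }
    return ds, realized


def multicentre_preset(scale: str = "desk", seed: int = 0) -> SimulationTruth:
    """A study-like generating truth: continuous lung-function-style outcome
    on smoking (binary), weight, sex (binary), height and age.

    ``full``: 10 centres of 521-1047 subjects; ``desk``: 6 centres of 80-120
    subjects with the same structure, sized for fast tests.  Fixed effects
    are of order 0.2-1.0 on the standardized scale with slope-heterogeneity
    ratios tau/beta around 0.2-0.5.
    """
    rng = np.random.default_rng(int(seed) % (2**31))
    if scale == "full":
        J = 10
        sizes = rng.integers(521, 1048, size=J).tolist()
    elif scale == "desk":
        J = 6
        sizes = rng.integers(80, 121, size=J).tolist()
    else:
        raise ValueError("scale must be 'full' or 'desk'")

    covs = [
        CovariateTruth("smoking", BINARY, beta=-2.5, tau=0.8,
                       prevalence=0.5, prevalence_logit_sd=0.3),
        CovariateTruth("weight", CONTINUOUS, beta=-0.15, tau=0.05,
                       mean=75.0, sd=12.0, between_sd=2.0),
        CovariateTruth("sex", BINARY, beta=1.5, tau=0.5,
                       prevalence=0.5, prevalence_logit_sd=0.2),
        CovariateTruth("height", CONTINUOUS, beta=0.25, tau=0.08,
                       mean=170.0, sd=9.0, between_sd=2.0),
        CovariateTruth("age", CONTINUOUS, beta=-0.20, tau=0.06,
                       mean=45.0, sd=10.0, between_sd=1.5),
    ]
    # smoking/weight/sex/height/age copula correlations: height-sex and
    # height-weight strongly linked, the rest weakly
    R = np.array(
        [
            [1.00, 0.05, 0.00, 0.05, 0.20],
            [0.05, 1.00, -0.25, 0.50, 0.10],
            [0.00, -0.25, 1.00, -0.45, 0.00],
            [0.05, 0.50, -0.45, 1.00, -0.05],
            [0.20, 0.10, 0.00, -0.05, 1.00],
        ]
    )
    truth = SimulationTruth(
        J=J,
        cluster_sizes=sizes,
        alpha0=70.0,
        tau_alpha=2.0,
        sigma_y=5.0,
        covariates=covs,
        correlation=R,
        seed=int(rng.integers(0, 2**31)),
    )
    truth.validate()
    return truth


def induce_sporadic(
    ds: MultilevelDataset,
    rate: float,
    variables=None,
    mechanism: str = "MCAR",
    mar_var: str | None = None,
    seed: int = 0,
):
    """Mask individual cells sporadically, MCAR or MAR.

    MCAR masks each eligible cell independently with probability ``rate``.
    MAR makes the masking probability logistic in the named fully observed
    variable (unit slope on its standardized value), with the intercept
    calibrated so the marginal masking rate is ``rate``.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    out = ds.copy()
    if variables is None:
        variables = ds.variables
    rng = np.random.default_rng(int(seed) % (2**31))
    if rate == 0.0:
        return out

    if mechanism == "MCAR":
        p = np.full(ds.n_rows, rate)
    elif mechanism == "MAR":
        if mar_var is None:
            raise ValueError("MAR requires mar_var")
        col = ds.values[mar_var].to_numpy(dtype=float)
        if np.isnan(col).any():
            raise ValueError(f"MAR conditioning variable {mar_var!r} has missing values")
        z = (col - col.mean()) / col.std(ddof=1)

        def marginal(a):
            return expit(a + z).mean() - rate

        a = brentq(marginal, -40.0, 40.0)
        p = expit(a + z)
    else:
        raise ValueError("mechanism must be 'MCAR' or 'MAR'")

    for name in variables:
        if name == mar_var:
            continue
        hit = rng.random(ds.n_rows) < p
        col = out.values[name].to_numpy(dtype=float)
        col[hit] = np.nan
        out.values[name] = col
        out.mask[name] = ~np.isnan(col)
    out.check_invariants()
    return out
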