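"""Gibbs sampler for the joint imputation-and-analysis model.

The posterior is explored by blocked Gibbs updates with latent-variable data
augmentation:

* per-cluster regression coefficients, their hyper-means and the global
  fixed-effect coefficients have conjugate (multivariate) normal full
  conditionals;
* every standard deviation carries a Uniform(0, upper) prior, giving a
  truncated inverse-gamma full conditional for the variance;
* binary cells enter through latent normals w with x = 1{w > 0}; observed
  binaries constrain w to a half-line (truncated-normal draw) and missing
  binaries are sampled by first choosing the side with the exact posterior
  odds (imputation-model conditional x analysis likelihood) and then drawing
  w from the matching truncated normal;
* missing continuous cells combine the multivariate-normal imputation
  conditional with the analysis likelihood in a conjugate normal draw;
* the free elements of the target covariance (continuous scales and the
  correlations) are updated by Metropolis steps on log/atanh scales.

Missing cells are sampled as parameters of the one chain: imputation is a
by-product of the MCMC and no multiple imputed datasets are materialized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky, LinAlgError
from scipy.special import gammainc, gammaincinv, log_ndtr, ndtri_exp

from .data_model import BINARY, CONTINUOUS
from .model_build import JointModel, default_initial_values

logger = logging.getLogger(__name__)


class SamplerError(RuntimeError):
    pass


@dataclass
class McmcSettings:
    """Burn-in/updates/chains control, mirroring the interactive tool knobs."""

    burn_in: int = 5000
    updates: int = 10000
    n_chains: int = 2
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.updates < 100:
            raise ValueError("updates must be >= 100")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def retained(self) -> int:
        return self.updates // self.thin


@dataclass
class ChainSet:
    """Posterior draws per monitored parameter, one row per chain."""

    draws: dict[str, np.ndarray]        # name -> (n_chains, retained)
    iterations: np.ndarray              # retained iteration numbers (post burn-in)
    settings: McmcSettings
    param_names: list[str]

    def pooled(self, param: str) -> np.ndarray:
        return self.draws[param].reshape(-1)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]


# ---------------------------------------------------------------------------
# primitives


def sample_truncated_normal(mean, sd, side: str, rng, size=None):
    """Draw from Normal(mean, sd^2) truncated strictly above or below zero.

    ``side`` is ``"above"`` (w > 0) or ``"below"`` (w < 0).  Vectorized over
    ``mean``; numerically robust far into the tail (|mean|/sd up to ~8 and
    beyond, via scipy's inverse-CDF truncated sampler).
    """
    mean = np.asarray(mean, dtype=float)
    sd_arr = np.asarray(sd, dtype=float)
    if np.any(sd_arr <= 0):
        raise ValueError("sd must be > 0")
    if side not in ("above", "below"):
        raise ValueError("side must be 'above' or 'below'")
    if size is None:
        size = np.broadcast_shapes(mean.shape, sd_arr.shape)
    # inverse-CDF in log space: for Z ~ N(0,1) | Z > a, draw U ~ Uniform(0,1)
    # and solve P(Z > z) = U * P(Z > a), i.e. z = -ndtri_exp(log U + log_ndtr(-a));
    # stable however far the truncation point sits in the tail
    if side == "above":
        a = (0.0 - mean) / sd_arr
    else:
        a = (0.0 + mean) / sd_arr  # mirror: sample above, then negate
    logu = np.log(rng.random(size))
    z = -ndtri_exp(logu + log_ndtr(-a))
    if side == "above":
        draw = mean + sd_arr * z
    else:
        draw = mean - sd_arr * z
    # guard against boundary round-off: the draw must lie strictly on the side
    tiny = 1e-300
    if side == "above":
        draw = np.maximum(draw, tiny)
    else:
        draw = np.minimum(draw, -tiny)
    return draw


def _sample_var_trunc_invgamma(rng, shape: float, scale: float, upper_var: float) -> float:
    """Variance draw for SD ~ Uniform(0, sqrt(upper_var)) conjugate updates.

    Full conditional of the variance v given a normal sum of squares is
    InvGamma(shape, scale) restricted to (0, upper_var); sampled through the
    gamma inverse-CDF of 1/v.
    """
    scale = max(float(scale), 1e-300)
    # 1/v ~ Gamma(shape, rate=scale) truncated to 1/v > 1/upper_var
    lo = gammainc(shape, scale / upper_var)
    u = rng.uniform(lo, 1.0)
    g = gammaincinv(shape, u) / scale
    g = max(g, 1.0 / upper_var)  # round-off guard: keep v <= upper_var
    return 1.0 / g


def _fitted(Z, blk, cluster, rand_idx, fix_idx):
    out = np.zeros(Z.shape[0])
    if rand_idx.size:
        out += np.einsum("ij,ij->i", Z[:, rand_idx], blk["b"][cluster])
    if fix_idx.size:
        out += Z[:, fix_idx] @ blk["bf"]
    return out


def _update_hier_block(
    rng,
    resp,
    Z,
    cluster,
    rows_by_cluster,
    blk,
    rand_idx,
    fix_idx,
    noise_var,
    loc_sd,
    sd_upper,
    frozen_tau=None,
):
    """One Gibbs sweep of a hierarchical normal regression block.

    Random-effect columns get per-cluster coefficients b_j ~ N(mu, diag(tau^2))
    with mu ~ N(0, loc_sd^2) and tau ~ Uniform(0, sd_upper); fixed columns get
    global coefficients ~ N(0, loc_sd^2).  ``frozen_tau`` is a boolean mask
    over random terms whose tau is held fixed.
    """
    R, F = rand_idx.size, fix_idx.size
    J = len(rows_by_cluster)
    Zr = Z[:, rand_idx] if R else None
    Zf = Z[:, fix_idx] if F else None

    if R:
        offset = Zf @ blk["bf"] if F else np.zeros(resp.size)
        prior_prec = 1.0 / blk["tau"] ** 2
        for j, rows in enumerate(rows_by_cluster):
            Zrj = Zr[rows]
            rj = resp[rows] - offset[rows]
            A = Zrj.T @ Zrj / noise_var
            A[np.diag_indices_from(A)] += prior_prec
            bvec = Zrj.T @ rj / noise_var + blk["mu"] * prior_prec
            try:
                cf = cho_factor(A, lower=True)
            except LinAlgError as exc:
                raise SamplerError(f"singular precision in cluster block: {exc}")
            mean = cho_solve(cf, bvec)
            L = np.tril(cf[0])
            z = rng.standard_normal(R)
            blk["b"][j] = mean + np.linalg.solve(L.T, z)

    if F:
        offset = (
            np.einsum("ij,ij->i", Zr, blk["b"][cluster]) if R else np.zeros(resp.size)
        )
        A = Zf.T @ Zf / noise_var
        A[np.diag_indices_from(A)] += 1.0 / loc_sd**2
        bvec = Zf.T @ (resp - offset) / noise_var
        cf = cho_factor(A, lower=True)
        mean = cho_solve(cf, bvec)
        L = np.tril(cf[0])
        blk["bf"] = mean + np.linalg.solve(L.T, rng.standard_normal(F))

    if R:
        # hyper-means
        prec = J / blk["tau"] ** 2 + 1.0 / loc_sd**2
        mean = (blk["b"].sum(axis=0) / blk["tau"] ** 2) / prec
        blk["mu"] = mean + rng.standard_normal(R) / np.sqrt(prec)
        # hyper-SDs
        for k in range(R):
            if frozen_tau is not None and frozen_tau[k]:
                continue
            S = float(((blk["b"][:, k] - blk["mu"][k]) ** 2).sum())
            v = _sample_var_trunc_invgamma(rng, (J - 1) / 2.0, S / 2.0, sd_upper**2)
            blk["tau"][k] = np.sqrt(v)


# ---------------------------------------------------------------------------
# the sampler


class _Sampler:
    def __init__(self, model: JointModel, state: dict, rng):
        self.m = model
        self.st = state
        self.rng = rng
        K = model.X_obs.shape[1]
        term_random = np.concatenate(([model.intercept_random], model.cov_random))
        self.a_rand_idx = np.flatnonzero(term_random)
        self.a_fix_idx = np.flatnonzero(~term_random)
        # positions of each term within its block
        self.term_pos = np.empty(1 + K, dtype=int)
        self.term_pos[self.a_rand_idx] = np.arange(self.a_rand_idx.size)
        self.term_pos[self.a_fix_idx] = np.arange(self.a_fix_idx.size)
        self.term_random = term_random
        self.frozen_tau = None
        if model.intercept_random and model.fixed_intercept_sd is not None:
            self.frozen_tau = np.zeros(self.a_rand_idx.size, dtype=bool)
            self.frozen_tau[0] = True
        D = model.n_targets
        self.cont_targets = [d for d, t in enumerate(model.targets) if t.vtype == CONTINUOUS]
        n = model.n
        self.mh_step = max(0.02, 2.5 / np.sqrt(max(n, 1)))
        self.M = np.zeros((n, D))
        for d, t in enumerate(model.targets):
            self.M[:, d] = _fitted(t.Zp, state["g"][d], model.cluster, t.rand_idx, t.fix_idx)
        self._sigma_parts()
        self._check_initial_state()

    # -- helpers ----------------------------------------------------------

    def _check_initial_state(self):
        m = self.m
        for name, arr in (("outcome", m.y), ("covariates", self.st["X"])):
            if not np.all(np.isfinite(arr)):
                raise SamplerError(f"non-finite values in the {name} block at start")
        if m.n_targets and not np.all(np.isfinite(self.st["W"])):
            raise SamplerError("non-finite latent values in the imputation block at start")

    def Sigma(self) -> np.ndarray:
        s = self.st["Sigma_scale"]
        return self.st["Sigma_corr"] * np.outer(s, s)

    def _sigma_parts(self):
        """Precompute the conditional regressions w_d | w_{-d} from Sigma."""
        D = self.m.n_targets
        self.cond_s = []
        self.cond_var = []
        if D == 0:
            return
        Sig = self.Sigma()
        for d in range(D):
            others = [k for k in range(D) if k != d]
            if not others:
                self.cond_s.append(np.zeros(0))
                self.cond_var.append(float(Sig[d, d]))
                continue
            So = Sig[np.ix_(others, others)]
            sv = np.linalg.solve(So, Sig[others, d])
            self.cond_s.append(sv)
            self.cond_var.append(float(Sig[d, d] - Sig[d, others] @ sv))

    def _analysis_design(self):
        return np.column_stack([np.ones(self.m.n), self.st["X"]])

    def _analysis_resp(self):
        if self.m.family == CONTINUOUS:
            return self.m.y, self.st["sigma_y"] ** 2
        return self.st["u"], 1.0

    def _coef_rows(self, col: int) -> np.ndarray:
        """Per-row analysis coefficient of covariate column ``col``."""
        term = 1 + col
        pos = self.term_pos[term]
        if self.term_random[term]:
            return self.st["b"][self.m.cluster, pos]
        return np.full(self.m.n, self.st["bf"][pos])

    # -- update steps -----------------------------------------------------

    def step(self):
        m, st, rng = self.m, self.st, self.rng
        Z = self._analysis_design()

        # latent outcome for a binary (probit) outcome
        if m.family == BINARY:
            eta = _fitted(Z, st, m.cluster, self.a_rand_idx, self.a_fix_idx)
            pos = m.y > 0.5
            u = np.empty(m.n)
            if pos.any():
                u[pos] = sample_truncated_normal(eta[pos], 1.0, "above", rng)
            if (~pos).any():
                u[~pos] = sample_truncated_normal(eta[~pos], 1.0, "below", rng)
            st["u"] = u

        resp, nv = self._analysis_resp()
        _update_hier_block(
            rng, resp, Z, m.cluster, m.rows_by_cluster, st,
            self.a_rand_idx, self.a_fix_idx, nv,
            m.priors.location_sd, m.priors.sd_upper, frozen_tau=self.frozen_tau,
        )
        eta = _fitted(Z, st, m.cluster, self.a_rand_idx, self.a_fix_idx)

        # residual SD
        if m.family == CONTINUOUS and m.fixed_residual_sd is None:
            ssr = float(((m.y - eta) ** 2).sum())
            v = _sample_var_trunc_invgamma(
                rng, (m.n - 1) / 2.0, ssr / 2.0, m.priors.sd_upper**2
            )
            st["sigma_y"] = np.sqrt(v)

        if m.n_targets:
            self._update_imputation(eta)

    def _update_imputation(self, eta):
        m, st, rng = self.m, self.st, self.rng
        D = m.n_targets
        W, M = st["W"], self.M
        resp_a, nv = self._analysis_resp()

        # 1. mean-model coefficients per target (conditional regression given
        #    the other components through Sigma)
        for d, t in enumerate(m.targets):
            sv, cvar = self.cond_s[d], self.cond_var[d]
            others = [k for k in range(D) if k != d]
            corr_off = (W[:, others] - M[:, others]) @ sv if others else 0.0
            resp_d = W[:, d] - corr_off
            _update_hier_block(
                rng, resp_d, t.Zp, m.cluster, m.rows_by_cluster, st["g"][d],
                t.rand_idx, t.fix_idx, cvar,
                m.priors.location_sd, m.priors.sd_upper,
            )
            M[:, d] = _fitted(t.Zp, st["g"][d], m.cluster, t.rand_idx, t.fix_idx)

        # 2. latent values / imputed cells
        for d, t in enumerate(m.targets):
            sv, cvar = self.cond_s[d], self.cond_var[d]
            csd = np.sqrt(cvar)
            others = [k for k in range(D) if k != d]
            cmean = M[:, d] + ((W[:, others] - M[:, others]) @ sv if others else 0.0)
            miss = ~t.obs
            if t.vtype == BINARY:
                obs_rows = np.flatnonzero(t.obs)
                if obs_rows.size:
                    x1 = t.x_obs[obs_rows] > 0.5
                    if x1.any():
                        W[obs_rows[x1], d] = sample_truncated_normal(
                            cmean[obs_rows[x1]], csd, "above", rng
                        )
                    if (~x1).any():
                        W[obs_rows[~x1], d] = sample_truncated_normal(
                            cmean[obs_rows[~x1]], csd, "below", rng
                        )
                rows = np.flatnonzero(miss)
                if rows.size:
                    lp1 = log_ndtr(cmean[rows] / csd)
                    lp0 = log_ndtr(-cmean[rows] / csd)
                    if t.analysis_col is not None:
                        coef = self._coef_rows(t.analysis_col)[rows]
                        r = resp_a[rows] - eta[rows] + coef * st["X"][rows, t.analysis_col]
                        lp1 = lp1 - (r - coef) ** 2 / (2.0 * nv)
                        lp0 = lp0 - r**2 / (2.0 * nv)
                    p1 = 1.0 / (1.0 + np.exp(lp0 - lp1))
                    x_new = (rng.random(rows.size) < p1).astype(float)
                    up = x_new > 0.5
                    if up.any():
                        W[rows[up], d] = sample_truncated_normal(
                            cmean[rows[up]], csd, "above", rng
                        )
                    if (~up).any():
                        W[rows[~up], d] = sample_truncated_normal(
                            cmean[rows[~up]], csd, "below", rng
                        )
                    if t.analysis_col is not None:
                        old = st["X"][rows, t.analysis_col]
                        st["X"][rows, t.analysis_col] = x_new
                        eta[rows] += coef * (x_new - old)
            else:
                rows = np.flatnonzero(miss)
                if rows.size:
                    if t.analysis_col is not None:
                        coef = self._coef_rows(t.analysis_col)[rows]
                        r = resp_a[rows] - eta[rows] + coef * st["X"][rows, t.analysis_col]
                        prec = 1.0 / cvar + coef**2 / nv
                        mean = (cmean[rows] / cvar + coef * r / nv) / prec
                        w_new = mean + rng.standard_normal(rows.size) / np.sqrt(prec)
                        old = st["X"][rows, t.analysis_col]
                        st["X"][rows, t.analysis_col] = w_new
                        eta[rows] += coef * (w_new - old)
                    else:
                        w_new = cmean[rows] + csd * rng.standard_normal(rows.size)
                    W[rows, d] = w_new
                # observed continuous cells: W stays fixed at the data values

        # 3. covariance of the targets
        self._update_sigma()

    def _update_sigma(self):
        m, st, rng = self.m, self.st, self.rng
        D = m.n_targets
        E = st["W"] - self.M
        n = m.n
        if D == 1:
            if self.cont_targets:
                ssr = float((E[:, 0] ** 2).sum())
                v = _sample_var_trunc_invgamma(
                    rng, (n - 1) / 2.0, ssr / 2.0, m.priors.sd_upper**2
                )
                st["Sigma_scale"][0] = np.sqrt(v)
                self._sigma_parts()
            return
        S = E.T @ E

        def logpost(scale, corr):
            Sig = corr * np.outer(scale, scale)
            try:
                L = cholesky(Sig, lower=True)
            except LinAlgError:
                return -np.inf
            logdet = 2.0 * np.log(np.diag(L)).sum()
            quad = np.trace(cho_solve((L, True), S))
            lp = -0.5 * n * logdet - 0.5 * quad
            # Jacobians of the log/atanh parameterization under uniform priors
            for d in self.cont_targets:
                if not (0.0 < scale[d] < m.priors.sd_upper):
                    return -np.inf
                lp += np.log(scale[d])
            iu = np.triu_indices(D, 1)
            lp += np.log1p(-corr[iu] ** 2).sum()
            return lp

        scale = st["Sigma_scale"].copy()
        corr = st["Sigma_corr"].copy()
        cur = logpost(scale, corr)
        step = self.mh_step
        for d in self.cont_targets:
            prop = scale.copy()
            prop[d] = scale[d] * np.exp(step * rng.standard_normal())
            new = logpost(prop, corr)
            if np.log(rng.random()) < new - cur:
                scale, cur = prop, new
        iu = list(zip(*np.triu_indices(D, 1)))
        for (i, j) in iu:
            prop = corr.copy()
            z = np.arctanh(corr[i, j]) + step * rng.standard_normal()
            prop[i, j] = prop[j, i] = np.tanh(z)
            new = logpost(scale, prop)
            if np.log(rng.random()) < new - cur:
                corr, cur = prop, new
        st["Sigma_scale"], st["Sigma_corr"] = scale, corr
        self._sigma_parts()

    # -- monitoring -------------------------------------------------------

    def monitor(self) -> dict[str, float]:
        m, st = self.m, self.st
        out = {}
        term = 0  # intercept
        if self.term_random[term]:
            out["alpha0"] = float(st["mu"][self.term_pos[term]])
        else:
            out["alpha0"] = float(st["bf"][self.term_pos[term]])
        for k, name in enumerate(m.cov_names):
            term = 1 + k
            if self.term_random[term]:
                out[f"beta_{name}"] = float(st["mu"][self.term_pos[term]])
            else:
                out[f"beta_{name}"] = float(st["bf"][self.term_pos[term]])
        if m.intercept_random:
            out["tau_alpha"] = float(st["tau"][self.term_pos[0]])
        for k, name in enumerate(m.cov_names):
            if m.cov_random[k]:
                out[f"tau_{name}"] = float(st["tau"][self.term_pos[1 + k]])
        if m.family == CONTINUOUS:
            out["sigma_y"] = float(st["sigma_y"])
        return out

    def check_latent_consistency(self):
        """Hard assertion: sign(w) must match every observed binary cell."""
        for d, t in enumerate(self.m.targets):
            if t.vtype != BINARY:
                continue
            w = self.st["W"][t.obs, d]
            x = self.m_target_obs_values(t)
            ok = np.all((w > 0) == (x > 0.5))
            if not ok:
                raise SamplerError(
                    f"latent/observed inconsistency for binary target {t.name!r}"
                )

    @staticmethod
    def m_target_obs_values(t):
        return t.x_obs[t.obs]

    def monitor_imputed(self) -> dict[str, float]:
        """Mean of the currently imputed values per target (missing cells only).

        For a binary target this is the imputed frequency of ones, the
        direct read-out of the probit mechanism.
        """
        out = {}
        for d, t in enumerate(self.m.targets):
            miss = ~t.obs
            if not miss.any():
                continue
            w = self.st["W"][miss, d]
            if t.vtype == BINARY:
                out[f"imp_mean_{t.name}"] = float((w > 0).mean())
            else:
                out[f"imp_mean_{t.name}"] = float(w.mean())
        return out


def run_mcmc(
    model: JointModel, settings: McmcSettings, monitor_imputed: bool = False
) -> ChainSet:
    """Draw from the joint posterior; seeded, chains run sequentially.

    Same seed and settings give bit-identical draws.  Missing cells are
    sampled within the chain (no imputed datasets are created); every
    retained draw satisfies the latent/observed sign constraint for binary
    targets, which is asserted during sampling.  With ``monitor_imputed``
    the per-draw mean of each target's imputed cells is recorded as an
    ``imp_mean_<target>`` parameter.
    """
    names = model.monitored
    if monitor_imputed:
        names = names + [
            f"imp_mean_{t.name}" for t in model.targets if not t.obs.all()
        ]
    kept = settings.retained
    draws = {p: np.empty((settings.n_chains, kept)) for p in names}
    iters = None
    for c in range(settings.n_chains):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(settings.seed) % (2**31), c])
        )
        state = default_initial_values(model, chain_index=c + 1, seed=settings.seed)
        sampler = _Sampler(model, state, rng)
        it_kept = []
        k = 0
        for it in range(settings.burn_in + settings.updates):
            sampler.step()
            post = it - settings.burn_in
            if post >= 0 and post % settings.thin == 0 and k < kept:
                sampler.check_latent_consistency()
                mon = sampler.monitor()
                if monitor_imputed:
                    mon.update(sampler.monitor_imputed())
                for p in names:
                    draws[p][c, k] = mon[p]
                it_kept.append(it + 1)
                k += 1
        if iters is None:
            iters = np.asarray(it_kept, dtype=int)
    for p in names:
        if p.startswith(("tau_", "sigma_")):
            if np.any(draws[p] <= 0):
                raise SamplerError(f"non-positive draws for SD parameter {p!r}")
    return ChainSet(draws=draws, iterations=iters, settings=settings, param_names=names)


def posterior_summary(chains: ChainSet, param: str):
    """Summarize one parameter over pooled post-burn-in draws across chains.

    Mean, median, SD (reported as the SE), equal-tail 95% credible interval
    (2.5th/97.5th percentiles, linear-interpolation quantiles), batch-means
    Monte-Carlo error and split-chain R-hat.
    """
    from .diagnostics import PosteriorSummary, gelman_rubin, mcmc_error

    arr2d = chains.draws[param]
    pooled = arr2d.reshape(-1)
    if pooled.size < 100:
        raise ValueError("need at least 100 pooled draws")
    lo, hi = np.quantile(pooled, [0.025, 0.975])
    rhat = gelman_rubin(arr2d)
    return PosteriorSummary(
        name=param,
        estimate=float(pooled.mean()),
        median=float(np.median(pooled)),
        se=float(pooled.std(ddof=1)),
        cri_low=float(lo),
        cri_high=float(hi),
        mcse=float(mcmc_error(pooled)),
        rhat=float(rhat.value),
        rhat_degenerate=bool(rhat.degenerate),
    )
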