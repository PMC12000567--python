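"""Hierarchical Bayesian two-source mixing model in 1-D ILR space.

Each omega-corrected consumer observation i (taxon s, lake l, covariate x) has
a linear predictor on the ILR coordinate of the source composition

    phi_i = (beta0 + b0_s + u_l) + (beta1 + b1_s) * x_l

with taxon random intercepts/slopes and lake random intercepts.  The inverse
ILR gives the aquatic proportion p_i, allochthony is 1 - p_i, and the
likelihood is Normal with a mixture mean and a multiplicative
process-x-residual error:

    m_i = (1 - p_i) T_l + p_i A_l
    V_i = xi * [ (1 - p_i)^2 sigma_T^2 + p_i^2 sigma_A^2 ] + sigma_extra^2

Fixed effects get wide Normal priors, variance-component SDs and xi get
uniform priors, and the two-source composition itself therefore carries a flat
prior.  Sampling uses an affine-invariant ensemble MCMC (emcee) run as
several independent ensembles ("chains") for Gelman-Rubin diagnostics.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy.special import expit

from .ilr import ilr_inverse, ilr_transform

logger = logging.getLogger(__name__)

_SQRT_TWO = np.sqrt(2.0)
_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class MixingModelConfig:
    """Sampler and prior settings.

    ``iterations`` counts ensemble steps (each advancing every walker), so
    totals are far smaller than single-walker iteration counts; the survey
    scale used 1e6 single-chain iterations with 5e5 burn-in and thinning 500,
    which corresponds here to ``paper_scale()``.

    covariate : name of the continuous covariate ('pc1', 'forest_pct',
        'nc_pom') or 'none' to drop the slope terms.
    chains : independent ensembles (>= 2 for R-hat).
    iterations, burn_in, thinning : ensemble steps.
    n_walkers : ensemble size (default: even max(2*ndim + 2, 64)).
    prior_sd_fixed : Normal prior SD for beta0/beta1 (ILR units).
    prior_bound_sigma, prior_bound_xi : upper bounds of the uniform priors.
    sigma_extra : additive observation SD in permil; None takes the
        per-observation ``d2h_corrected_sd`` column.
    fix_xi : fix the multiplicative error at this value instead of sampling.
    include_random_effects : drop all hierarchical terms when False
        (used by the reduced-model oracle).
    noncentered : sample weakly identified random effects (lake intercepts,
        taxon slopes) as standardized deviates internally; the posterior is
        unchanged but the variance-component funnels mix far better.
    rhat_max, geweke_z_max, geweke_frac : convergence thresholds.
    """

    covariate: str = "pc1"
    chains: int = 3
    iterations: int = 3000
    burn_in: int = 2100
    thinning: int = 10
    n_walkers: int | None = None
    prior_sd_fixed: float = 10.0
    prior_bound_sigma: float = 5.0
    prior_bound_xi: float = 20.0
    sigma_extra: float | None = None
    fix_xi: float | None = None
    include_random_effects: bool = True
    noncentered: bool = True
    seed: int = 0
    rhat_max: float = 1.05
    geweke_z_max: float = 2.0
    geweke_frac: float = 0.95

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.chains < 1:
            raise ValueError("chains must be >= 1")

    @property
    def include_covariate(self) -> bool:
        return self.covariate != "none"

    @classmethod
    def paper_scale(cls, **kw):
        """Survey-scale settings (long chains, heavy thinning)."""
        return cls(iterations=20_000, burn_in=10_000, thinning=100, chains=3, **kw)


def geweke_z(trace, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score comparing early vs late segment means.

    Segment-mean standard errors use autocorrelation-corrected effective
    sample sizes.
    """
    trace = np.asarray(trace, float)
    n = trace.size
    a = trace[: max(2, int(first * n))]
    b = trace[n - max(2, int(last * n)):]
    if np.var(trace) == 0:
        return 0.0
    # one autocorrelation time for the whole trace: segment windows are too
    # short for a stable spectral estimate of their own
    import logging as _logging

    try:
        _logging.disable(_logging.WARNING)
        tau = float(emcee.autocorr.integrated_time(trace, quiet=True)[0])
    except Exception:
        tau = 1.0
    finally:
        _logging.disable(_logging.NOTSET)
    tau = min(max(tau, 1.0), n / 4.0)
    denom = np.var(a, ddof=1) * tau / a.size + np.var(b, ddof=1) * tau / b.size
    if denom == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(denom))


class AllochthonyMixingModel:
    """Fit-style estimator for the hierarchical allochthony mixing model.

    ``fit`` expects a prepared-consumer frame joined to source pairs, with
    columns ``lake_id``, ``taxon``, ``d2h_corrected``, ``d2h_corrected_sd``,
    ``terrestrial_mean``, ``terrestrial_sd``, ``aquatic_mean``,
    ``aquatic_sd`` and (unless the covariate is 'none') ``covariate``.

    Fitted attributes (trailing underscore): ``param_names_``, ``chains_``
    (list of (draws, ndim) arrays), ``posterior_`` (name -> flat draws),
    ``diagnostics_``, ``converged_``, ``dic_``, ``p_d_``, ``r2_``,
    ``pointwise_loglik_``, ``xi_mean_``.
    """

    def __init__(self, config: MixingModelConfig | None = None):
        self.config = config

    # sklearn-compatible param plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------ setup
    def _cfg(self) -> MixingModelConfig:
        return self.config or MixingModelConfig()

    def _prepare(self, X: pd.DataFrame):
        cfg = self._cfg()
        req = ["lake_id", "taxon", "d2h_corrected", "terrestrial_mean", "terrestrial_sd",
               "aquatic_mean", "aquatic_sd"]
        for c in req:
            if c not in X.columns:
                raise KeyError(f"mixing-model data missing column {c!r}")
        self._y = X["d2h_corrected"].to_numpy(float)
        self._T = X["terrestrial_mean"].to_numpy(float)
        self._A = X["aquatic_mean"].to_numpy(float)
        self._sT = X["terrestrial_sd"].to_numpy(float)
        self._sA = X["aquatic_sd"].to_numpy(float)
        if cfg.sigma_extra is not None:
            self._s_extra = np.full(len(X), float(cfg.sigma_extra))
        elif "d2h_corrected_sd" in X.columns:
            self._s_extra = X["d2h_corrected_sd"].to_numpy(float)
        else:
            self._s_extra = np.zeros(len(X))
        if cfg.include_covariate:
            if "covariate" not in X.columns:
                raise KeyError("data missing 'covariate' column (or set covariate='none')")
            self._x = X["covariate"].to_numpy(float)
        else:
            self._x = np.zeros(len(X))
        for name, arr in (("observations", self._y), ("covariate", self._x),
                          ("terrestrial source", self._T), ("aquatic source", self._A)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite {name} value in mixing-model data")
        if np.any((self._sT <= 0) | (self._sA <= 0)):
            raise ValueError("source SDs must be > 0 at fit time")

        self._taxa, self._s_idx = np.unique(X["taxon"].to_numpy(), return_inverse=True)
        self._lakes, self._l_idx = np.unique(X["lake_id"].to_numpy(), return_inverse=True)
        S, L = len(self._taxa), len(self._lakes)
        if cfg.include_random_effects and (S < 2 or L < 2):
            raise ValueError("random effects need >= 2 taxa and >= 2 lakes; "
                             "set include_random_effects=False for the reduced model")

        names = ["beta0"]
        if cfg.include_covariate:
            names.append("beta1")
        if cfg.include_random_effects:
            names += [f"b0[{t}]" for t in self._taxa]
            if cfg.include_covariate:
                names += [f"b1[{t}]" for t in self._taxa]
            names += [f"u[{lk}]" for lk in self._lakes]
            names.append("sigma_sp0")
            if cfg.include_covariate:
                names.append("sigma_sp1")
            names.append("sigma_lake")
        if cfg.fix_xi is None:
            names.append("xi")
        self.param_names_ = names
        self._ndim = len(names)
        self._slices = self._layout(S, L, cfg)
        self.n_obs_ = len(X)
        self.data_hash_ = hashlib.sha256(
            np.ascontiguousarray(np.round(self._y, 9)).tobytes()
        ).hexdigest()
        # per-lake covariate value for summaries
        self._lake_x = np.zeros(L)
        for j in range(L):
            self._lake_x[j] = self._x[self._l_idx == j][0]
        return self

    def _layout(self, S, L, cfg):
        pos = 0
        sl = {}

        def take(name, n=1):
            nonlocal pos
            sl[name] = slice(pos, pos + n)
            pos += n

        take("beta0")
        if cfg.include_covariate:
            take("beta1")
        if cfg.include_random_effects:
            take("b0", S)
            if cfg.include_covariate:
                take("b1", S)
            take("u", L)
            take("sigma_sp0")
            if cfg.include_covariate:
                take("sigma_sp1")
            take("sigma_lake")
        if cfg.fix_xi is None:
            take("xi")
        return sl

    # ------------------------------------------------------------- posterior
    def _linear_predictor(self, theta):
        """phi for parameter matrix theta of shape (W, ndim) -> (W, n_obs)."""
        cfg = self._cfg()
        sl = self._slices
        beta0 = theta[:, sl["beta0"]]
        phi = np.broadcast_to(beta0, (theta.shape[0], self.n_obs_)).copy()
        slope = None
        if cfg.include_covariate:
            slope = np.broadcast_to(theta[:, sl["beta1"]], phi.shape).copy()
        if cfg.include_random_effects:
            phi += theta[:, sl["b0"]][:, self._s_idx]
            phi += theta[:, sl["u"]][:, self._l_idx]
            if cfg.include_covariate:
                slope += theta[:, sl["b1"]][:, self._s_idx]
        if slope is not None:
            phi += slope * self._x[None, :]
        return phi

    def log_posterior(self, theta, X: pd.DataFrame | None = None):
        """Vectorised log posterior density.

        ``theta`` is (ndim,) or (W, ndim); pass ``X`` to (re)bind data outside
        of :meth:`fit`.
        """
        if X is not None:
            self._prepare(X)
        cfg = self._cfg()
        theta = np.asarray(theta, float)
        scalar = theta.ndim == 1
        theta = np.atleast_2d(theta)
        W = theta.shape[0]
        sl = self._slices
        lp = np.zeros(W)

        # uniform bounds on variance components and xi
        if cfg.include_random_effects:
            sig_names = ["sigma_sp0", "sigma_lake"] + (["sigma_sp1"] if cfg.include_covariate else [])
            for s in sig_names:
                v = theta[:, sl[s]].ravel()
                lp[(v <= 0) | (v > cfg.prior_bound_sigma)] = -np.inf
        if cfg.fix_xi is None:
            xi = theta[:, sl["xi"]].ravel()
            lp[(xi <= 0) | (xi > cfg.prior_bound_xi)] = -np.inf
        else:
            xi = np.full(W, float(cfg.fix_xi))
        ok = np.isfinite(lp)
        if not ok.any():
            return float(lp[0]) if scalar else lp

        # fixed-effect priors
        for name in ("beta0", "beta1") if cfg.include_covariate else ("beta0",):
            b = theta[:, sl[name]].ravel()
            lp[ok] += -0.5 * (b[ok] / cfg.prior_sd_fixed) ** 2

        # hierarchical priors on random effects
        if cfg.include_random_effects:
            pairs = [("b0", "sigma_sp0"), ("u", "sigma_lake")]
            if cfg.include_covariate:
                pairs.append(("b1", "sigma_sp1"))
            for eff, sig in pairs:
                e = theta[:, sl[eff]]
                s = theta[:, sl[sig]]
                lp[ok] += np.sum(
                    -0.5 * (e[ok] / s[ok]) ** 2 - np.log(s[ok]), axis=1
                )

        phi = self._linear_predictor(theta[ok])
        p = expit(_SQRT_TWO * phi)
        m = (1.0 - p) * self._T[None, :] + p * self._A[None, :]
        V = xi[ok, None] * ((1.0 - p) ** 2 * self._sT[None, :] ** 2 + p**2 * self._sA[None, :] ** 2) \
            + self._s_extra[None, :] ** 2
        if np.any(V <= 0):
            bad = np.any(V <= 0, axis=1)
            V[bad] = 1.0
            loglik = -0.5 * np.sum(_LOG_2PI + np.log(V) + (self._y[None, :] - m) ** 2 / V, axis=1)
            loglik[bad] = -np.inf
        else:
            loglik = -0.5 * np.sum(_LOG_2PI + np.log(V) + (self._y[None, :] - m) ** 2 / V, axis=1)
        lp[ok] += loglik
        return float(lp[0]) if scalar else lp

    def pointwise_loglik(self, theta):
        """Per-observation log likelihood for draws theta (W, ndim) -> (W, n)."""
        cfg = self._cfg()
        theta = np.atleast_2d(np.asarray(theta, float))
        sl = self._slices
        xi = (theta[:, sl["xi"]].ravel() if cfg.fix_xi is None
              else np.full(theta.shape[0], float(cfg.fix_xi)))
        phi = self._linear_predictor(theta)
        p = expit(_SQRT_TWO * phi)
        m = (1.0 - p) * self._T[None, :] + p * self._A[None, :]
        V = xi[:, None] * ((1.0 - p) ** 2 * self._sT[None, :] ** 2 + p**2 * self._sA[None, :] ** 2) \
            + self._s_extra[None, :] ** 2
        return -0.5 * (_LOG_2PI + np.log(V) + (self._y[None, :] - m) ** 2 / V)

    # -------------------------------------------- sampling parameterization
    def _to_natural(self, theta_s):
        """Sampling coords -> natural coords (u and b1 stored standardized)."""
        cfg = self._cfg()
        theta = np.atleast_2d(np.asarray(theta_s, float)).copy()
        if cfg.noncentered and cfg.include_random_effects:
            sl = self._slices
            s_lake = theta[:, sl["sigma_lake"]]
            theta[:, sl["u"]] = theta[:, sl["u"]] * s_lake
            if cfg.include_covariate:
                s1 = theta[:, sl["sigma_sp1"]]
                theta[:, sl["b1"]] = theta[:, sl["b1"]] * s1
        return theta

    def _log_prob_sampling(self, theta_s):
        """Posterior density in the internal sampling parameterization."""
        cfg = self._cfg()
        theta_s = np.atleast_2d(np.asarray(theta_s, float))
        if not (cfg.noncentered and cfg.include_random_effects):
            return self.log_posterior(theta_s)
        sl = self._slices
        lp = self.log_posterior(self._to_natural(theta_s))
        # Jacobian/prior adjustment: standardized effects carry N(0,1)
        # priors, cancelling the -log(sigma) terms of the centered form
        ok = np.isfinite(lp)
        L = sl["u"].stop - sl["u"].start
        lp[ok] += L * np.log(theta_s[ok][:, sl["sigma_lake"]].ravel())
        if cfg.include_covariate:
            S = sl["b1"].stop - sl["b1"].start
            lp[ok] += S * np.log(theta_s[ok][:, sl["sigma_sp1"]].ravel())
        return lp

    # ------------------------------------------------------------------- fit
    def _initial_point(self):
        """Cheap empirical start: invert the mixing equation per observation,
        least-squares the ILR coordinates on the design."""
        cfg = self._cfg()
        denom = self._A - self._T
        denom = np.where(np.abs(denom) < 1e-9, 1e-9, denom)
        p_emp = np.clip((self._y - self._T) / denom, 0.02, 0.98)
        phi_emp = ilr_transform(p_emp)
        X_design = [np.ones(self.n_obs_)]
        if cfg.include_covariate:
            X_design.append(self._x)
        coef, *_ = np.linalg.lstsq(np.column_stack(X_design), phi_emp, rcond=None)

        center = np.zeros(self._ndim)
        sl = self._slices
        center[sl["beta0"]] = coef[0]
        if cfg.include_covariate:
            center[sl["beta1"]] = coef[1]
        if cfg.include_random_effects:
            resid = phi_emp - np.column_stack(X_design) @ coef
            b0 = np.array([resid[self._s_idx == s].mean() for s in range(len(self._taxa))])
            center[sl["b0"]] = np.clip(b0, -3, 3)
            u = np.array([resid[self._l_idx == j].mean() for j in range(len(self._lakes))])
            center[sl["u"]] = np.clip(u * 0.3, -1, 1)
            center[sl["sigma_sp0"]] = max(0.3, float(np.std(b0)))
            center[sl["sigma_lake"]] = 0.3
            if cfg.include_covariate:
                center[sl["sigma_sp1"]] = 0.2
        if cfg.fix_xi is None:
            center[sl["xi"]] = 0.8
        return center

    def fit(self, X: pd.DataFrame, y=None):
        cfg = self._cfg()
        self._prepare(X)
        ndim = self._ndim
        nw = cfg.n_walkers or max(2 * ndim + 2, 64)
        nw += nw % 2
        center = self._initial_point()
        sl = self._slices

        noncentered = cfg.noncentered and cfg.include_random_effects
        if noncentered:
            # express the start point in sampling coordinates
            for name, sig in (("u", "sigma_lake"), ("b1", "sigma_sp1")):
                if name in sl and sig in sl:
                    center[sl[name]] = center[sl[name]] / max(float(center[sl[sig]][0]), 1e-3)

        kept_chains, gw_z, ess_chains = [], [], []
        moves = emcee.moves.DEMove()
        root = np.random.SeedSequence([int(cfg.seed), 0x5EED])
        for c, ss in enumerate(root.spawn(cfg.chains)):
            rng = np.random.default_rng(ss)
            p0 = center[None, :] + 0.05 * rng.standard_normal((nw, ndim))
            # keep sigmas/xi strictly positive at start
            for s in ("sigma_sp0", "sigma_sp1", "sigma_lake", "xi"):
                if s in sl:
                    p0[:, sl[s]] = np.abs(p0[:, sl[s]]) + 0.05
            sampler = emcee.EnsembleSampler(nw, ndim, self._log_prob_sampling, vectorize=True, moves=moves)
            sampler._random = np.random.RandomState(int(ss.generate_state(1, np.uint32)[0] % (2**31 - 1)))
            sampler.run_mcmc(p0, cfg.iterations, progress=False)
            post = sampler.get_chain(discard=cfg.burn_in)  # (steps, nw, ndim)
            if noncentered:
                post = self._to_natural(post.reshape(-1, ndim)).reshape(post.shape)
            z_c, ess_c = self._geweke_ensemble(post)
            gw_z.append(z_c)
            ess_chains.append(ess_c)
            thin = post[:: cfg.thinning]
            kept_chains.append(thin.reshape(-1, ndim))
            self.acceptance_fraction_ = float(np.mean(sampler.acceptance_fraction))

        self.chains_ = kept_chains
        draws = np.concatenate(kept_chains, axis=0)
        self.draws_ = draws
        self.posterior_ = {n: draws[:, i] for i, n in enumerate(self.param_names_)}
        self.xi_mean_ = (float(np.mean(self.posterior_["xi"])) if "xi" in self.posterior_
                         else float(cfg.fix_xi))

        self.ess_ = np.sum(ess_chains, axis=0)  # per-parameter, summed over chains
        self._diagnose(kept_chains, gw_z)
        self._model_fit_stats()
        return self

    # ----------------------------------------------------------- diagnostics
    def _geweke_ensemble(self, post, first: float = 0.1, last: float = 0.5,
                         max_walkers: int = 16):
        """Geweke z per parameter for one ensemble run.

        Segment means are taken over all walkers in the early (first 10%)
        and late (last 50%) step windows; their standard errors use an
        autocorrelation-corrected effective sample size estimated by treating
        a subset of walkers as parallel chains.
        """
        steps, nw, ndim = post.shape
        na = max(2, int(first * steps))
        nb = max(2, int(last * steps))
        z = np.zeros(ndim)
        ess_out = np.zeros(ndim)
        sub = post[:, : min(max_walkers, nw), :]
        for i in range(ndim):
            block = sub[:, :, i].T  # (chains=walkers, draws=steps)
            if np.var(block) == 0:
                ess_out[i] = 1.0
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ess = float(az.ess(block)) * (nw / block.shape[0])
            ess_out[i] = ess
            a = post[:na, :, i]
            b = post[-nb:, :, i]
            se2 = (a.var() / max(ess * na / steps, 2.0)
                   + b.var() / max(ess * nb / steps, 2.0))
            if se2 > 0:
                z[i] = (a.mean() - b.mean()) / np.sqrt(se2)
        return z, ess_out

    def _diagnose(self, kept_chains, gw_z=None):
        cfg = self._cfg()
        rows = []
        n_min = min(c.shape[0] for c in kept_chains)
        stacked = np.stack([c[:n_min] for c in kept_chains])  # (chain, draw, dim)
        for i, name in enumerate(self.param_names_):
            if len(kept_chains) < 2:
                rhat = np.nan
            elif np.var(stacked[:, :, i]) == 0:
                rhat = 1.0  # identical constant chains are perfectly converged
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rhat = float(az.rhat(stacked[:, :, i]))
            if gw_z is not None:
                z = max(abs(zc[i]) for zc in gw_z)
            else:
                z = max(abs(geweke_z(c[:, i])) for c in kept_chains)
            rows.append((name, rhat, z))
        self.diagnostics_ = pd.DataFrame(rows, columns=["parameter", "rhat", "geweke_z"])
        rhat_ok = (self.diagnostics_["rhat"].isna() | (self.diagnostics_["rhat"] <= cfg.rhat_max))
        gew_ok = (self.diagnostics_["geweke_z"].abs() <= cfg.geweke_z_max)
        self.rhat_max_ = float(np.nanmax(self.diagnostics_["rhat"])) if len(kept_chains) >= 2 else np.nan
        self.converged_ = bool(rhat_ok.all() and gew_ok.mean() >= cfg.geweke_frac)
        if not self.converged_:
            warnings.warn(
                f"MCMC convergence not confirmed (max R-hat {self.rhat_max_:.3f}, "
                f"{(~gew_ok).sum()} parameter(s) with |Geweke z| > {cfg.geweke_z_max})",
                stacklevel=2,
            )

    def diagnose(self) -> pd.DataFrame:
        """Per-parameter R-hat and Geweke z with pass/fail flags."""
        cfg = self._cfg()
        d = self.diagnostics_.copy()
        d["rhat_ok"] = d["rhat"].isna() | (d["rhat"] <= cfg.rhat_max)
        d["geweke_ok"] = d["geweke_z"].abs() <= cfg.geweke_z_max
        return d

    def _model_fit_stats(self, max_draws: int = 1000):
        draws = self.draws_
        idx = np.linspace(0, len(draws) - 1, min(max_draws, len(draws))).astype(int)
        ll = self.pointwise_loglik(draws[idx])
        self.pointwise_loglik_ = ll
        dev = -2.0 * ll.sum(axis=1)
        d_bar = float(dev.mean())
        d_hat = float(-2.0 * self.pointwise_loglik(draws.mean(axis=0)[None, :]).sum())
        self.p_d_ = d_bar - d_hat
        self.dic_ = d_bar + self.p_d_
        # approximate R^2: squared correlation of observations with posterior-mean fit
        phi = self._linear_predictor(draws[idx])
        p = expit(_SQRT_TWO * phi)
        m = ((1.0 - p) * self._T[None, :] + p * self._A[None, :]).mean(axis=0)
        self.fitted_mean_ = m
        self.r2_ = float(np.corrcoef(self._y, m)[0, 1] ** 2) if np.std(m) > 0 else 0.0

    # -------------------------------------------------------------- summaries
    @staticmethod
    def _ci(draws, axis=0):
        med = np.median(draws, axis=axis)
        lo, hi = np.percentile(draws, [2.5, 97.5], axis=axis)
        return med, lo, hi

    def summarize_allochthony(self, covariate_grid=None, global_mode: str = "sample",
                              n_global: int = 4000, seed: int = 0) -> dict:
        """Posterior summaries of allochthony.

        Returns a dict with ``taxon_intercepts`` (allochthony at covariate 0
        and the taxon ILR slope with a CI-excludes-zero flag), ``curves``
        (per-taxon median/CI along the covariate grid), ``global_curve``
        (average-consumer curve with random effects integrated by sampling
        fresh effects from their hierarchical SDs, or set to zero with
        ``global_mode='zero'``) and ``lake_taxon`` point estimates.
        """
        cfg = self._cfg()
        sl = self._slices
        draws = self.draws_
        if covariate_grid is None:
            covariate_grid = np.linspace(self._x.min(), self._x.max(), 21) \
                if cfg.include_covariate else np.array([0.0])
        grid = np.asarray(covariate_grid, float)
        if grid.size == 0:
            raise ValueError("covariate grid is empty")

        beta0 = draws[:, sl["beta0"]].ravel()
        beta1 = draws[:, sl["beta1"]].ravel() if cfg.include_covariate else np.zeros_like(beta0)
        if cfg.include_random_effects:
            b0 = draws[:, sl["b0"]]
            b1 = draws[:, sl["b1"]] if cfg.include_covariate else np.zeros_like(b0)
            u = draws[:, sl["u"]]
        else:
            b0 = np.zeros((len(draws), 1))
            b1 = np.zeros((len(draws), 1))
            u = np.zeros((len(draws), 1))
        taxa = self._taxa if cfg.include_random_effects else np.array(["all"])

        rows = []
        for s, taxon in enumerate(taxa):
            alo = 1.0 - ilr_inverse(beta0 + b0[:, s])
            med, lo, hi = self._ci(alo)
            slope = beta1 + b1[:, s]
            smed, s_lo, s_hi = self._ci(slope)
            rows.append((taxon, med, lo, hi, smed, s_lo, s_hi, bool(s_lo > 0 or s_hi < 0)))
        taxon_intercepts = pd.DataFrame(
            rows, columns=["taxon", "allochthony_median", "allochthony_lo95", "allochthony_hi95",
                           "ilr_slope_median", "ilr_slope_lo95", "ilr_slope_hi95", "slope_nonzero"],
        )

        curve_rows = []
        for s, taxon in enumerate(taxa):
            phi = (beta0[:, None] + b0[:, s, None]) + (beta1[:, None] + b1[:, s, None]) * grid[None, :]
            alo = 1.0 - ilr_inverse(phi)
            med, lo, hi = self._ci(alo, axis=0)
            for g, x in enumerate(grid):
                curve_rows.append((taxon, x, med[g], lo[g], hi[g]))
        curves = pd.DataFrame(curve_rows, columns=["taxon", "covariate", "median", "lo95", "hi95"])

        # global average consumer
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(draws), min(n_global, len(draws) * 4))
        g_b0 = beta0[idx].copy()
        g_b1 = beta1[idx].copy()
        if cfg.include_random_effects and global_mode == "sample":
            s0 = draws[:, sl["sigma_sp0"]].ravel()[idx]
            slk = draws[:, sl["sigma_lake"]].ravel()[idx]
            g_b0 += rng.normal(0, s0) + rng.normal(0, slk)
            if cfg.include_covariate:
                s1 = draws[:, sl["sigma_sp1"]].ravel()[idx]
                g_b1 += rng.normal(0, s1)
        phi = g_b0[:, None] + g_b1[:, None] * grid[None, :]
        med, lo, hi = self._ci(1.0 - ilr_inverse(phi), axis=0)
        global_curve = pd.DataFrame(
            {"covariate": grid, "median": med, "lo95": lo, "hi95": hi}
        )

        lake_rows = []
        if cfg.include_random_effects:
            for j, lake in enumerate(self._lakes):
                for s, taxon in enumerate(taxa):
                    phi = beta0 + b0[:, s] + u[:, j] + (beta1 + b1[:, s]) * self._lake_x[j]
                    med, lo, hi = self._ci(1.0 - ilr_inverse(phi))
                    lake_rows.append((lake, taxon, self._lake_x[j], med, lo, hi))
        lake_taxon = pd.DataFrame(
            lake_rows, columns=["lake_id", "taxon", "covariate", "median", "lo95", "hi95"]
        )

        return {
            "taxon_intercepts": taxon_intercepts,
            "curves": curves,
            "global_curve": global_curve,
            "lake_taxon": lake_taxon,
        }


def compare_models(fits: list, labels: list | None = None) -> pd.DataFrame:
    """DIC / Akaike-weight / approximate-R^2 comparison of fits on one dataset.

    DIC = mean deviance + p_D with p_D = mean deviance - deviance at the
    posterior mean; Akaike weights are exp(-dDIC/2) normalised.  Pointwise
    log-likelihood matrices are exposed on each fit for external LOO tools.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 fitted models to compare")
    h = {f.data_hash_ for f in fits}
    if len(h) != 1:
        raise ValueError("models were fitted on different data; comparison undefined")
    labels = labels or [f"model_{i}" for i in range(len(fits))]
    dic = np.array([f.dic_ for f in fits])
    delta = dic - dic.min()
    w = np.exp(-0.5 * delta)
    w = w / w.sum()
    return pd.DataFrame(
        {
            "model": labels,
            "dic": dic,
            "p_d": [f.p_d_ for f in fits],
            "delta_dic": delta,
            "akaike_weight": w,
            "approx_r2": [f.r2_ for f in fits],
            "converged": [f.converged_ for f in fits],
        }
    )
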