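"""Gibbs sampler for additive Bayesian quantile regression.

The conditional tau-quantile of birth weight is modelled as

    q(tau | x_i) = w_i' gamma + f_age(age_i) + f_vis(visits_i) + f_spat(d_i)

with dummy-coded fixed effects ``gamma`` under a diffuse Gaussian prior
(precision 1e-6), RW2 smooths for the metrical covariates, and an ICAR
district effect — each intrinsic block carrying a Gamma(shape, rate)
hyperprior on its precision delta and a sum-to-zero constraint.

Inference uses the asymmetric-Laplace working likelihood in its
normal-exponential mixture form.  One Gibbs cycle:

1. latent mixing variables ``v_i`` from their generalized inverse
   Gaussian full conditional (drawn as inverse-Gaussian on 1/v);
2. each Gaussian block (fixed effects, each smooth, spatial) from its
   multivariate normal full conditional — prior precision delta*Q plus
   the mixture-weighted design cross product — with the sum-to-zero
   constraint enforced exactly by conditioning by kriging;
3. each block precision delta from its Gamma full conditional with
   shape increment (n - m)/2, m the rank deficiency of Q.

The ALD scale sigma is a nuisance of the working likelihood; by
default it is sampled alongside the blocks (a Gamma prior on 1/sigma
gives a conjugate update) so the pseudo-likelihood sharpness matches
the data's residual spread.  Identical seeds give bit-identical chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from . import ald
from .data_model import (AdjacencyGraph, Dataset, DesignMatrices, ModelSpec,
                         build_design)
from .gmrf import GMRFPrior, icar_precision, rw1_precision, rw2_precision

__all__ = [
    "MCMCSettings",
    "DICResult",
    "PosteriorFit",
    "fit_model",
    "posterior_summary",
    "compute_dic",
    "spatial_effect_table",
]


@dataclass(frozen=True)
class MCMCSettings:
    """Chain length controls.  The seed is mandatory: every run is replayable."""

    seed: int
    iters: int = 12000
    burnin: int = 2000
    thin: int = 5

    def __post_init__(self) -> None:
        if self.iters <= self.burnin:
            raise ValueError("iters must exceed burnin")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.iters - self.burnin + self.thin - 1) // self.thin


@dataclass(frozen=True)
class DICResult:
    """Deviance information criterion pieces: DIC = Dbar + pD."""

    dbar: float
    pd: float
    dic: float


@dataclass
class PosteriorFit:
    """Retained MCMC draws of all blocks, plus everything needed to
    summarize, predict and score the fit."""

    fixed: np.ndarray                    # (S, p)
    fixed_names: list[str]
    smooths: dict[str, np.ndarray]       # name -> (S, G)
    smooth_grids: dict[str, np.ndarray]
    spatial: np.ndarray | None           # (S, K)
    spatial_labels: list[str] | None
    deltas: dict[str, np.ndarray]        # block name -> (S,)
    sigma: np.ndarray                    # (S,)
    spec: ModelSpec
    settings: MCMCSettings
    design: DesignMatrices = field(repr=False)
    y: np.ndarray = field(repr=False)
    dic: DICResult | None = None

    @property
    def n_draws(self) -> int:
        return self.fixed.shape[0]

    def linear_predictor(self, draws: slice | np.ndarray = slice(None)) -> np.ndarray:
        """Matrix of mu_i per retained draw, shape (S_sel, n)."""
        mu = self.fixed[draws] @ self.design.W.T
        for name, fdraws in self.smooths.items():
            idx = self.design.smooth_index[name]
            obs = idx >= 0
            mu[:, obs] += fdraws[draws][:, idx[obs]]
        if self.spatial is not None:
            mu += self.spatial[draws][:, self.design.spatial_index]
        return mu

    def posterior_mean_predictor(self) -> np.ndarray:
        """mu_i at the posterior mean of every block (for DIC's D(theta-bar))."""
        mu = self.design.W @ self.fixed.mean(axis=0)
        for name, fdraws in self.smooths.items():
            idx = self.design.smooth_index[name]
            obs = idx >= 0
            mu[obs] += fdraws.mean(axis=0)[idx[obs]]
        if self.spatial is not None:
            mu += self.spatial.mean(axis=0)[self.design.spatial_index]
        return mu


# ---------------------------------------------------------------------------
# sampler internals
# ---------------------------------------------------------------------------

def _chol(P: np.ndarray):
    try:
        return cho_factor(P, lower=True)
    except np.linalg.LinAlgError:
        return cho_factor(P + 1e-10 * np.trace(P) / len(P) * np.eye(len(P)),
                          lower=True)


def _draw_gaussian_block(P: np.ndarray, b: np.ndarray,
                         rng: np.random.Generator,
                         sum_to_zero: bool) -> np.ndarray:
    """Draw x ~ N(P^{-1} b, P^{-1}), optionally conditioned on 1'x = 0.

    The constraint is exact conditioning by kriging:
    x* = x - P^{-1} 1 (1'x) / (1' P^{-1} 1).
    """
    c, low = _chol(P)
    mean = cho_solve((c, low), b)
    z = rng.standard_normal(len(b))
    x = mean + solve_triangular(c, z, lower=low, trans="T")
    if sum_to_zero:
        Pinv1 = cho_solve((c, low), np.ones(len(b)))
        x = x - Pinv1 * (x.sum() / Pinv1.sum())
    return x


def fit_model(data: Dataset, graph: AdjacencyGraph | None, spec: ModelSpec,
              settings: MCMCSettings, *, sigma: float = 1.0,
              sample_sigma: bool = True,
              sigma_hyperprior: tuple[float, float] = (1.0, 1.0)) -> PosteriorFit:
    """Run the Gibbs sampler and return retained draws.

    ``graph`` may be None only when the spec has no spatial term.  The
    ALD scale is sampled by default (Gamma(shape, rate) prior on
    1/sigma), letting the working likelihood adapt to the response
    scale — on kilogram-scale data a fixed sigma = 1 visibly
    miscalibrates the extreme-quantile surface.  Pass
    ``sample_sigma=False`` to hold it at ``sigma``.
    """
    if spec.spatial_term is not None and graph is None:
        raise ValueError("spec has a spatial term but no graph was given")
    if graph is not None and spec.spatial_term is not None:
        data.validate_against(graph)
    design = build_design(data, spec, graph)
    y = data.y
    n = len(y)
    tau = spec.tau
    theta, kappa_sq = ald.mixture_constants(tau)
    rng = np.random.default_rng(settings.seed)

    W = design.W
    p = W.shape[1]
    fixed_prior = np.full(p, spec.fixed_prior_precision)

    smooth_priors: dict[str, GMRFPrior] = {}
    for term in spec.smooth_terms:
        grid = design.smooth_grids[term.name]
        builder = rw2_precision if term.order == 2 else rw1_precision
        smooth_priors[term.name] = builder(len(grid),
                                           hyperprior=spec.hyperprior(term.name))
    spatial_prior = None
    if spec.spatial_term is not None:
        spatial_prior = icar_precision(
            graph, hyperprior=spec.hyperprior(spec.spatial_term))

    # state
    gamma = np.zeros(p)
    gamma[0] = float(np.quantile(y, tau))
    f_smooth = {name: np.zeros(pr.n) for name, pr in smooth_priors.items()}
    f_spat = np.zeros(spatial_prior.n) if spatial_prior is not None else None
    delta = {name: 100.0 for name in smooth_priors}
    if spatial_prior is not None:
        delta[spec.spatial_term] = 100.0
    sig = float(sigma)

    contrib_fixed = W @ gamma
    contrib_smooth = {}
    for name in smooth_priors:
        idx = design.smooth_index[name]
        contrib_smooth[name] = np.where(idx >= 0, f_smooth[name][np.maximum(idx, 0)], 0.0)
    contrib_spat = (f_spat[design.spatial_index]
                    if spatial_prior is not None else np.zeros(n))

    S = settings.n_draws
    draws_fixed = np.empty((S, p))
    draws_smooth = {name: np.empty((S, pr.n)) for name, pr in smooth_priors.items()}
    draws_spat = np.empty((S, spatial_prior.n)) if spatial_prior is not None else None
    draws_delta = {name: np.empty(S) for name in delta}
    draws_sigma = np.empty(S)

    psi_base = 1.0 / (2.0 * tau * (1.0 - tau))
    s = 0
    for it in range(settings.iters):
        mu = contrib_fixed + sum(contrib_smooth.values()) + contrib_spat

        # (1) latent mixing variables: 1/v ~ inverse Gaussian
        resid = y - mu
        chi = np.maximum(resid * resid / (kappa_sq * sig), 1e-12)
        psi = psi_base / sig
        w = rng.wald(np.sqrt(psi / chi), psi)          # w = 1/v
        w = np.maximum(w, 1e-12)
        v = 1.0 / w
        omega = w / (kappa_sq * sig)                   # obs precision weights
        ytil = y - theta * v

        # (2a) fixed-effect block
        r = ytil - sum(contrib_smooth.values()) - contrib_spat
        Wo = W * omega[:, None]
        P = W.T @ Wo + np.diag(fixed_prior)
        b = Wo.T @ r
        if not np.all(np.isfinite(P)):
            raise FloatingPointError(
                f"non-finite full-conditional precision in block 'fixed' "
                f"at iteration {it}")
        gamma = _draw_gaussian_block(P, b, rng, sum_to_zero=False)
        contrib_fixed = W @ gamma

        # (2b) smooth blocks
        for name, prior in smooth_priors.items():
            idx = design.smooth_index[name]
            obs = idx >= 0
            others = sum(c for nm, c in contrib_smooth.items() if nm != name)
            if isinstance(others, int):
                others = 0.0
            r = ytil - contrib_fixed - others - contrib_spat
            G = prior.n
            d = np.bincount(idx[obs], weights=omega[obs], minlength=G)
            b = np.bincount(idx[obs], weights=(omega * r)[obs], minlength=G)
            P = delta[name] * prior.Q + np.diag(d)
            if not np.all(np.isfinite(P)):
                raise FloatingPointError(
                    f"non-finite full-conditional precision in block "
                    f"{name!r} at iteration {it}")
            f = _draw_gaussian_block(P, b, rng, sum_to_zero=True)
            f_smooth[name] = f
            contrib_smooth[name] = np.where(obs, f[np.maximum(idx, 0)], 0.0)

        # (2c) spatial block
        if spatial_prior is not None:
            r = ytil - contrib_fixed - sum(contrib_smooth.values())
            idx = design.spatial_index
            K = spatial_prior.n
            d = np.bincount(idx, weights=omega, minlength=K)
            b = np.bincount(idx, weights=omega * r, minlength=K)
            P = delta[spec.spatial_term] * spatial_prior.Q + np.diag(d)
            if not np.all(np.isfinite(P)):
                raise FloatingPointError(
                    f"non-finite full-conditional precision in block "
                    f"'spatial' at iteration {it}")
            f_spat = _draw_gaussian_block(P, b, rng, sum_to_zero=True)
            contrib_spat = f_spat[idx]

        # (3) block precisions
        for name, prior in smooth_priors.items():
            a0, b0 = prior.delta_hyperprior
            f = f_smooth[name]
            rate = b0 + 0.5 * float(f @ prior.Q @ f)
            delta[name] = rng.gamma(a0 + 0.5 * prior.rank, 1.0 / rate)
        if spatial_prior is not None:
            a0, b0 = spatial_prior.delta_hyperprior
            rate = b0 + 0.5 * float(f_spat @ spatial_prior.Q @ f_spat)
            delta[spec.spatial_term] = rng.gamma(
                a0 + 0.5 * spatial_prior.rank, 1.0 / rate)

        # (4) optional ALD scale
        if sample_sigma:
            a0, b0 = sigma_hyperprior
            mu = contrib_fixed + sum(contrib_smooth.values()) + contrib_spat
            rr = y - mu - theta * v
            c1 = float(np.sum(rr * rr / (2.0 * kappa_sq * v)) + v.sum())
            phi = rng.gamma(a0 + 1.5 * n, 1.0 / (b0 + c1))
            sig = 1.0 / phi

        if it >= settings.burnin and (it - settings.burnin) % settings.thin == 0:
            draws_fixed[s] = gamma
            for name in smooth_priors:
                draws_smooth[name][s] = f_smooth[name]
            if spatial_prior is not None:
                draws_spat[s] = f_spat
            for name in delta:
                draws_delta[name][s] = delta[name]
            draws_sigma[s] = sig
            s += 1

    fit = PosteriorFit(
        fixed=draws_fixed[:s], fixed_names=design.colnames,
        smooths={k: a[:s] for k, a in draws_smooth.items()},
        smooth_grids=design.smooth_grids,
        spatial=draws_spat[:s] if draws_spat is not None else None,
        spatial_labels=design.spatial_labels,
        deltas={k: a[:s] for k, a in draws_delta.items()},
        sigma=draws_sigma[:s], spec=spec, settings=settings,
        design=design, y=y)
    fit.dic = compute_dic(fit)
    return fit


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _summarize(draws: np.ndarray, names: list[str], block: str) -> pd.DataFrame:
    mean = draws.mean(axis=0)
    sd = draws.std(axis=0, ddof=1) if draws.shape[0] > 1 else np.zeros(draws.shape[1])
    lo = np.quantile(draws, 0.025, axis=0)
    hi = np.quantile(draws, 0.975, axis=0)
    sig = (lo > 0) | (hi < 0)
    return pd.DataFrame({
        "block": block, "name": names, "mean": mean, "sd": sd,
        "ci_lower": lo, "ci_upper": hi, "significant": sig,
    })


def posterior_summary(fit: PosteriorFit) -> pd.DataFrame:
    """Coefficient table: mean, sd, equal-tailed 95% CI and a
    significance flag (CI excludes 0) per coefficient of every block."""
    if fit.n_draws == 0:
        raise ValueError("fit has no retained draws")
    parts = [_summarize(fit.fixed, fit.fixed_names, "fixed")]
    for name, draws in fit.smooths.items():
        labels = [f"{name}={g:g}" for g in fit.smooth_grids[name]]
        parts.append(_summarize(draws, labels, f"smooth:{name}"))
    if fit.spatial is not None:
        parts.append(_summarize(fit.spatial, fit.spatial_labels, "spatial"))
    for name, draws in fit.deltas.items():
        parts.append(_summarize(1.0 / draws[:, None], [f"variance(1/delta):{name}"],
                                "hyper"))
    return pd.concat(parts, ignore_index=True)


def compute_dic(fit: PosteriorFit, data: Dataset | None = None,
                spec: ModelSpec | None = None, *,
                chunk: int = 256) -> DICResult:
    """DIC under the ALD working likelihood.

    Dbar is the posterior mean of the deviance -2 sum_i log ALD(y_i;
    mu_i, sigma, tau); D(theta-bar) evaluates at posterior-mean
    parameters; pD = Dbar - D(theta-bar); DIC = Dbar + pD.  ``data`` and
    ``spec`` allow recomputation against a dataset; by default the
    fit's cached design is used.
    """
    if data is not None:
        spec = spec if spec is not None else fit.spec
        design = build_design(data, spec)
        if design.spatial_index is not None:
            # align record->node positions with the fit's node order
            lut = {lab: i for i, lab in enumerate(fit.spatial_labels)}
            design.spatial_index = np.array(
                [lut[design.spatial_labels[k]] for k in design.spatial_index])
            design.spatial_labels = list(fit.spatial_labels)
        y = data.y
        work = PosteriorFit(fixed=fit.fixed, fixed_names=fit.fixed_names,
                            smooths=fit.smooths, smooth_grids=fit.smooth_grids,
                            spatial=fit.spatial, spatial_labels=fit.spatial_labels,
                            deltas=fit.deltas, sigma=fit.sigma, spec=spec,
                            settings=fit.settings, design=design, y=y)
    else:
        work, y = fit, fit.y
    tau = work.spec.tau
    S = work.n_draws
    dev = np.empty(S)
    for start in range(0, S, chunk):
        sel = np.arange(start, min(start + chunk, S))
        mu = work.linear_predictor(sel)
        for j, sidx in enumerate(sel):
            dev[sidx] = -2.0 * float(
                np.sum(ald.ald_logpdf(y, mu[j], float(work.sigma[sidx]), tau)))
    dbar = float(dev.mean())
    mu_bar = work.posterior_mean_predictor()
    d_hat = -2.0 * float(np.sum(ald.ald_logpdf(y, mu_bar,
                                               float(work.sigma.mean()), tau)))
    p_d = dbar - d_hat
    return DICResult(dbar=dbar, pd=p_d, dic=dbar + p_d)


def spatial_effect_table(fit: PosteriorFit) -> pd.DataFrame:
    """Per-district posterior mean, 95% CI and a three-way class
    (negative / insignificant / positive) by the CI's sign — the
    tabular equivalent of a credible-interval map."""
    if fit.spatial is None:
        raise ValueError("fit has no spatial term")
    lo = np.quantile(fit.spatial, 0.025, axis=0)
    hi = np.quantile(fit.spatial, 0.975, axis=0)
    mean = fit.spatial.mean(axis=0)
    category = np.where(hi < 0, "negative",
                        np.where(lo > 0, "positive", "insignificant"))
    return pd.DataFrame({
        "district": fit.spatial_labels, "mean": mean,
        "ci_lower": lo, "ci_upper": hi, "category": category,
    })
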