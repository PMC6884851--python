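"""Check loss and the asymmetric Laplace working likelihood.

Quantile regression at level tau minimizes the check (pinball) loss
``rho_tau(u) = u * (tau - 1{u < 0})``.  Exponentiating the negative
loss gives the asymmetric Laplace distribution (ALD), the standard
working likelihood for Bayesian quantile regression: ALD(mu, sigma,
tau) places probability exactly tau below its location mu, so the
posterior over mu is a posterior over the conditional tau-quantile.

The ALD admits a normal-exponential scale mixture,

    y = mu + theta * v + kappa * sqrt(sigma * v) * z,
    v ~ Exp(rate 1/sigma),   z ~ N(0, 1),

with ``theta = (1 - 2 tau) / (tau (1 - tau))`` and ``kappa^2 =
2 / (tau (1 - tau))``; conditioning on v makes every regression block
Gaussian, which powers the Gibbs sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QuantileLoss",
    "ALDParams",
    "check_loss",
    "ald_logpdf",
    "ald_cdf",
    "ald_ppf",
    "ald_rvs",
    "mixture_constants",
]


def _check_tau(tau: float) -> None:
    if not 0.0 < tau < 1.0:
        raise ValueError(f"tau must lie in (0, 1), got {tau}")


@dataclass(frozen=True)
class QuantileLoss:
    """The check loss at a fixed quantile level."""

    tau: float

    def __post_init__(self) -> None:
        _check_tau(self.tau)

    def __call__(self, u):
        return check_loss(u, self.tau)


@dataclass(frozen=True)
class ALDParams:
    """Location (the conditional quantile), scale and quantile level."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        _check_tau(self.tau)
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


def check_loss(u, tau: float):
    """rho_tau(u) = u (tau - 1{u<0}); nonnegative, zero iff u = 0."""
    _check_tau(tau)
    u = np.asarray(u, dtype=float)
    out = u * (tau - (u < 0))
    return float(out) if out.ndim == 0 else out


def ald_logpdf(y, mu, sigma: float, tau: float):
    """log ALD density: log[tau(1-tau)/sigma] - rho_tau((y-mu)/sigma)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    y = np.asarray(y, dtype=float)
    out = np.log(tau * (1.0 - tau) / sigma) - check_loss((y - mu) / sigma, tau)
    return float(out) if out.ndim == 0 else out


def ald_cdf(y, mu, sigma: float, tau: float):
    """ALD distribution function (closed form; mass tau at y = mu)."""
    _check_tau(tau)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    u = (np.asarray(y, dtype=float) - mu) / sigma
    below = tau * np.exp((1.0 - tau) * np.minimum(u, 0.0))
    above = 1.0 - (1.0 - tau) * np.exp(-tau * np.maximum(u, 0.0))
    out = np.where(u < 0, below, above)
    return float(out) if out.ndim == 0 else out


def ald_ppf(p, mu, sigma: float, tau: float):
    """ALD quantile function (inverse of :func:`ald_cdf`)."""
    _check_tau(tau)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly in (0, 1)")
    lower = sigma / (1.0 - tau) * np.log(p / tau)
    upper = -sigma / tau * np.log((1.0 - p) / (1.0 - tau))
    out = mu + np.where(p < tau, lower, upper)
    return float(out) if out.ndim == 0 else out


def ald_rvs(rng: np.random.Generator, mu, sigma: float, tau: float, size=None):
    """ALD draws by inversion (deterministic under a fixed generator)."""
    u = rng.uniform(size=size)
    return ald_ppf(u, mu, sigma, tau)


def mixture_constants(tau: float) -> tuple[float, float]:
    """(theta, kappa^2) of the normal-exponential ALD mixture.

    theta = (1-2 tau)/(tau(1-tau)), kappa^2 = 2/(tau(1-tau)); at the
    median theta = 0 and kappa^2 = 8.
    """
    _check_tau(tau)
    w = tau * (1.0 - tau)
    return (1.0 - 2.0 * tau) / w, 2.0 / w
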