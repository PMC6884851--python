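"""Intrinsic Gaussian Markov random field priors.

A GMRF prior on an effect vector ``f`` of length ``n`` has density

    p(f | delta)  ∝  delta^{(n-m)/2} exp(-delta/2 · f' Q f)

where ``Q`` is a symmetric positive semi-definite structure matrix of
rank ``n - m`` and ``delta`` is the block precision.  The rank
deficiency ``m`` identifies the flat directions: constants for a
first-order random walk (RW1) and the intrinsic CAR, constants plus
linear trends for a second-order random walk (RW2), and one constant
per connected component for an ICAR on a disconnected graph.

RW2 is the default smoother for metrical covariates (a locally
quadratic fit); the ICAR prior gives each district an effect that is
conditionally normal around the mean of its neighbours with precision
``delta * n_i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.io import mmwrite
from scipy.sparse import csr_matrix

from .data_model import AdjacencyGraph

__all__ = [
    "GMRFPrior",
    "rw1_precision",
    "rw2_precision",
    "icar_precision",
    "sample_gmrf",
    "log_pseudo_det",
    "to_matrix_market",
]

DEFAULT_HYPERPRIOR = (1.0, 5e-5)

#: relative eigenvalue threshold below which a direction counts as null
_NULL_TOL = 1e-9


@dataclass
class GMRFPrior:
    """Structure matrix, rank deficiency and precision hyperprior.

    ``delta_hyperprior`` is the (shape, rate) of the Gamma prior on the
    block precision delta; ``sum_to_zero`` records that the effect
    vector is identified by a sum-to-zero constraint (always true here —
    the intercept lives with the fixed effects).
    """

    Q: np.ndarray
    m: int
    delta_hyperprior: tuple[float, float] = DEFAULT_HYPERPRIOR
    sum_to_zero: bool = True
    kind: str = "gmrf"

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    @property
    def rank(self) -> int:
        return self.n - self.m

    def eigendecomposition(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigenvalues/vectors of Q with exact symmetrization."""
        lam, V = np.linalg.eigh((self.Q + self.Q.T) / 2.0)
        return lam, V


def _difference_operator(n: int, order: int) -> np.ndarray:
    D = np.eye(n)
    for _ in range(order):
        D = np.diff(D, axis=0)
    return D


def rw1_precision(n: int,
                  hyperprior: tuple[float, float] = DEFAULT_HYPERPRIOR) -> GMRFPrior:
    """First-order random-walk structure matrix: Q = D1' D1, m = 1."""
    if n < 2:
        raise ValueError("RW1 needs at least 2 grid points")
    D = _difference_operator(n, 1)
    return GMRFPrior(Q=D.T @ D, m=1, delta_hyperprior=hyperprior, kind="rw1")


def rw2_precision(n: int,
                  hyperprior: tuple[float, float] = DEFAULT_HYPERPRIOR) -> GMRFPrior:
    """Second-order random-walk structure matrix: Q = D2' D2, m = 2.

    Q annihilates constant and linear vectors, so the prior penalizes
    curvature only (a locally quadratic smoother).
    """
    if n < 3:
        raise ValueError("RW2 needs at least 3 grid points; use rw1_precision")
    D = _difference_operator(n, 2)
    return GMRFPrior(Q=D.T @ D, m=2, delta_hyperprior=hyperprior, kind="rw2")


def icar_precision(graph: AdjacencyGraph,
                   hyperprior: tuple[float, float] = DEFAULT_HYPERPRIOR) -> GMRFPrior:
    """Intrinsic CAR structure matrix: Q = diag(n_i) - A.

    The implied full conditional of node i given its neighbours is
    N(mean of neighbour effects, 1 / (delta * n_i)).  Isolated nodes are
    rejected: an island has no neighbour mean to shrink to, and a silent
    fallback would hide a data error.
    """
    if graph.n == 0:
        raise ValueError("empty adjacency graph")
    counts = graph.n_i()
    isolated = [a for a in graph.nodes if counts[a] == 0]
    if isolated:
        raise ValueError(f"isolated district(s) in adjacency graph: {isolated}")
    A = graph.adjacency_matrix()
    Q = np.diag(A.sum(axis=1)) - A
    return GMRFPrior(Q=Q, m=graph.n_components(),
                     delta_hyperprior=hyperprior, kind="icar")


def sample_gmrf(prior: GMRFPrior, delta: float,
                rng: np.random.Generator | int) -> np.ndarray:
    """Draw one effect vector from the constrained intrinsic GMRF.

    The draw lives in the row space of Q (each non-null eigendirection
    gets variance 1/(delta * lambda_k), null directions are zeroed), so
    it sums to zero — and for RW2 also has zero projection on the
    linear contrast — by construction.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lam, V = prior.eigendecomposition()
    pos = lam > _NULL_TOL * lam.max()
    z = rng.standard_normal(int(pos.sum()))
    return V[:, pos] @ (z / np.sqrt(delta * lam[pos]))


def log_pseudo_det(prior: GMRFPrior) -> float:
    """Log generalized determinant: sum of log non-zero eigenvalues of Q."""
    lam, _ = prior.eigendecomposition()
    pos = lam > _NULL_TOL * lam.max()
    if int(pos.sum()) != prior.rank:
        raise ValueError(
            f"numerical rank {int(pos.sum())} != n - m = {prior.rank}")
    return float(np.sum(np.log(lam[pos])))


def to_matrix_market(prior: GMRFPrior, path) -> None:
    """Export Q as Matrix-Market sparse text for inspection."""
    mmwrite(str(path), csr_matrix(prior.Q))
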