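"""Closed-form mutation-selection-balance expectations.

Three pieces of deterministic theory frame the simulations:

* Lande's Gaussian-regime equilibrium genetic covariance ``b``, per-trait
  variance ``c``, and correlation r = b/c = rho / (1 + sqrt(1 - rho^2)),
  which is independent of the mutational input (mu, alpha2) and of omega2.
* The house-of-cards single-locus G-matrix for a mutational direction
  theta: G = 2 mu a a^T / (a^T Omega^{-1} a), with the equivalent
  trigonometric closed form
  G = 2 mu omega2 (1-rho^2) / (1 - rho * 2 cos(theta) sin(theta)) *
      [[cos^2, cos*sin], [cos*sin, sin^2]](theta).
  The magnitude of ``a`` cancels; only its direction matters. On-axis
  directions (theta in {0, pi/2, pi, 3pi/2} — nonpleiotropic mutations)
  give zero off-diagonal: single-trait mutations generate no covariance.
* A mutation-regime classifier: the Gaussian regime needs mu >> alpha2/omega2
  (many small mutations), the house-of-cards regime mu << alpha2/omega2
  (rare large mutations); we use factor-of-10 margins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TheoryParams",
    "lande_equilibrium",
    "hoc_gmatrix",
    "hoc_gmatrix_eq8",
    "classify_regime",
]


@dataclass(frozen=True)
class TheoryParams:
    rho_omega: float
    omega2: float
    mu: float
    alpha2: float
    theta_angle: float = 0.0


def lande_equilibrium(params: TheoryParams, n_loci: int = 1):
    """Equilibrium (b, c, r): genetic covariance, variance, correlation.

    Per-locus values are scaled by ``n_loci`` (independent loci summing under
    linkage equilibrium between loci); the correlation r is invariant to
    n_loci, mu, alpha2 and omega2 and equals rho / (1 + sqrt(1 - rho^2)).
    """
    rho = params.rho_omega
    if abs(rho) >= 1:
        raise ValueError("|rho_omega| must be < 1")
    if params.mu <= 0 or params.alpha2 <= 0 or params.omega2 <= 0:
        raise ValueError("mu, alpha2, omega2 must be positive")
    s = math.sqrt(1.0 - rho * rho)
    w2ma = params.omega2 * params.mu * params.alpha2
    c = math.sqrt(2.0 * (1.0 + s) * w2ma)
    b = 2.0 * rho * w2ma / c
    r = rho / (1.0 + s)
    return n_loci * b, n_loci * c, r


def hoc_gmatrix_eq8(a_vec, params: TheoryParams, n_loci: int = 1) -> np.ndarray:
    """House-of-cards G-matrix from the matrix form 2 mu a a^T/(a^T Om^-1 a)."""
    a = np.asarray(a_vec, dtype=float)
    if np.allclose(a, 0):
        raise ValueError("mutational direction a must be nonzero")
    rho = params.rho_omega
    if abs(rho) >= 1:
        raise ValueError("singular selection surface")
    Om_inv = np.array([[1.0, -rho], [-rho, 1.0]]) / (
        params.omega2 * (1.0 - rho * rho)
    )
    denom = a @ Om_inv @ a
    return n_loci * 2.0 * params.mu * np.outer(a, a) / denom


def hoc_gmatrix(params: TheoryParams, n_loci: int = 1) -> np.ndarray:
    """House-of-cards G-matrix, trigonometric closed form in theta.

    Agrees with :func:`hoc_gmatrix_eq8` to machine precision for every
    (theta, rho_omega); rank 1 and positive semidefinite by construction.
    """
    th = params.theta_angle
    rho = params.rho_omega
    if abs(rho) >= 1:
        raise ValueError("singular selection surface")
    c, s = math.cos(th), math.sin(th)
    scalar = (
        2.0
        * params.mu
        * params.omega2
        * (1.0 - rho * rho)
        / (1.0 - rho * 2.0 * c * s)
    )
    mat = np.array([[c * c, c * s], [c * s, s * s]])
    return n_loci * scalar * mat


def classify_regime(params: TheoryParams) -> str:
    """Classify (mu, alpha2, omega2) into a mutation regime.

    "gaussian" if mu >= 10 * alpha2/omega2, "house_of_cards" if
    mu <= 0.1 * alpha2/omega2, else "intermediate".
    """
    if params.mu <= 0 or params.alpha2 <= 0 or params.omega2 <= 0:
        raise ValueError("mu, alpha2, omega2 must be positive")
    pivot = params.alpha2 / params.omega2
    if params.mu >= 10.0 * pivot:
        return "gaussian"
    if params.mu <= 0.1 * pivot:
        return "house_of_cards"
    return "intermediate"
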