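"""Gaussian stabilizing + correlational viability selection on two traits.

Fitness (juvenile survival probability) is

    w(z) = exp(-1/2 (z - theta)^T Omega^{-1} (z - theta)),

with selection surface Omega = omega2 * [[1, rho], [rho, 1]]: ``omega2`` sets
the width per trait (smaller = stronger stabilizing selection) and
``rho_omega`` the correlational component favoring matched trait
combinations along the diagonal when positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SelectionRegime", "build_selection", "fitness"]


@dataclass
class SelectionRegime:
    omega2: float
    rho_omega: float
    optima: np.ndarray
    Omega: np.ndarray = field(init=False, repr=False)
    Omega_inv: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.omega2 <= 0:
            raise ValueError("omega2 must be positive")
        if abs(self.rho_omega) >= 1:
            raise ValueError("|rho_omega| must be < 1 (singular surface)")
        self.optima = np.asarray(self.optima, dtype=float)
        if self.optima.shape != (2,):
            raise ValueError("optima must be a 2-vector")
        r = self.rho_omega
        self.Omega = self.omega2 * np.array([[1.0, r], [r, 1.0]])
        self.Omega_inv = np.array([[1.0, -r], [-r, 1.0]]) / (
            self.omega2 * (1.0 - r * r)
        )


def build_selection(omega2: float, rho_omega: float, optima) -> SelectionRegime:
    """Build a selection regime; rejects |rho_omega| >= 1."""
    return SelectionRegime(omega2, rho_omega, np.asarray(optima, dtype=float))


def fitness(z, regime: SelectionRegime):
    """Survival probability for phenotype(s) z (shape (2,) or (B, 2))."""
    z = np.asarray(z, dtype=float)
    dz = z - regime.optima
    if dz.ndim == 1:
        q = dz @ regime.Omega_inv @ dz
        return float(np.exp(-0.5 * q))
    q = np.einsum("bi,ij,bj->b", dz, regime.Omega_inv, dz)
    return np.exp(-0.5 * q)
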