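"""Mutation models for causal loci and neutral markers.

Causal loci mutate at haploid per-locus rate ``mu`` per gamete per
generation. Under the continuum-of-alleles model a mutation adds an effect
drawn from N(0, alpha2) to the existing allelic value; at a pleiotropic locus
the increment is bivariate N2(0, alpha2*I) (no mutational correlation), while
at a single-trait locus the mutational vector lies on that trait's axis
(direction angle theta in {0, pi/2, pi, 3pi/2}) so a pair of linked
nonpleiotropic loci produces a cross-shaped joint distribution of mutational
effects: both components are simultaneously nonzero only when both members
mutate in the same generation (probability mu^2).

In biallelic QTN mode each causal locus has a fixed effect magnitude and a
mutation flips the sign of the allele's effect. Neutral markers are
reversible diallelic 0/1 loci mutating at ``neutral_mu``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome import ArchitectureSpec

__all__ = [
    "MutationParams",
    "MutationVector",
    "Gamete",
    "sample_pleiotropic_effect",
    "sample_nonpleiotropic_effect",
    "apply_mutations",
]

CONTINUUM = "continuum"
QTN_BIALLELIC = "qtn_biallelic"


@dataclass(frozen=True)
class MutationParams:
    """Mutation rates and effect-size variance.

    mu : haploid per-causal-locus mutation rate per generation.
    alpha2 : variance of the Gaussian mutational effect distribution.
    mode : "continuum" (additive continuum-of-alleles) or "qtn_biallelic".
    neutral_mu : per-allele flip rate of diallelic neutral markers.
    qtn_equal_magnitudes : in QTN mode, fix every |effect| to sqrt(alpha2)
        instead of drawing per-locus magnitudes |N(0, alpha2)|.
    """

    mu: float
    alpha2: float
    mode: str = CONTINUUM
    neutral_mu: float = 1e-6
    qtn_equal_magnitudes: bool = False

    def __post_init__(self):
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError("mu must be in [0, 1]")
        if self.alpha2 < 0:
            raise ValueError("alpha2 must be nonnegative")
        if self.mode not in (CONTINUUM, QTN_BIALLELIC):
            raise ValueError(f"unknown mutation mode {self.mode!r}")


@dataclass(frozen=True)
class MutationVector:
    """A mutational effect in the two-trait plane: a*(cos theta, sin theta)."""

    effect_on_trait1: float
    effect_on_trait2: float
    theta: float

    @property
    def magnitude(self) -> float:
        return math.hypot(self.effect_on_trait1, self.effect_on_trait2)


@dataclass
class Gamete:
    """One haplotype: causal allelic values (n_causal, 2) + marker states."""

    values: np.ndarray
    markers: np.ndarray


def sample_pleiotropic_effect(params: MutationParams, rng: np.random.Generator) -> MutationVector:
    """Draw a pleiotropic mutational effect ~ N2(0, alpha2 * I)."""
    if params.mode != CONTINUUM:
        raise ValueError("pleiotropic effect sampling requires continuum mode")
    sd = math.sqrt(params.alpha2)
    e1, e2 = rng.normal(0.0, sd, size=2)
    return MutationVector(e1, e2, math.atan2(e2, e1) % (2 * math.pi))


def sample_nonpleiotropic_effect(
    params: MutationParams, target_trait: int, rng: np.random.Generator
) -> MutationVector:
    """Draw a single-trait mutational effect a ~ N(0, alpha2) on one axis."""
    if params.mode != CONTINUUM:
        raise ValueError("nonpleiotropic effect sampling requires continuum mode")
    if target_trait not in (1, 2):
        raise ValueError("target_trait must be 1 or 2")
    a = rng.normal(0.0, math.sqrt(params.alpha2))
    if target_trait == 1:
        theta = 0.0 if a >= 0 else math.pi
        return MutationVector(a, 0.0, theta)
    theta = math.pi / 2 if a >= 0 else 3 * math.pi / 2
    return MutationVector(0.0, a, theta)


def mutate_value_batch(
    values: np.ndarray,
    trait_matrix: np.ndarray,
    params: MutationParams,
    rng: np.random.Generator,
) -> None:
    """In place, mutate a batch of causal haplotypes (B, n_causal, 2).

    Each (gamete, locus) cell mutates independently with probability mu.
    Continuum mode adds a Gaussian effect masked by the loci's trait
    assignments; QTN mode flips the sign of the current effect.
    """
    if params.mu == 0.0 or values.size == 0:
        return
    B, L, _ = values.shape
    hits = rng.random((B, L)) < params.mu
    k = int(hits.sum())
    if k == 0:
        return
    b_idx, l_idx = np.nonzero(hits)
    if params.mode == CONTINUUM:
        eff = rng.normal(0.0, math.sqrt(params.alpha2), size=(k, 2))
        values[b_idx, l_idx, :] += eff * trait_matrix[l_idx]
    else:
        values[b_idx, l_idx, :] *= -1.0


def mutate_marker_batch(
    markers: np.ndarray, neutral_mu: float, rng: np.random.Generator
) -> None:
    """In place, flip diallelic marker states (B, n_neutral) at neutral_mu.

    The flip count is binomial over all cells with positions drawn uniformly;
    at the tiny per-site rates used here coincident draws are negligible.
    """
    if neutral_mu == 0.0 or markers.size == 0:
        return
    n_cells = markers.size
    k = rng.binomial(n_cells, neutral_mu)
    if k == 0:
        return
    flat = rng.integers(0, n_cells, size=k)
    markers.reshape(-1)[flat] ^= 1


def apply_mutations(
    gamete: Gamete,
    arch: ArchitectureSpec,
    params: MutationParams,
    rng: np.random.Generator,
) -> Gamete:
    """Return a mutated copy of one gamete (convenience, single-haplotype).

    The simulator uses the batched in-place kernels directly; this wrapper
    exposes the same process for one haplotype.
    """
    if gamete.values.shape[0] != arch.n_causal or gamete.markers.shape[0] != arch.n_neutral:
        raise ValueError("gamete length does not match architecture")
    vals = gamete.values[None, :, :].copy()
    marks = gamete.markers[None, :].copy()
    mutate_value_batch(vals, arch.trait_matrix, params, rng)
    mutate_marker_batch(marks, params.neutral_mu, rng)
    return Gamete(vals[0], marks[0])
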