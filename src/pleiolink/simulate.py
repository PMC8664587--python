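"""Forward-time Wright-Fisher engine for one or two demes.

Life cycle per nonoverlapping generation: N diploid hermaphrodites mate at
random (selfing allowed, parents drawn with replacement); each parent
transmits one recombined, mutated gamete; the juvenile survives viability
selection with probability w(z) from its two-trait phenotype; reproduction
repeats until exactly N survivors regulate the population back to carrying
capacity (soft selection). With unidirectional migration at backward rate m,
an offspring draws both parents from the source deme with probability m.

Phenotypes are purely genetic: the sum over the 2L allele copies of their
effects on each trait (no environmental deviation). Populations start
monomorphic with every phenotype exactly at the local optimum; variation
builds up through mutation.

Recombination uses per-interval Haldane fractions between adjacent loci on
a chromosome; chromosomes assort independently. Crossovers are sampled
sparsely (binomial counts per interval), which keeps dense neutral-marker
panels cheap since adjacent-marker fractions are ~1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ArchitectureSpec, Role
from .mutation import (
    CONTINUUM,
    MutationParams,
    QTN_BIALLELIC,
    mutate_marker_batch,
    mutate_value_batch,
)
from .selection import SelectionRegime, fitness

__all__ = [
    "Population",
    "SimConfig",
    "SimResult",
    "initialize_population",
    "advance_generation",
    "run_simulation",
    "take_sample",
]

_FITNESS_FLOOR = 1e-12


@dataclass
class Population:
    """One deme: haplotype-level state plus derived phenotypes.

    values : (N, 2, n_causal, 2) allelic effects of each allele copy on
        traits 1 and 2 (zero on a trait the locus does not affect).
    markers : (N, 2, n_neutral) diallelic neutral marker states (0/1).
    basal : (2,) non-evolving phenotype offset (nonzero only in QTN mode,
        where it recenters the monomorphic start onto the optimum).
    """

    values: np.ndarray
    markers: np.ndarray
    phenotypes: np.ndarray
    basal: np.ndarray
    deme_id: int = 0
    generation: int = 0

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    def recompute_phenotypes(self) -> np.ndarray:
        """Phenotypes implied by the haplotypes (consistency check/refresh)."""
        return self.values.sum(axis=(1, 2)) + self.basal


@dataclass
class SimConfig:
    architecture: ArchitectureSpec
    mutation: MutationParams
    selection: SelectionRegime | None
    n_individuals: int = 5000
    generations: int = 50000
    migration_rate: float = 0.0
    migration_start: int = 0
    sample_size: int = 1000
    seed: int = 0
    record_every: int | None = None

    def __post_init__(self):
        if not (0.0 <= self.migration_rate < 1.0):
            raise ValueError("migration rate must be in [0, 1)")
        if self.sample_size > self.n_individuals:
            raise ValueError("sample_size cannot exceed N")


@dataclass
class SimResult:
    trajectory: pd.DataFrame
    population: Population
    sample: "object | None"
    config: SimConfig


# ---------------------------------------------------------------------------
# recombination machinery


class _RecombPlan:
    """Precomputed sparse crossover layout for one architecture."""

    def __init__(self, arch: ArchitectureSpec):
        self.L = arch.n_loci
        # contiguous 0-based chromosome index per locus
        _, self.chrom_map = np.unique(arch.chrom, return_inverse=True)
        self.n_chrom = int(self.chrom_map.max()) + 1 if self.L else 0
        r = arch.interval_recomb()
        within = np.diff(arch.chrom) == 0
        active = within & (r > 0)
        self.event_interval = np.flatnonzero(active)  # interval i = loci (i, i+1)
        self.event_r = r[self.event_interval]
        # end-of-chromosome locus index (exclusive) for each event interval
        ends = np.searchsorted(self.chrom_map, self.chrom_map, side="right")
        self.event_end = ends[self.event_interval]

    def sample_haplotype_choice(self, B: int, rng: np.random.Generator) -> np.ndarray:
        """(B, L) uint8 array: which parental haplotype each locus comes from."""
        starts = rng.integers(0, 2, size=(B, self.n_chrom), dtype=np.uint8)
        hap = starts[:, self.chrom_map]
        if self.event_interval.size:
            counts = rng.binomial(B, self.event_r)
            for e in np.flatnonzero(counts):
                rows = rng.choice(B, size=counts[e], replace=False)
                hap[rows, self.event_interval[e] + 1 : self.event_end[e]] ^= 1
        return hap


def _gametes(
    pop: Population,
    parents: np.ndarray,
    plan: _RecombPlan,
    arch: ArchitectureSpec,
    rng: np.random.Generator,
):
    """Form one gamete per parent index: (values (B,Lc,2), markers (B,Lm))."""
    B = parents.shape[0]
    hap = plan.sample_haplotype_choice(B, rng)
    hc = hap[:, arch.causal_idx]  # (B, Lc)
    gv = np.where(
        hc[:, :, None] == 0,
        pop.values[parents, 0],
        pop.values[parents, 1],
    )
    if arch.n_neutral:
        hm = hap[:, arch.neutral_idx]
        gm = np.where(hm == 0, pop.markers[parents, 0], pop.markers[parents, 1])
    else:
        gm = np.empty((B, 0), dtype=pop.markers.dtype)
    return gv, gm


# ---------------------------------------------------------------------------
# life cycle


def initialize_population(
    config: SimConfig, rng: np.random.Generator | None = None, deme_id: int = 0
) -> Population:
    """Monomorphic starting population with every phenotype at the optimum.

    Continuum mode: each allele copy at a trait-k locus holds value
    theta_k / (2 n_k), so the 2 n_k copies sum exactly to the optimum.
    QTN mode: per-locus effect magnitudes are fixed (|N(0, alpha2)| draws,
    or sqrt(alpha2) when equal magnitudes are requested), initial signs are
    random but shared by all individuals, and the residual theta - sum goes
    into a non-evolving basal value so selection is neutral at generation 0.
    """
    arch = config.architecture
    N = config.n_individuals
    Lc, Lm = arch.n_causal, arch.n_neutral
    theta = (
        config.selection.optima if config.selection is not None else np.zeros(2)
    )
    qtn_roles = {r in Role.QTN for r in arch.roles[arch.causal_idx]}
    if config.mutation.mode == QTN_BIALLELIC and qtn_roles != ({True} if Lc else set()):
        raise ValueError("qtn_biallelic mutation requires an all-QTN architecture")
    if config.mutation.mode == CONTINUUM and True in qtn_roles:
        raise ValueError("continuum mutation cannot drive QTN loci")

    basal = np.zeros(2)
    per_locus = np.zeros((Lc, 2))
    if config.mutation.mode == CONTINUUM:
        n_per_trait = arch.trait_matrix.sum(axis=0)  # loci affecting each trait
        for k in range(2):
            if n_per_trait[k] > 0:
                per_locus[:, k] = (
                    arch.trait_matrix[:, k] * theta[k] / (2.0 * n_per_trait[k])
                )
    else:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        if config.mutation.qtn_equal_magnitudes:
            mags = np.full(Lc, np.sqrt(config.mutation.alpha2))
        else:
            mags = np.abs(rng.normal(0.0, np.sqrt(config.mutation.alpha2), size=Lc))
        signs = rng.choice([-1.0, 1.0], size=Lc)
        per_locus = (signs * mags)[:, None] * arch.trait_matrix
        basal = theta - 2.0 * per_locus.sum(axis=0)

    values = np.broadcast_to(per_locus, (N, 2, Lc, 2)).copy()
    markers = np.zeros((N, 2, Lm), dtype=np.int8)
    pop = Population(values, markers, np.empty((N, 2)), basal, deme_id=deme_id)
    pop.phenotypes = pop.recompute_phenotypes()
    if config.selection is not None and not np.allclose(pop.phenotypes[0], theta):
        raise AssertionError("initialization failed to hit the optimum")
    return pop


def _offspring_batch(
    pop: Population,
    source: Population | None,
    config: SimConfig,
    plan: _RecombPlan,
    B: int,
    rng: np.random.Generator,
    migrating: bool,
):
    """Candidate juveniles before selection: (values, markers, phenotypes)."""
    arch = config.architecture
    m = config.migration_rate if migrating else 0.0
    if m > 0.0 and source is not None:
        is_migrant = rng.random(B) < m  # both parents from the source deme
    else:
        is_migrant = np.zeros(B, dtype=bool)
    vals = np.empty((B, 2, arch.n_causal, 2))
    marks = np.empty((B, 2, arch.n_neutral), dtype=pop.markers.dtype)
    for deme, mask in ((pop, ~is_migrant), (source, is_migrant)):
        nb = int(mask.sum())
        if nb == 0:
            continue
        N = deme.n_individuals
        gv1, gm1 = _gametes(deme, rng.integers(0, N, nb), plan, arch, rng)
        gv2, gm2 = _gametes(deme, rng.integers(0, N, nb), plan, arch, rng)
        vals[mask] = np.stack([gv1, gv2], axis=1)
        marks[mask] = np.stack([gm1, gm2], axis=1)
    # mutate both gametes in one pass
    if arch.n_causal:
        mutate_value_batch(
            vals.reshape(-1, arch.n_causal, 2), arch.trait_matrix, config.mutation, rng
        )
    if arch.n_neutral:
        mutate_marker_batch(
            marks.reshape(-1, arch.n_neutral), config.mutation.neutral_mu, rng
        )
    z = vals.sum(axis=(1, 2)) + pop.basal
    return vals, marks, z


def advance_generation(
    pop: Population,
    source: Population | None,
    config: SimConfig,
    rng: np.random.Generator,
    plan: _RecombPlan | None = None,
    migrating: bool | None = None,
) -> Population:
    """Produce the next generation of exactly N surviving adults."""
    if plan is None:
        plan = _RecombPlan(config.architecture)
    if migrating is None:
        migrating = config.migration_rate > 0.0 and source is not None
    N = config.n_individuals
    regime = config.selection
    acc_v, acc_m, acc_z = [], [], []
    n_have, w_est = 0, 1.0
    while n_have < N:
        B = min(int((N - n_have) / max(w_est, 0.05) * 1.15) + 16, 8 * N)
        vals, marks, z = _offspring_batch(pop, source, config, plan, B, rng, migrating)
        if regime is None:
            keep = np.arange(B)
            w_mean = 1.0
        else:
            w = fitness(z, regime)
            w_mean = float(w.mean())
            if w_mean < _FITNESS_FLOOR:
                raise RuntimeError(
                    "mean fitness collapsed below floor; population regulation "
                    "cannot terminate"
                )
            keep = np.flatnonzero(rng.random(B) < w)
        w_est = 0.5 * (w_est + max(w_mean, _FITNESS_FLOOR))
        if keep.size:
            take = keep[: N - n_have]
            acc_v.append(vals[take])
            acc_m.append(marks[take])
            acc_z.append(z[take])
            n_have += take.size
    new = Population(
        np.concatenate(acc_v) if len(acc_v) > 1 else acc_v[0],
        np.concatenate(acc_m) if len(acc_m) > 1 else acc_m[0],
        np.concatenate(acc_z) if len(acc_z) > 1 else acc_z[0],
        pop.basal,
        deme_id=pop.deme_id,
        generation=pop.generation + 1,
    )
    return new


# ---------------------------------------------------------------------------
# recording and sampling


def _segregating_causal(pop: Population) -> int:
    if pop.values.shape[2] == 0:
        return 0
    ref = pop.values[0, 0]  # (Lc, 2)
    diff = np.any(pop.values != ref[None, None, :, :], axis=(0, 1, 3))
    return int(diff.sum())


def _record(pop: Population) -> dict:
    z = pop.phenotypes
    var = z.var(axis=0, ddof=1)
    cov = float(np.cov(z[:, 0], z[:, 1], ddof=1)[0, 1])
    denom = np.sqrt(var[0] * var[1])
    return {
        "generation": pop.generation,
        "gvar1": float(var[0]),
        "gvar2": float(var[1]),
        "gcov": cov,
        "gcor": cov / denom if denom > 0 else 0.0,
        "mean_z1": float(z[:, 0].mean()),
        "mean_z2": float(z[:, 1].mean()),
        "n_seg_causal": _segregating_causal(pop),
    }


def take_sample(pop: Population, arch: ArchitectureSpec, n: int, rng: np.random.Generator):
    """Draw n individuals without replacement as a GenotypeSample."""
    from .gwaa import build_sample_from_population

    idx = rng.choice(pop.n_individuals, size=n, replace=False)
    return build_sample_from_population(pop, arch, idx)


def run_simulation(
    config: SimConfig, source_config: SimConfig | None = None
) -> SimResult:
    """Run one replicate; optionally co-evolve an unaffected source deme.

    The source deme (island-mainland layout) evolves under its own selection
    regime with no immigration; the focal deme draws both parents of a
    fraction m of its offspring from the source once ``migration_start``
    generations have elapsed. Records population statistics at the
    configured cadence and, at the end, a sample of ``sample_size``
    individuals with full genotypes and phenotypes.
    """
    if config.migration_rate > 0.0 and source_config is None:
        raise ValueError("migration requires a source deme configuration")
    rng = np.random.default_rng(config.seed)
    plan = _RecombPlan(config.architecture)
    pop = initialize_population(config, rng, deme_id=0)
    source = None
    if source_config is not None:
        source = initialize_population(source_config, rng, deme_id=1)
    cadence = config.record_every
    records = [_record(pop)]
    for gen in range(config.generations):
        migrating = (
            config.migration_rate > 0.0
            and source is not None
            and gen >= config.migration_start
        )
        if source is not None:
            source = advance_generation(source, None, source_config, rng, plan, False)
        pop = advance_generation(pop, source, config, rng, plan, migrating)
        if (cadence and pop.generation % cadence == 0) or gen == config.generations - 1:
            records.append(_record(pop))
    sample = None
    if config.sample_size:
        sample = take_sample(pop, config.architecture, config.sample_size, rng)
    return SimResult(pd.DataFrame(records), pop, sample, config)
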