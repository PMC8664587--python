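import numpy as np
import pytest

from pleiolink.genome import ArchitectureSpec, LocusDescriptor, Role, build_architecture
from pleiolink.mutation import MutationParams
from pleiolink.selection import build_selection
from pleiolink.simulate import (
    Population,
    SimConfig,
    advance_generation,
    initialize_population,
    run_simulation,
)


def _config(kind="pleiotropy", n_loci=10, mu=1e-4, alpha2=0.1, rho=0.9, N=50,
            generations=5, mode="continuum", seed=3, **kw):
    arch = build_architecture(kind, n_loci, biallelic=(mode == "qtn_biallelic"))
    return SimConfig(
        architecture=arch,
        mutation=MutationParams(mu=mu, alpha2=alpha2, mode=mode),
        selection=build_selection(100.0, rho, (10.0, 10.0)),
        n_individuals=N,
        generations=generations,
        sample_size=0,
        seed=seed,
        **kw,
    )


def _neutral_only_arch(n_markers):
    """One diallelic neutral marker per chromosome (independent loci)."""
    loci = [LocusDescriptor(i, i, 0.0, Role.NEUTRAL) for i in range(n_markers)]
    return ArchitectureSpec(loci, n_markers, [0.0] * n_markers, "pleiotropy")


def _neutral_population(arch, N, p, rng):
    markers = (rng.random((N, 2, arch.n_neutral)) < p).astype(np.int8)
    pop = Population(
        np.zeros((N, 2, 0, 2)), markers, np.zeros((N, 2)), np.zeros(2)
    )
    return pop


class TestInitialization:
    def test_pleiotropy_per_allele_contribution(self):
        cfg = _config("pleiotropy", 120, N=20)
        pop = initialize_population(cfg)
        assert np.allclose(pop.values, 10.0 / 240.0)
        assert np.allclose(pop.phenotypes, 10.0)

    def test_linkage_initial_values(self):
        cfg = _config("linkage", 60, N=20)
        pop = initialize_population(cfg)
        # trait-1 loci carry theta1/(2*60) on component 0 only
        assert np.allclose(pop.values[:, :, ::2, 0], 10.0 / 120.0)
        assert np.allclose(pop.values[:, :, ::2, 1], 0.0)
        assert np.allclose(pop.phenotypes, 10.0)

    def test_zero_optimum_all_zero(self):
        arch = build_architecture("pleiotropy", 10)
        cfg = SimConfig(
            architecture=arch,
            mutation=MutationParams(mu=1e-4, alpha2=0.1),
            selection=build_selection(100.0, 0.9, (0.0, 0.0)),
            n_individuals=10,
            generations=1,
            sample_size=0,
        )
        pop = initialize_population(cfg)
        assert np.all(pop.values == 0.0)

    def test_initial_variance_zero(self):
        pop = initialize_population(_config("linkage", 30, N=30))
        assert pop.phenotypes.var(axis=0).max() == 0.0

    def test_qtn_start_at_optimum_with_basal(self):
        cfg = _config("pleiotropy", 20, mode="qtn_biallelic", N=15)
        pop = initialize_population(cfg)
        assert np.allclose(pop.phenotypes, 10.0)
        assert not np.allclose(pop.basal, 0.0)
        # monomorphic: all individuals identical
        assert np.all(pop.values == pop.values[0, 0][None, None, :, :])


class TestAdvanceGeneration:
    def test_nothing_varies_without_mutation(self, rng):
        cfg = _config(mu=0.0, N=40)
        pop = initialize_population(cfg)
        nxt = advance_generation(pop, None, cfg, rng)
        assert nxt.n_individuals == 40
        assert np.allclose(nxt.phenotypes, 10.0)
        assert np.array_equal(nxt.values, pop.values)

    def test_population_size_constant(self, rng):
        cfg = _config(mu=1e-2, N=35, rho=0.5)
        pop = initialize_population(cfg)
        for _ in range(4):
            pop = advance_generation(pop, None, cfg, rng)
            assert pop.n_individuals == 35

    def test_phenotype_haplotype_consistency(self, rng):
        cfg = _config(mu=5e-3, N=60)
        pop = initialize_population(cfg)
        for _ in range(5):
            pop = advance_generation(pop, None, cfg, rng)
            assert np.allclose(pop.phenotypes, pop.recompute_phenotypes())

    def test_fitness_collapse_raises(self, rng):
        # optimum far away from the monomorphic start
        arch = build_architecture("pleiotropy", 5)
        cfg = SimConfig(
            architecture=arch,
            mutation=MutationParams(mu=0.0, alpha2=0.1),
            selection=build_selection(1e-4, 0.0, (10.0, 10.0)),
            n_individuals=20,
            generations=1,
            sample_size=0,
        )
        pop = initialize_population(cfg)
        pop.values *= 0.0  # shift everyone to (0, 0), ~infinitely unfit
        pop.phenotypes = pop.recompute_phenotypes()
        with pytest.raises(RuntimeError, match="fitness"):
            advance_generation(pop, None, cfg, rng)

    def test_migration_fraction_of_source_parents(self, rng):
        """With m, on average a fraction m of offspring have source parents."""
        arch = _neutral_only_arch(1)
        N = 400
        cfg = SimConfig(
            architecture=arch,
            mutation=MutationParams(mu=0.0, alpha2=0.1, neutral_mu=0.0),
            selection=None,
            n_individuals=N,
            migration_rate=0.1,
            generations=1,
            sample_size=0,
        )
        focal = _neutral_population(arch, N, 0.0, rng)
        source = _neutral_population(arch, N, 1.0, rng)  # fixed for allele 1
        fracs = []
        for _ in range(60):
            nxt = advance_generation(focal, source, cfg, rng)
            # marker dosage 2 iff both parents were migrants (allele fixed in source)
            fracs.append((nxt.markers.sum(axis=(1, 2)) == 2).mean())
        assert np.mean(fracs) == pytest.approx(0.1, abs=0.01)


class TestNeutralDrift:
    def test_wright_fisher_sampling_variance(self, rng):
        """One neutral generation: Var(dp) ~= p(1-p)/(2N), E[dp] ~= 0."""
        arch = _neutral_only_arch(30)
        N, p = 200, 0.5
        cfg = SimConfig(
            architecture=arch,
            mutation=MutationParams(mu=0.0, alpha2=0.1, neutral_mu=0.0),
            selection=None,
            n_individuals=N,
            generations=1,
            sample_size=0,
        )
        dps = []
        for _ in range(40):
            pop = _neutral_population(arch, N, p, rng)
            p0 = pop.markers.mean(axis=(0, 1))
            nxt = advance_generation(pop, None, cfg, rng)
            dps.append(nxt.markers.mean(axis=(0, 1)) - p0)
        dps = np.concatenate(dps)
        expected_var = p * (1 - p) / (2 * N)
        assert dps.mean() == pytest.approx(0.0, abs=4 * np.sqrt(expected_var / dps.size))
        assert dps.var() == pytest.approx(expected_var, rel=0.15)


class TestRunSimulation:
    def test_zero_generations_single_record(self):
        cfg = _config(N=30, generations=0)
        cfg.sample_size = 10
        res = run_simulation(cfg)
        assert len(res.trajectory) == 1
        assert res.population.generation == 0
        assert res.sample.phenotypes.shape == (10, 2)

    def test_bit_reproducible_with_same_seed(self):
        r1 = run_simulation(_config(mu=1e-2, N=40, generations=6, seed=99))
        r2 = run_simulation(_config(mu=1e-2, N=40, generations=6, seed=99))
        assert np.array_equal(r1.population.values, r2.population.values)
        assert r1.trajectory.equals(r2.trajectory)

    def test_different_seed_differs(self):
        r1 = run_simulation(_config(mu=1e-2, N=40, generations=6, seed=1))
        r2 = run_simulation(_config(mu=1e-2, N=40, generations=6, seed=2))
        assert not np.array_equal(r1.population.values, r2.population.values)

    def test_no_correlational_selection_no_systematic_gcor(self):
        """rho_omega=0 with pleiotropic loci: mean equilibrium Gcor ~ 0."""
        gcors = [
            run_simulation(
                _config("pleiotropy", 20, mu=1e-3, rho=0.0, N=100,
                        generations=300, seed=s)
            ).trajectory.iloc[-1]["gcor"]
            for s in range(6)
        ]
        se = np.std(gcors, ddof=1) / np.sqrt(len(gcors))
        assert abs(np.mean(gcors)) < 3 * max(se, 0.02)

    def test_migration_requires_source(self):
        cfg = _config(N=20, migration_rate=0.1)
        with pytest.raises(ValueError):
            run_simulation(cfg)

    def test_trajectory_cadence(self):
        cfg = _config(N=30, generations=10, record_every=5)
        tr = run_simulation(cfg).trajectory
        assert list(tr["generation"]) == [0, 5, 10]
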