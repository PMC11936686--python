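import numpy as np
import pandas as pd
import pytest

from erosim.demography import Scenario, Timeline
from erosim.engine import (
    GenotypeMatrix,
    MutationTable,
    PopulationState,
    SimulationError,
    _diplotype_split,
    individual_fitness,
    initialize_equilibrium,
    run_scenario,
    sample_individuals,
    step_generation,
)
from erosim.genome_model import (
    DELETERIOUS,
    NEUTRAL,
    ConfigurationError,
    DFESpec,
)


def table_from(positions, s, h, kind):
    t = MutationTable()
    t.append(np.array(positions), np.array(s, float), np.array(h, float),
             np.array(kind, np.uint8), origin=0)
    return t


def hap(*ids):
    return np.array(ids, dtype=np.int64)


class TestFitness:
    def test_no_deleterious_mutations(self):
        t = table_from([10, 20], [0, 0], [0.5, 0.5], [NEUTRAL, NEUTRAL])
        assert individual_fitness((hap(0), hap(1)), t) == 1.0

    def test_single_heterozygote(self):
        t = table_from([10], [-0.2], [0.25], [DELETERIOUS])
        assert individual_fitness((hap(0), hap()), t) == pytest.approx(0.95)

    def test_two_homozygous_sites(self):
        t = table_from([10, 20], [-0.1, -0.1], [0.1, 0.1],
                       [DELETERIOUS, DELETERIOUS])
        assert individual_fitness((hap(0, 1), hap(0, 1)), t) == pytest.approx(0.81)

    def test_lethal_homozygote_has_zero_fitness(self):
        t = table_from([10], [-1.0], [0.0], [DELETERIOUS])
        assert individual_fitness((hap(0), hap(0)), t) == 0.0

    def test_kernel_agrees_with_reference_on_random_diplotypes(self, rng):
        """JIT path vs a direct per-genotype dictionary computation."""
        for _ in range(25):
            n = int(rng.integers(1, 60))
            pos = np.sort(rng.choice(10_000, n, replace=False))
            s = np.where(rng.random(n) < 0.5, -rng.random(n) * 0.3, 0.0)
            kind = (s < 0).astype(np.uint8)
            h = rng.random(n) * 0.5
            t = table_from(pos, s, h, kind)
            ids = np.arange(n)
            h0 = np.sort(rng.choice(ids, rng.integers(0, n + 1), replace=False))
            h1 = np.sort(rng.choice(ids, rng.integers(0, n + 1), replace=False))
            expected = 1.0
            for i in ids:
                g = (i in h0) + (i in h1)
                if s[i] < 0 and g == 2:
                    expected *= 1.0 + s[i]
                elif s[i] < 0 and g == 1:
                    expected *= 1.0 + h[i] * s[i]
            got = individual_fitness((h0.astype(np.int64), h1.astype(np.int64)), t)
            assert got == pytest.approx(expected, rel=1e-12)

    def test_diplotype_split(self):
        t = table_from([10, 20, 30], [0, 0, 0], [0.5] * 3, [0, 0, 0])
        hom, het0, het1 = _diplotype_split(hap(0, 2), hap(0, 1), t.position)
        assert hom.tolist() == [0]
        assert het0.tolist() == [2]
        assert het1.tolist() == [1]


def two_deme_state(arch, dfe):
    """Two demes whose individuals carry deme-private neutral alleles."""
    t = MutationTable()
    t.append(np.array([100, 200]), np.zeros(2), np.full(2, 0.5),
             np.zeros(2, np.uint8), origin=0)
    d0 = [(hap(0), hap(0)) for _ in range(10)]
    d1 = [(hap(1), hap(1)) for _ in range(10)]
    st = PopulationState(arch, dfe, [d0, d1], t)
    st._used_positions.update([100, 200])
    st.recompute_fitness()
    return st


class TestStepGeneration:
    def test_no_migration_keeps_private_alleles(self, small_arch, rng):
        dfe = DFESpec(mutation_rate_per_bp=0.0)
        st = two_deme_state(small_arch, dfe)
        for _ in range(5):
            step_generation(st, [10, 10], 0.0, rng)
        for ind in st.demes[0]:
            assert 1 not in ind[0] and 1 not in ind[1]
        for ind in st.demes[1]:
            assert 0 not in ind[0] and 0 not in ind[1]

    def test_migration_moves_alleles(self, small_arch, rng):
        dfe = DFESpec(mutation_rate_per_bp=0.0)
        st = two_deme_state(small_arch, dfe)
        for _ in range(10):
            step_generation(st, [10, 10], 0.3, rng)
        crossed = any(
            0 in ind[0] or 0 in ind[1] for ind in st.demes[1]
        ) or any(1 in ind[0] or 1 in ind[1] for ind in st.demes[0])
        assert crossed

    def test_exact_size_control(self, small_arch, rng):
        dfe = DFESpec(mutation_rate_per_bp=1e-6)
        st = initialize_equilibrium(small_arch, dfe, [8, 12], rng=rng,
                                    burn_in_generations=3)
        step_generation(st, [5, 17], 0.1, rng)
        assert st.deme_sizes == [5, 17]

    def test_lethal_recessive_never_survives_homozygous(self, small_arch, rng):
        """Offspring of lethal-allele carriers are never hom for the lethal."""
        t = table_from([100], [-1.0], [0.0], [DELETERIOUS])
        deme = [(hap(0), hap()) for _ in range(30)]  # every parent a carrier
        st = PopulationState(small_arch, DFESpec(mutation_rate_per_bp=0.0),
                             [deme], t)
        st._used_positions.add(100)
        st.recompute_fitness()
        for _ in range(3):
            step_generation(st, [30], 0.0, rng)
            for h0, h1 in st.demes[0]:
                assert not (0 in h0 and 0 in h1)

    def test_neutrality_conservation(self, small_arch):
        """Mean allele frequency is conserved by one neutral generation."""
        rng = np.random.default_rng(77)
        freqs = []
        for _ in range(400):
            t = table_from([100], [0.0], [0.5], [NEUTRAL])
            n = 50
            carriers = rng.choice(2 * n, n, replace=False)  # freq 0.5
            deme = []
            for i in range(n):
                deme.append((hap(0) if 2 * i in carriers else hap(),
                             hap(0) if 2 * i + 1 in carriers else hap()))
            st = PopulationState(small_arch, DFESpec(mutation_rate_per_bp=0.0),
                                 [deme], t)
            st.recompute_fitness()
            step_generation(st, [n], 0.0, rng, compact_every=0)
            freqs.append(st.allele_counts()[0] / (2 * n))
        se = np.std(freqs) / np.sqrt(len(freqs))
        assert abs(np.mean(freqs) - 0.5) < 4 * se + 1e-12

    def test_empty_deme_raises(self, small_arch, rng):
        st = PopulationState(small_arch, DFESpec(), [[]], MutationTable())
        with pytest.raises(SimulationError):
            step_generation(st, [5], 0.0, rng)


class TestInitialization:
    def test_zero_mutation_rate_gives_no_segregating_sites(self, small_arch, rng):
        dfe = DFESpec(mutation_rate_per_bp=0.0)
        st = initialize_equilibrium(small_arch, dfe, [20], mode="analytic", rng=rng)
        assert st.muts.n == 0

    def test_unknown_mode_rejected(self, small_arch, rng):
        with pytest.raises(ConfigurationError):
            initialize_equilibrium(small_arch, DFESpec(), [20], mode="bogus", rng=rng)

    def test_analytic_heterozygosity_matches_theta(self, small_arch, neutral_dfe):
        """Seeded equilibrium: mean per-site H ~ 4*N*mu over replicates."""
        rng = np.random.default_rng(5)
        n = 100
        theta = 4 * n * neutral_dfe.mutation_rate_per_bp
        h_vals = []
        for _ in range(25):
            st = initialize_equilibrium(small_arch, neutral_dfe, [n], rng=rng)
            gm = sample_individuals(st, 20, rng)
            h_vals.append((gm.genotypes == 1).sum() / (20 * small_arch.total_functional_length))
        se = np.std(h_vals) / np.sqrt(len(h_vals))
        assert abs(np.mean(h_vals) - theta) < max(3 * se, 0.1 * theta)

    def test_burn_in_mode_agrees_with_analytic_seed(self, small_arch, neutral_dfe):
        """Two initialization routes give consistent diversity (<5% apart
        would need huge replication; assert overlap within joint spread)."""
        rng = np.random.default_rng(9)
        n = 40

        def mean_h(mode, burn):
            vals = []
            for _ in range(12):
                st = initialize_equilibrium(small_arch, neutral_dfe, [n],
                                            mode=mode, rng=rng,
                                            burn_in_generations=burn)
                gm = sample_individuals(st, 20, rng)
                vals.append((gm.genotypes == 1).sum() / (20 * small_arch.total_functional_length))
            return np.mean(vals), np.std(vals) / np.sqrt(len(vals))

        h_a, se_a = mean_h("analytic", None)
        h_b, se_b = mean_h("burn_in", 10 * n)
        assert abs(h_a - h_b) < 3 * np.hypot(se_a, se_b) + 0.05 * max(h_a, h_b)

    def test_rescaled_expansion_reaches_nominal_size(self, small_arch, hot_dfe, rng):
        st = initialize_equilibrium(small_arch, hot_dfe, [100], rng=rng,
                                    rescale_lambda=10, burn_in_generations=20)
        assert st.n_individuals == 100
        assert st.rescale_lambda == 1.0
        # fitness rescaling dropped: s_fit equals the true s (clipped)
        assert np.allclose(st.muts.s_fit, np.clip(st.muts.s, -1, 0))


class TestSampling:
    def test_full_sample_reproduces_allele_counts(self, small_arch, hot_dfe, rng):
        st = initialize_equilibrium(small_arch, hot_dfe, [30], rng=rng,
                                    burn_in_generations=10)
        gm = sample_individuals(st, 30, rng)
        counts = st.allele_counts()
        seg = (counts > 0) & (counts < 60)
        expected = counts[seg]
        order = np.argsort(st.muts.position[seg], kind="stable")
        assert np.array_equal(gm.genotypes.sum(axis=0), expected[order])

    def test_monomorphic_population_gives_zero_sites(self, small_arch, rng):
        st = PopulationState.empty(small_arch, DFESpec(), [10])
        gm = sample_individuals(st, 5, rng)
        assert gm.n_sites == 0

    def test_oversampling_rejected(self, small_arch, rng):
        st = PopulationState.empty(small_arch, DFESpec(), [10])
        with pytest.raises(SimulationError):
            sample_individuals(st, 11, rng)

    def test_fixed_seed_is_bit_reproducible(self, small_arch, hot_dfe):
        def go():
            rng = np.random.default_rng(123)
            st = initialize_equilibrium(small_arch, hot_dfe, [20], rng=rng,
                                        burn_in_generations=15)
            return sample_individuals(st, 10, rng)

        a, b = go(), go()
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.positions, b.positions)


class TestGenotypeMatrix:
    def test_validation(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(np.zeros((2, 3), np.int8), np.array([5, 4, 6]))
        with pytest.raises(ValueError):
            GenotypeMatrix(np.zeros((2, 3), np.int8), np.array([1, 2]))

    def test_neutral_subset(self):
        gm = GenotypeMatrix(
            np.array([[1, 2, 0]], np.int8),
            np.array([1, 5, 9]),
            s=np.array([0.0, -0.1, 0.0]),
            h=np.array([0.5, 0.1, 0.5]),
            kind=np.array([0, 1, 0], np.uint8),
        )
        sub = gm.neutral_only()
        assert sub.positions.tolist() == [1, 9]


class TestRunScenario:
    def test_row_structure_and_determinism(self, small_arch, hot_dfe):
        scen = Scenario(n_anc=60, n_bot=24, n_demes=3, migration_rate=0.05)
        tl = Timeline()
        kwargs = dict(
            sample_size=8,
            replicates=2,
            burn_in_generations=5,
            bins=("historical", "modern"),
            compute_roh=False,
        )
        df1 = run_scenario(scen, tl, small_arch, hot_dfe, rng=42, **kwargs)
        df2 = run_scenario(scen, tl, small_arch, hot_dfe, rng=42, **kwargs)
        pd.testing.assert_frame_equal(df1, df2)
        assert len(df1) == 4  # 2 bins x 2 replicates
        hist = df1[df1["bin"] == "historical"]
        assert np.allclose(hist["pct_loss"], 0.0)

    def test_horizon_too_short_rejected(self, small_arch, hot_dfe):
        scen = Scenario(n_anc=60, n_bot=24, post_decline_generations=1)
        with pytest.raises(ConfigurationError):
            run_scenario(scen, Timeline(), small_arch, hot_dfe, replicates=1)
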