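"""Mutation, selection, population dynamics and the specificity assay."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import srb


class TestMutate:
    def test_zero_rate_is_identity(self, small_params, rng):
        P = srb.random_protein(small_params, 5, rng)
        assert np.array_equal(srb.mutate(P, 0.0, rng).epitopes, P.epitopes)

    def test_rate_one_changes_every_residue(self, small_params, rng):
        P = srb.random_protein(small_params, 5, rng)
        Q = srb.mutate(P, 1.0, rng)
        assert np.all(Q.epitopes != P.epitopes)

    def test_substitution_fraction_matches_rate(self, small_params):
        gen = srb.stream(9, "mut")
        P = srb.random_protein(small_params, 1000, gen)  # 1e4 residues
        eps = 0.05
        reps = 10
        changed = 0
        for _ in range(reps):
            changed += int((srb.mutate(P, eps, gen).epitopes != P.epitopes).sum())
        n = reps * P.epitopes.size
        se = np.sqrt(n * eps * (1 - eps))
        assert abs(changed - n * eps) < 4 * se

    def test_invalid_rate(self, small_params, rng):
        P = srb.random_protein(small_params, 2, rng)
        with pytest.raises(ValueError):
            srb.mutate(P, 1.5, rng)


class TestSurvivalProbability:
    def test_fermi_midpoint_and_saturation(self):
        assert srb.survival_probability(-3.0, -3.0, 1.0) == pytest.approx(0.5)
        assert srb.survival_probability(-1e4, 0.0, 1.0) == pytest.approx(1.0)
        assert srb.survival_probability(1e4, 0.0, 1.0) == pytest.approx(0.0)

    def test_one_width_above_threshold(self):
        assert srb.survival_probability(1.0, 0.0, 1.0) == pytest.approx(
            1.0 / (np.e + 1.0))

    @given(st.floats(-50, 50), st.floats(-50, 50), st.floats(0.1, 5))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_decreasing_in_energy(self, u, du, w):
        """Lower binding energy never hurts survival."""
        lo = srb.survival_probability(u, 0.0, w)
        hi = srb.survival_probability(u + abs(du), 0.0, w)
        assert hi <= lo + 1e-12

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            srb.survival_probability(0.0, 0.0, 0.0)


class TestEvolvePopulation:
    def test_no_mutation_keeps_energy_constant(self, small_params):
        evo = srb.EvolutionParams(mode="heterodimer", n_epitopes=5, ensemble_size=20,
                                  mutation_rate=0.0, generations=10, seed=1)
        traj = srb.evolve_population(small_params, evo)
        assert np.allclose(traj.mean_energy, traj.mean_energy[0])
        assert np.allclose(traj.min_energy, traj.mean_energy[0])

    def test_threshold_bookkeeping(self, small_params):
        """U0(t) equals the recorded pre-selection ensemble mean at t."""
        evo = srb.EvolutionParams(mode="homodimer", n_epitopes=5, ensemble_size=50,
                                  generations=25, seed=2)
        traj = srb.evolve_population(small_params, evo)
        assert np.array_equal(traj.threshold, traj.mean_energy)
        assert traj.survivors.min() >= 0
        assert traj.survivors.max() <= 50
        assert np.all(traj.min_energy <= traj.mean_energy)

    def test_selection_improves_affinity(self, small_params):
        evo = srb.EvolutionParams(mode="heterodimer", n_epitopes=10, ensemble_size=200,
                                  generations=150, seed=3)
        traj = srb.evolve_population(small_params, evo)
        assert traj.mean_energy[-1] < traj.mean_energy[0] - 2.0

    def test_trajectory_frame_and_reproducibility(self, small_params):
        evo = srb.EvolutionParams(mode="homodimer", n_epitopes=4, ensemble_size=20,
                                  generations=5, seed=4)
        a = srb.evolve_population(small_params, evo)
        b = srb.evolve_population(small_params, evo)
        assert np.array_equal(a.final_population_P, b.final_population_P)
        frame = a.to_frame()
        assert list(frame.columns) == ["generation", "U0", "mean_U", "min_U", "survivors"]
        assert len(frame) == 5

    @pytest.mark.parametrize("mode", ["homodimer", "heterodimer"])
    def test_incremental_energies_match_spectrum_route(self, small_params, mode):
        """The incrementally maintained per-member energies equal a full
        spectrum recomputation after many generations of mutation and
        resampling."""
        evo = srb.EvolutionParams(mode=mode, n_epitopes=7, ensemble_size=40,
                                  generations=40, seed=11)
        traj = srb.evolve_population(small_params, evo)
        mm = srb.build_motif_map(small_params)
        table = srb.CouplingTable(small_params, traj.coupling_seed, "lazy")
        for n in range(0, 40, 5):
            P = srb.Protein(traj.final_population_P[n], small_params)
            if mode == "homodimer":
                spec = srb.homodimer_spectrum(P, mm, table)
            else:
                B = srb.Protein(traj.final_population_B[n], small_params)
                spec = srb.complex_spectrum(P, B, mm, table)
            U_ref, _ = srb.complex_binding_energy(spec)
            assert traj.final_energies[n] == pytest.approx(U_ref, abs=1e-9)

    def test_large_motif_alphabet_uses_lazy_couplings(self):
        """xi = 7 at |A| = 4 implies |M| = 16384: far too many pairs to tabulate."""
        p = srb.ModelParams(4, 10, 7, master_seed=5)
        evo = srb.EvolutionParams(mode="heterodimer", n_epitopes=5, ensemble_size=30,
                                  generations=5, seed=5)
        traj = srb.evolve_population(p, evo)
        assert np.isfinite(traj.mean_energy).all()


class TestSpecificity:
    def test_unevolved_samples_match_nonspecific_law(self, small_params):
        """With zero generations both assay samples are nonspecific minima."""
        evo = srb.EvolutionParams(mode="heterodimer", n_epitopes=20, ensemble_size=2,
                                  generations=0, seed=6)
        trajs = [srb.evolve_population(
            srb.ModelParams(4, 10, 3, master_seed=100 + r), evo) for r in range(10)]
        evolved, rand = srb.specificity_assay(trajs, 5, seed=61)
        assert evolved.size == 10
        assert rand.size == 10 * 2 * 5
        ref = srb.sample_nonspecific_minima(
            srb.ModelParams(4, 10, 3, master_seed=7), 20, 20, 2000, seed=62)
        from scipy import stats

        assert stats.ks_2samp(evolved, ref).pvalue > 0.01
        assert stats.ks_2samp(rand, ref).pvalue > 0.01

    def test_homodimer_trajectories_rejected(self, small_params):
        evo = srb.EvolutionParams(mode="homodimer", n_epitopes=3, ensemble_size=5,
                                  generations=0, seed=8)
        traj = srb.evolve_population(small_params, evo)
        with pytest.raises(ValueError):
            srb.specificity_assay([traj], 2, seed=0)


class TestEvolvedCensus:
    def test_zero_generations_equals_random_census(self, small_params):
        evo = srb.EvolutionParams(mode="homodimer", n_epitopes=20, ensemble_size=2,
                                  generations=0, seed=9)
        census = srb.evolved_homodimer_census(small_params, evo, 30, seed=91)
        fr = census.fractions
        assert census.n_realizations == 30
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_requires_homodimer_mode(self, small_params):
        evo = srb.EvolutionParams(mode="heterodimer")
        with pytest.raises(ValueError):
            srb.evolved_homodimer_census(small_params, evo, 1, seed=0)
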