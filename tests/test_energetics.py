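"""Binding energies, spectra, interface classification and their invariants."""

import numpy as np
import pytest
from scipy import stats

import srb
from srb.energetics import Orientation, _best_heterodimer, _best_heterodimer_lazy, \
    _best_homodimer, _best_homodimer_lazy


def brute_force_energy(p, b, orientation, mm, table):
    """Term-by-term oracle: explicit python loop over contacts."""
    mp = [mm.encode_tuple(p[i:i + mm.params.xi]) for i in range(mm.params.l_prime)]
    mb = [mm.encode_tuple(b[i:i + mm.params.xi]) for i in range(mm.params.l_prime)]
    lp = mm.params.l_prime
    total = 0.0
    for i in range(lp):
        if orientation == Orientation.PARALLEL:
            total += table.coupling(mp[i], mb[i])
        else:
            total += table.coupling(mp[lp - 1 - i], mb[i])
    return total


class TestBindingEnergy:
    def test_single_contact_at_xi_equals_l(self):
        p = srb.ModelParams(4, 3, 3, master_seed=1)
        mm = srb.build_motif_map(p)
        table = srb.build_coupling_table(p, coupling_seed=2)
        a = np.array([1, 2, 3])
        b = np.array([0, 0, 1])
        u = srb.binding_energy(a, b, Orientation.PARALLEL, mm, table)
        assert u == pytest.approx(table.coupling(mm.encode_tuple(a), mm.encode_tuple(b)))

    def test_two_contact_hand_case(self):
        """l' = 2: parallel pairs (m1,m1'), (m2,m2'); antiparallel (m2,m1'), (m1,m2')."""
        p = srb.ModelParams(4, 3, 2, master_seed=1)
        mm = srb.build_motif_map(p)
        table = srb.build_coupling_table(p, coupling_seed=3)
        a = np.array([1, 2, 3])
        b = np.array([2, 0, 1])
        ma, mb = mm.encode(a), mm.encode(b)
        u_par = srb.binding_energy(a, b, Orientation.PARALLEL, mm, table)
        u_anti = srb.binding_energy(a, b, Orientation.ANTIPARALLEL, mm, table)
        assert u_par == pytest.approx(
            table.coupling(ma[0], mb[0]) + table.coupling(ma[1], mb[1]))
        assert u_anti == pytest.approx(
            table.coupling(ma[1], mb[0]) + table.coupling(ma[0], mb[1]))

    def test_exchange_symmetry_and_oracle(self, small_params):
        """u(p,b,o) = u(b,p,o), and both match the term-by-term oracle."""
        mm = srb.build_motif_map(small_params)
        table = srb.build_coupling_table(small_params, coupling_seed=4)
        gen = srb.stream(3, "pairs")
        for _ in range(50):
            a = srb.random_peptide(small_params, gen)
            b = srb.random_peptide(small_params, gen)
            for o in Orientation:
                u_ab = srb.binding_energy(a, b, o, mm, table)
                u_ba = srb.binding_energy(b, a, o, mm, table)
                assert u_ab == pytest.approx(u_ba)
                assert u_ab == pytest.approx(brute_force_energy(a, b, o, mm, table))

    def test_level_distribution_is_gaussian(self, amino_params):
        """P(u) over random peptide pairs is N(0, l' sigma_J^2) (KS < 0.01 at 1e5)."""
        levels = srb.heterodimer_level_samples(amino_params, 1, 1, 50_000, seed=9)
        u = levels.ravel()  # 1e5 oriented energies
        ks = stats.kstest(u, stats.norm(scale=np.sqrt(8)).cdf).statistic
        assert ks < 0.01


class TestSpectra:
    def test_heterodimer_level_count(self, small_universe):
        mm, table, P, B = small_universe
        spec = srb.complex_spectrum(P, B, mm, table)
        assert spec.n_levels == 2 * 20 * 20 == 800
        tiny = srb.complex_spectrum(
            srb.Protein(P.epitopes[:1], P.params), srb.Protein(B.epitopes[:1], B.params),
            mm, table)
        assert tiny.n_levels == 2

    def test_homodimer_level_count(self, small_universe):
        mm, table, P, _ = small_universe
        spec = srb.homodimer_spectrum(P, mm, table)
        assert spec.n_levels == 20 * 19 + 2 * 20 == 420
        cats = spec.category
        assert (cats == srb.Category.ANTIPARALLEL_ISOLOGOUS).sum() == 20
        assert (cats == srb.Category.PARALLEL_ISOLOGOUS).sum() == 20
        assert (cats == srb.Category.HETEROLOGOUS).sum() == 380
        one = srb.homodimer_spectrum(srb.Protein(P.epitopes[:1], P.params), mm, table)
        assert one.n_levels == 2
        assert set(one.category) <= {int(srb.Category.PARALLEL_ISOLOGOUS),
                                     int(srb.Category.ANTIPARALLEL_ISOLOGOUS)}

    def test_spectrum_matches_pairwise_recomputation(self, small_params):
        """Every level equals binding_energy on its own (i, j, orientation)."""
        mm = srb.build_motif_map(small_params)
        table = srb.build_coupling_table(small_params, coupling_seed=6)
        gen = srb.stream(4, "spec")
        P = srb.random_protein(small_params, 3, gen)
        B = srb.random_protein(small_params, 3, gen)
        for spec, right in [(srb.complex_spectrum(P, B, mm, table), B),
                            (srb.homodimer_spectrum(P, mm, table), P)]:
            for k in range(spec.n_levels):
                cfg = spec.config(k)
                u = srb.binding_energy(P.epitopes[cfg.epitope_i],
                                       right.epitopes[cfg.epitope_j],
                                       cfg.orientation, mm, table)
                assert spec.energies[k] == pytest.approx(u)

    def test_antiparallel_isologous_pairing(self, small_universe):
        """For even l', u_anti(p,p) is twice the sum over the first l'/2 pairs."""
        mm, table, P, _ = small_universe
        lp = P.params.l_prime
        for ep in P.epitopes[:5]:
            m = mm.encode(ep)
            expected = 2.0 * sum(
                table.coupling(m[lp - 1 - k], m[k]) for k in range(lp // 2))
            u = srb.binding_energy(ep, ep, Orientation.ANTIPARALLEL, mm, table)
            assert u == pytest.approx(expected)

    def test_argmin_and_tie_break(self, small_universe):
        mm, table, P, B = small_universe
        spec = srb.complex_spectrum(P, B, mm, table)
        U, cfg = srb.complex_binding_energy(spec)
        order = np.argsort(spec.energies, kind="stable")
        assert U == spec.energies[order[0]]
        # force an exact tie: duplicate the minimum at a later level
        e = spec.energies.copy()
        k = int(np.argmin(e))
        e[-1] = e[k]
        tied = srb.Spectrum(e, spec.epitope_i, spec.epitope_j,
                            spec.orientation, spec.category, spec.kind)
        _, cfg_tied = srb.complex_binding_energy(tied)
        assert (cfg_tied.epitope_i, cfg_tied.epitope_j, int(cfg_tied.orientation)) == (
            cfg.epitope_i, cfg.epitope_j, int(cfg.orientation))

    def test_classify_rejects_heterodimer(self, small_universe):
        mm, table, P, B = small_universe
        with pytest.raises(ValueError):
            srb.classify_interface(srb.complex_spectrum(P, B, mm, table))

    def test_tsv_round_trip(self, small_universe, tmp_path):
        import pandas as pd

        mm, table, P, _ = small_universe
        spec = srb.homodimer_spectrum(P, mm, table)
        path = tmp_path / "spectrum.tsv"
        spec.to_tsv(path)
        frame = pd.read_csv(path, sep="\t")
        assert list(frame.columns) == ["level_index", "energy", "epitope_i",
                                       "epitope_j", "orientation", "category"]
        assert np.allclose(frame["energy"], spec.energies)


class TestKernels:
    def test_kernels_match_spectrum_argmin(self, small_universe):
        """Jitted population kernels agree with the Spectrum route, including ties."""
        mm, table, P, B = small_universe
        J = table.dense()
        mp = np.ascontiguousarray(mm.encode(P.epitopes)[None])
        mb = np.ascontiguousarray(mm.encode(B.epitopes)[None])
        U, bi, bj, bo = _best_heterodimer(mp, mb, J)
        U_ref, cfg = srb.complex_binding_energy(srb.complex_spectrum(P, B, mm, table))
        assert U[0] == pytest.approx(U_ref, abs=1e-9)
        assert (bi[0], bj[0], bo[0]) == (cfg.epitope_i, cfg.epitope_j, int(cfg.orientation))
        U, bi, bj, bo = _best_homodimer(mp, J)
        U_ref, cfg = srb.complex_binding_energy(srb.homodimer_spectrum(P, mm, table))
        assert U[0] == pytest.approx(U_ref, abs=1e-9)
        assert (bi[0], bj[0], bo[0]) == (cfg.epitope_i, cfg.epitope_j, int(cfg.orientation))

    def test_lazy_kernels_match_dense(self, small_universe):
        mm, table, P, B = small_universe
        J = table.dense()
        mp = np.ascontiguousarray(mm.encode(P.epitopes)[None])
        mb = np.ascontiguousarray(mm.encode(B.epitopes)[None])
        args = (table.mixed_seed, table.params.n_motifs, table.params.sigma_J)
        assert _best_heterodimer_lazy(mp, mb, *args)[0][0] == pytest.approx(
            _best_heterodimer(mp, mb, J)[0][0], abs=1e-12)
        assert _best_homodimer_lazy(mp, *args)[0][0] == pytest.approx(
            _best_homodimer(mp, J)[0][0], abs=1e-12)


class TestIsologousVariance:
    def test_variance_doubling_even_l_prime(self, amino_params):
        """Var[u_anti(p,p)] / Var[u_par(p,p)] -> 2 for even l' (twice the variance)."""
        u_par, u_anti = srb.sample_isologous_energies(amino_params, 100_000, seed=21)
        assert u_anti.var(ddof=1) / u_par.var(ddof=1) == pytest.approx(2.0, abs=0.06)

    def test_odd_l_prime_variance(self):
        """For odd l' the middle contact pairs with itself once:
        Var[u_anti(p,p)] = (2 l' - 1) sigma_J^2."""
        params = srb.ModelParams(997, 7, 1, master_seed=4)  # l' = 7, huge alphabet
        u_par, u_anti = srb.sample_isologous_energies(params, 150_000, seed=22)
        lp = params.l_prime
        assert u_anti.var(ddof=1) == pytest.approx(2 * lp - 1, rel=0.03)
        assert u_par.var(ddof=1) == pytest.approx(lp, rel=0.03)
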