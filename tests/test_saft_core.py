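"""Unit and property tests for the equation-of-state layer."""

import math

import numpy as np
import pytest

from saftscreen import saft_core as sc
from saftscreen.saft_core import (ComponentModel, InvalidParameterError,
                                  InvalidStateError, MixtureSpec,
                                  SegmentParameters, binary_mixture,
                                  cross_parameters)

from conftest import random_toy_mixture


def liquid_like_rho(mix, T, eta=0.4):
    ws = sc.get_workspace(mix, T)
    return ws.rho_from_eta(eta, mix.x)


class TestCrossParameters:
    def test_identity(self):
        seg = SegmentParameters(0.02, 3.5, 300.0, 1000.0, 0.02, 1, 1)
        cr = cross_parameters(seg, seg, 0.0)
        assert cr.u_over_kB == pytest.approx(300.0)
        assert cr.sigma == pytest.approx(3.5)
        assert cr.epsHB_over_kB == pytest.approx(1000.0)
        assert cr.kappaHB == pytest.approx(0.02)

    def test_geometric_mean(self):
        a = SegmentParameters(0.02, 3.0, 100.0)
        b = SegmentParameters(0.02, 4.0, 400.0)
        assert cross_parameters(a, b, 0.0).u_over_kB == pytest.approx(200.0)

    def test_kij_correction(self):
        a = SegmentParameters(0.02, 3.0, 100.0)
        b = SegmentParameters(0.02, 4.0, 400.0)
        assert cross_parameters(a, b, 0.1).u_over_kB == pytest.approx(180.0)

    def test_negative_energy_rejected(self):
        a = SegmentParameters(0.02, 3.0, 100.0)
        with pytest.raises(InvalidParameterError):
            cross_parameters(a, a, 1.5)

    def test_induced_cross_association(self):
        donor = SegmentParameters(0.02, 3.5, 300.0, 1600.0, 0.02, 2, 2)
        induced = SegmentParameters(0.02, 3.5, 300.0, 0.0, 0.02, 0, 4)
        cr = cross_parameters(donor, induced, 0.0)
        assert cr.epsHB_over_kB == pytest.approx(800.0)
        assert cr.kappaHB == pytest.approx(0.02)


class TestAssociation:
    def test_no_sites_empty(self, sphere):
        mix = MixtureSpec((sphere,), (1.0,))
        rho = liquid_like_rho(mix, 300.0)
        assert sc.association_site_fractions(mix, 300.0, rho) == {}
        bd = sc.reduced_residual_helmholtz(mix, 300.0, rho)
        assert bd.assoc == 0.0

    def test_two_site_quadratic_oracle(self):
        """Symmetric donor-acceptor pair matches the closed-form root."""
        seg = SegmentParameters(0.02, 3.5, 300.0, 1500.0, 0.02, 1, 1)
        comp = ComponentModel("AB", 250.0, ((seg, 1.0),))
        mix = MixtureSpec((comp,), (1.0,))
        T = 350.0
        rho = liquid_like_rho(mix, T)
        ws = sc.get_workspace(mix, T)
        st = ws.evaluate(mix.x, rho)
        # mass action for one donor + one acceptor per molecule reduces to
        # the quadratic X = 1/(1 + rho*X*Delta); solve it in closed form
        frac = sc.association_site_fractions(mix, T, rho)
        X = list(frac.values())[0]
        delta = float(ws.assoc_K[0, 1]) * (
            1.0 / (1.0 - st.eta)
            + ws.assoc_q[0, 1] * 3.0 * _zeta(ws, mix.x, rho, 2)
            / (1.0 - st.eta) ** 2
            + ws.assoc_q[0, 1] ** 2 * 2.0
            * _zeta(ws, mix.x, rho, 2) ** 2 / (1.0 - st.eta) ** 3)
        x_closed = (-1.0 + math.sqrt(1.0 + 4.0 * rho * delta)) / (
            2.0 * rho * delta)
        assert X == pytest.approx(x_closed, rel=1e-10)

    def test_vanishing_energy_gives_unbonded(self):
        seg = SegmentParameters(0.02, 3.5, 300.0, 1e-10, 0.02, 1, 1)
        comp = ComponentModel("weak", 250.0, ((seg, 1.0),))
        mix = MixtureSpec((comp,), (1.0,))
        rho = liquid_like_rho(mix, 350.0)
        for X in sc.association_site_fractions(mix, 350.0, rho).values():
            assert X == pytest.approx(1.0, abs=1e-6)

    def test_bounds_and_sign(self, api_polymer_mix):
        rho = liquid_like_rho(api_polymer_mix, 360.0)
        fr = sc.association_site_fractions(api_polymer_mix, 360.0, rho)
        assert fr  # cross-association active
        for X in fr.values():
            assert 0.0 < X <= 1.0
        bd = sc.reduced_residual_helmholtz(api_polymer_mix, 360.0, rho)
        assert bd.assoc < 0.0


def _zeta(ws, x, rho, n):
    return math.pi / 6.0 * rho * float(ws.czeta[n] @ np.asarray(x))


class TestHelmholtz:
    def test_ideal_gas_limit(self, api_polymer_mix):
        rho_liq = liquid_like_rho(api_polymer_mix, 360.0)
        bd = sc.reduced_residual_helmholtz(api_polymer_mix, 360.0,
                                           rho_liq * 1e-12)
        assert abs(bd.hc) < 1e-8
        assert abs(bd.disp) < 1e-8
        assert abs(bd.assoc) < 1e-8
        assert abs(sc.compressibility_factor(
            api_polymer_mix, 360.0, rho_liq * 1e-12) - 1.0) < 1e-8

    def test_m1_reduces_to_hard_sphere(self, sphere):
        """For m = 1 the chain term vanishes; hc equals Carnahan-Starling."""
        mix = MixtureSpec((sphere,), (1.0,))
        ws = sc.get_workspace(mix, 300.0)
        rho = ws.rho_from_eta(0.35, mix.x)
        st = ws.evaluate(mix.x, rho)
        eta = st.eta
        a_cs = (4.0 * eta - 3.0 * eta ** 2) / (1.0 - eta) ** 2
        assert st.breakdown.hc == pytest.approx(a_cs, rel=1e-12)

    def test_degenerate_copolymer_equals_homopolymer(self):
        seg = SegmentParameters(0.03, 3.6, 260.0, 0.0, 0.02, 0, 3)
        homo = ComponentModel("H", 5000.0, ((seg, 1.0),), role="polymer")
        copo = ComponentModel("C", 5000.0, ((seg, 0.5), (seg, 0.5)),
                              role="polymer")
        T = 350.0
        mh = MixtureSpec((homo,), (1.0,))
        mct = MixtureSpec((copo,), (1.0,))
        rho = liquid_like_rho(mh, T)
        ah = sc.reduced_residual_helmholtz(mh, T, rho).total
        ac = sc.reduced_residual_helmholtz(mct, T, rho).total
        assert ac == pytest.approx(ah, rel=1e-12)
        zh = sc.compressibility_factor(mh, T, rho)
        zcp = sc.compressibility_factor(mct, T, rho)
        assert zcp == pytest.approx(zh, rel=1e-12)

    def test_breakdown_conservation(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            mix = random_toy_mixture(rng)
            T = float(rng.uniform(300.0, 450.0))
            rho = liquid_like_rho(mix, T, eta=float(rng.uniform(0.1, 0.5)))
            bd = sc.reduced_residual_helmholtz(mix, T, rho)
            assert bd.hc + bd.disp + bd.assoc == pytest.approx(bd.total,
                                                              abs=1e-10)

    def test_close_packing_rejected(self, api_polymer_mix):
        ws = sc.get_workspace(api_polymer_mix, 360.0)
        rho = ws.rho_from_eta(0.75, api_polymer_mix.x)
        with pytest.raises(InvalidStateError):
            sc.reduced_residual_helmholtz(api_polymer_mix, 360.0, rho)


class TestCompressibility:
    def test_fd_oracle_seeded_states(self):
        """Analytic Z against central differences of a_res in rho."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            mix = random_toy_mixture(rng)
            T = float(rng.uniform(300.0, 450.0))
            ws = sc.get_workspace(mix, T)
            rho = ws.rho_from_eta(float(rng.uniform(0.05, 0.55)), mix.x)
            Z = ws.evaluate(mix.x, rho).Z
            h = 1e-6 * rho
            ap = ws.evaluate(mix.x, rho + h).a_res
            am = ws.evaluate(mix.x, rho - h).a_res
            Z_fd = 1.0 + rho * (ap - am) / (2.0 * h)
            assert Z == pytest.approx(Z_fd, rel=1e-6)

    def test_z_continuous_increasing_near_liquid_root(self, api_polymer_mix):
        T = 360.0
        ws = sc.get_workspace(api_polymer_mix, T)
        rho0, eta0 = ws.solve_density(api_polymer_mix.x, 1e5, "liquid")
        etas = np.linspace(eta0 * 0.98, eta0 * 1.02, 15)
        zs = [ws.evaluate(api_polymer_mix.x,
                          ws.rho_from_eta(e, api_polymer_mix.x)).Z
              for e in etas]
        assert np.all(np.diff(zs) > 0)
        assert np.all(np.isfinite(zs))


class TestDensitySolver:
    def test_vapor_ideal_gas_closure(self, toy_api):
        mix = MixtureSpec((toy_api,), (1.0,))
        T, p = 400.0, 5.0
        rho, eta = sc.solve_density(mix, T, p, "vapor")
        rho_ig = p / (sc.K_BOLTZMANN * T * 1e30)
        assert rho == pytest.approx(rho_ig, rel=1e-3)

    def test_liquid_packing_bound(self, api_polymer_mix):
        rho, eta = sc.solve_density(api_polymer_mix, 360.0, 1e5, "liquid")
        assert 0.0 < eta < 0.74

    def test_pressure_round_trip(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            mix = random_toy_mixture(rng)
            T = float(rng.uniform(320.0, 440.0))
            p = float(rng.uniform(5e4, 5e5))
            rho, _ = sc.solve_density(mix, T, p, "liquid")
            assert sc.pressure(mix, T, rho) == pytest.approx(p, rel=1e-9)

    def test_no_root_signal(self, toy_api):
        mix = MixtureSpec((toy_api,), (1.0,))
        with pytest.raises(InvalidStateError):
            sc.solve_density(mix, 400.0, -10.0)


class TestFugacity:
    def test_ideal_gas_limit(self, api_polymer_mix):
        lnphi = sc.ln_fugacity_coefficients(api_polymer_mix, 400.0, 1e-6,
                                            "vapor")
        assert np.all(np.abs(lnphi) < 1e-6)

    def test_pure_limit_consistency(self, toy_api, toy_polymer_acceptor):
        mix = binary_mixture(toy_api, toy_polymer_acceptor, 1.0)
        lnphi_mix = sc.ln_fugacity_coefficients(mix, 390.0, 1e5)
        lnphi_pure = sc.pure_ln_phi_liquid(toy_api, 390.0, 1e5)
        assert lnphi_mix[0] == pytest.approx(lnphi_pure, abs=1e-8)

    def test_mole_number_oracle(self):
        """ln phi against finite differences of the total Helmholtz energy
        with respect to mole numbers at fixed T, V."""
        rng = np.random.default_rng(19)
        for _ in range(20):
            mix = random_toy_mixture(rng)
            T = float(rng.uniform(320.0, 440.0))
            ws = sc.get_workspace(mix, T)
            rho, _ = ws.solve_density(mix.x, 1e5, "liquid")
            lnphi = ws.ln_phi(mix.x, rho)
            st = ws.evaluate(mix.x, rho)
            V = 1.0 / rho

            def a_total(n):
                ntot = n.sum()
                return ntot * ws.evaluate(n / ntot, ntot / V).a_res

            for k in range(2):
                h = 1e-6
                npp = mix.x.copy()
                nmm = mix.x.copy()
                npp[k] += h
                nmm[k] -= h
                mu = (a_total(npp) - a_total(nmm)) / (2.0 * h)
                oracle = mu - math.log(st.Z)
                assert lnphi[k] == pytest.approx(oracle, rel=1e-6, abs=1e-6)

    def test_permutation_symmetry(self, toy_api, toy_polymer_acceptor):
        T, p = 380.0, 1e5
        mix = binary_mixture(toy_api, toy_polymer_acceptor, 0.35)
        rev = MixtureSpec((toy_polymer_acceptor, toy_api), (0.65, 0.35))
        a = sc.ln_fugacity_coefficients(mix, T, p)
        b = sc.ln_fugacity_coefficients(rev, T, p)
        assert a[0] == pytest.approx(b[1], rel=1e-10)
        assert a[1] == pytest.approx(b[0], rel=1e-10)


class TestActivityCoefficient:
    def test_pure_limit(self, toy_api, toy_polymer_acceptor):
        mix = binary_mixture(toy_api, toy_polymer_acceptor, 1.0)
        assert sc.activity_coefficient(mix, 0, 390.0, 1e5) == pytest.approx(
            1.0, abs=1e-8)

    def test_identical_components(self, toy_api):
        twin = ComponentModel("TWIN", toy_api.molar_mass, toy_api.segments,
                              role="API")
        for x in (0.2, 0.5, 0.8):
            mix = binary_mixture(toy_api, twin, x)
            assert sc.activity_coefficient(mix, 0, 380.0, 1e5) == \
                pytest.approx(1.0, abs=1e-6)

    def test_gibbs_duhem(self, toy_api, toy_polymer_acceptor):
        """sum_i x_i dln(gamma_i)/dx = 0 along the composition path."""
        T, p = 380.0, 1e5
        h = 1e-4
        for x in (0.25, 0.5, 0.75):
            lg = {}
            for s in (-1, 1):
                mix = binary_mixture(toy_api, toy_polymer_acceptor, x + s * h)
                lnphi = sc.ln_fugacity_coefficients(mix, T, p)
                lg[s] = lnphi - np.array([
                    sc.pure_ln_phi_liquid(toy_api, T, p),
                    sc.pure_ln_phi_liquid(toy_polymer_acceptor, T, p)])
            dlg = (lg[1] - lg[-1]) / (2.0 * h)
            resid = x * dlg[0] + (1.0 - x) * dlg[1]
            assert abs(resid) < 1e-5


class TestResidualState:
    def test_state_bundle_consistency(self, api_polymer_mix):
        st = sc.residual_state(api_polymer_mix, 380.0, 1e5, "liquid")
        assert 0.0 < st.eta < 0.74
        assert st.breakdown.total == pytest.approx(st.a_res_reduced,
                                                   abs=1e-12)
        p_back = st.Z * st.density * 1e30 * sc.K_BOLTZMANN * 380.0
        assert p_back == pytest.approx(1e5, rel=1e-9)
        assert st.ln_phi.shape == (2,)


class TestValidation:
    def test_sigma_positive(self):
        with pytest.raises(InvalidParameterError):
            SegmentParameters(0.02, -1.0, 300.0)

    def test_eps_requires_kappa(self):
        with pytest.raises(InvalidParameterError):
            SegmentParameters(0.02, 3.5, 300.0, 1000.0, 0.0)

    def test_mole_fraction_simplex(self, toy_api, toy_polymer_acceptor):
        with pytest.raises(InvalidParameterError):
            MixtureSpec((toy_api, toy_polymer_acceptor), (0.5, 0.6))

    def test_kij_symmetry_enforced(self, toy_api, toy_polymer_acceptor):
        with pytest.raises(InvalidParameterError):
            MixtureSpec((toy_api, toy_polymer_acceptor), (0.5, 0.5),
                        kij=((0.0, 0.1), (0.2, 0.0)))
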