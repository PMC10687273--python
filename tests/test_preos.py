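"""Peng-Robinson EoS: pure-solvent states, dilute-limit fugacity, and the
sublimation-pressure/molar-volume closures."""

import numpy as np
import pytest

import scsol as s
from _oracles import lnphi2_full_mixture

# Published correlation constants of the EoS model (sublimation pressure
# expression and molar-volume quadratic).
BETA, GAMMA, DSUB_DELTA = 23.310, -9127.5, -5.9988
K1, K2, K3 = 7.516e-4, -7.3793e-8, -7.8339e-11


class TestPureSolvent:
    def test_covolume_from_critical_constants(self):
        _, b1 = s.pr_ab_from_critical(s.CO2, 308.0)
        assert b1 == pytest.approx(2.666e-5, rel=1e-3)

    def test_alpha_is_one_at_critical_temperature(self):
        a_tc, _ = s.pr_ab_from_critical(s.CO2, 304.13)
        tc, pc, omega = s.CO2.require_critical()
        kappa = 0.37464 + 1.54226 * omega - 0.26992 * omega**2
        a_ref = 0.45724 * s.R**2 * tc**2 / (pc * 1e6)
        assert a_tc == pytest.approx(a_ref, rel=1e-12)

    def test_kappa_polynomial_at_zero_acentric_factor(self):
        neutral = s.SubstanceProperties(
            name="x", molar_mass=44.01, critical_temperature=304.13,
            critical_pressure=7.377, acentric_factor=0.0,
        )
        a0, _ = s.pr_ab_from_critical(neutral, 304.13 * 0.81)
        # alpha = (1 + 0.37464 (1 - 0.9))^2 when omega = 0 and sqrt(Tr) = 0.9
        alpha = (1 + 0.37464 * 0.1) ** 2
        a_ref = 0.45724 * s.R**2 * 304.13**2 / 7.377e6 * alpha
        assert a0 == pytest.approx(a_ref, rel=1e-12)

    def test_universal_critical_compressibility(self):
        a, b = s.pr_ab_from_critical(s.CO2, 304.13)
        st = s.pr_pure_solve(304.13, 7.377, a, b)
        # triple root at Zc = 0.3074; numerical root clustering at the
        # exact critical point dominates the tolerance
        assert st.Z1 == pytest.approx(0.3074, abs=0.02)

    def test_ideal_gas_limit(self):
        a, b = s.pr_ab_from_critical(s.CO2, 308.0)
        st = s.pr_pure_solve(308.0, 1e-3, a, b)
        assert abs(st.Z1 - 1.0) < 1e-3

    def test_supercritical_density_near_reference_value(self):
        # PR has a known density bias near the critical region; the NIST
        # value at 308 K / 12 MPa is 769 kg/m3
        a, b = s.pr_ab_from_critical(s.CO2, 308.0)
        st = s.pr_pure_solve(308.0, 12.0, a, b)
        rho = s.CO2.molar_mass / 1000.0 / st.V1
        assert abs(rho - 769.0) / 769.0 < 0.15

    def test_state_invariants(self):
        a, b = s.pr_ab_from_critical(s.CO2, 318.0)
        st = s.pr_pure_solve(318.0, 15.0, a, b)
        assert st.V1 > st.b1 > 0
        assert st.Z1 == pytest.approx(15.0e6 * st.V1 / (s.R * 318.0))


class TestDiluteFugacity:
    def test_zero_solute_constants_leave_log_volume_term(self):
        a, b = s.pr_ab_from_critical(s.CO2, 318.0)
        st = s.pr_pure_solve(318.0, 15.0, a, b)
        phi = s.fugacity_coeff_dilute(st, 318.0, 15.0, 0.0, 0.0)
        expected = -np.log(15.0e6 * (st.V1 - st.b1) / (s.R * 318.0))
        assert np.log(phi) == pytest.approx(expected, rel=1e-12)

    def test_dilute_limit_matches_full_mixture_oracle(self):
        # the dilute expression is the y2 -> 0 limit of the full
        # two-component PR formula; agreement at y2 = 1e-10 over random
        # solute constants
        rng = np.random.default_rng(42)
        for _ in range(25):
            T = rng.uniform(308.0, 338.0)
            P = rng.uniform(12.0, 27.0)
            a2 = rng.uniform(0.1, 10.0)
            b2 = rng.uniform(1e-5, 1e-3)
            a1, b1 = s.pr_ab_from_critical(s.CO2, T)
            st = s.pr_pure_solve(T, P, a1, b1)
            ln9 = np.log(s.fugacity_coeff_dilute(st, T, P, a2, b2))
            ln8 = lnphi2_full_mixture(T, P, 1e-10, a1, b1, a2, b2)
            assert abs(ln9 - ln8) < 1e-6

    def test_solvent_constants_recover_pure_solvent_coefficient(self):
        # with (a2, b2) = (a1, b1) the dilute formula must equal the full
        # mixture expression evaluated for an identical second component
        T, P = 318.0, 15.0
        a1, b1 = s.pr_ab_from_critical(s.CO2, T)
        st = s.pr_pure_solve(T, P, a1, b1)
        ln9 = np.log(s.fugacity_coeff_dilute(st, T, P, a1, b1))
        ln8 = lnphi2_full_mixture(T, P, 1e-10, a1, b1, a1, b1)
        assert abs(ln9 - ln8) < 1e-6

    def test_stronger_attraction_lowers_fugacity_coefficient(self):
        T, P = 318.0, 15.0
        a1, b1 = s.pr_ab_from_critical(s.CO2, T)
        st = s.pr_pure_solve(T, P, a1, b1)
        phis = [s.fugacity_coeff_dilute(st, T, P, a2, 3e-4) for a2 in (0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(phis) < 0)

    def test_negative_a2_rejected(self):
        a1, b1 = s.pr_ab_from_critical(s.CO2, 318.0)
        st = s.pr_pure_solve(318.0, 15.0, a1, b1)
        with pytest.raises(s.DomainError):
            s.fugacity_coeff_dilute(st, 318.0, 15.0, -1.0, 3e-4)


class TestClosures:
    def test_molar_volume_quadratic(self):
        assert s.solute_molar_volume(0.0, K1, K2, K3) == K1
        assert s.solute_molar_volume(769.0, K1, K2, K3) == pytest.approx(
            6.485e-4, rel=1e-3
        )
        # linear in each coefficient
        v = s.solute_molar_volume(500.0, 2 * K1, 2 * K2, 2 * K3)
        assert v == pytest.approx(2 * s.solute_molar_volume(500.0, K1, K2, K3))

    def test_sublimation_pressure_reference_temperature(self):
        # at 298.15 K the log term vanishes: R ln P = beta + gamma/298.15
        p = s.sublimation_pressure(298.15, BETA, GAMMA, DSUB_DELTA)
        assert np.log(p) * s.R == pytest.approx(BETA + GAMMA / 298.15, rel=1e-12)
        assert p == pytest.approx(0.4154, rel=1e-3)

    def test_sublimation_pressure_increasing_over_study_range(self):
        temps = np.linspace(308.0, 338.0, 7)
        p = s.sublimation_pressure(temps, BETA, GAMMA, DSUB_DELTA)
        assert np.all(np.diff(p) > 0)

    def test_sublimation_enthalpy_published_values(self):
        assert s.sublimation_enthalpy(308.0, GAMMA, DSUB_DELTA) / 1000 == pytest.approx(
            60.524, abs=0.01
        )
        temps = np.array([308.0, 318.0, 328.0, 338.0])
        avg = s.sublimation_enthalpy(temps, GAMMA, DSUB_DELTA).mean() / 1000
        assert avg == pytest.approx(59.776, abs=0.01)

    def test_sublimation_enthalpy_constant_without_delta(self):
        for T in (250.0, 300.0, 400.0):
            assert s.sublimation_enthalpy(T, GAMMA, 0.0) == pytest.approx(-GAMMA * s.R)

    def test_sublimation_enthalpy_decreasing_for_negative_delta(self):
        temps = np.array([308.0, 318.0, 328.0, 338.0])
        dh = s.sublimation_enthalpy(temps, GAMMA, DSUB_DELTA)
        assert np.all(np.diff(dh) < 0)


class TestEoSSolubility:
    def _params(self, **over):
        base = dict(a2=1.0, b2=3e-4, beta=BETA, gamma=GAMMA, dsub_delta=DSUB_DELTA,
                    K1=K1, K2=K2, K3=K3)
        base.update(over)
        return s.PREoSParams(**base)

    def test_linear_in_sublimation_pressure_at_fixed_closures(self):
        # with v2 = 0 the Poynting factor is 1 and shifting beta by R ln 2
        # exactly doubles the sublimation pressure, hence y2
        p1 = self._params(K1=0.0, K2=0.0, K3=0.0)
        p2 = self._params(K1=0.0, K2=0.0, K3=0.0, beta=BETA + s.R * np.log(2.0))
        y1 = s.eos_solubility(p1, s.CO2, 318.0, 15.0, 744.0)
        y2 = s.eos_solubility(p2, s.CO2, 318.0, 15.0, 744.0)
        assert y2 == pytest.approx(2.0 * y1, rel=1e-12)

    def test_vanishing_sublimation_pressure_gives_zero_solubility(self):
        p = self._params(beta=-3000.0)  # P_sub ~ exp(-400)
        y = s.eos_solubility(p, s.CO2, 318.0, 15.0, 744.0)
        assert y == pytest.approx(0.0, abs=1e-100)

    def test_composition_identity(self):
        # y2 * P * phi2 / P_sub must equal the Poynting factor
        p = self._params()
        T, P, rho = 318.0, 15.0, 744.0
        y = s.eos_solubility(p, s.CO2, T, P, rho)
        a1, b1 = s.pr_ab_from_critical(s.CO2, T)
        st = s.pr_pure_solve(T, P, a1, b1)
        phi = s.fugacity_coeff_dilute(st, T, P, p.a2, p.b2)
        psub = s.sublimation_pressure(T, p.beta, p.gamma, p.dsub_delta)
        v2 = s.solute_molar_volume(rho, p.K1, p.K2, p.K3)
        poynting = np.exp((P - psub) * 1e6 * v2 / (s.R * T))
        assert y * P * phi / psub == pytest.approx(poynting, rel=1e-10)

    def test_model_class_modes(self, codeine):
        m_crit = s.PengRobinson(codeine)
        m_fixed = s.PengRobinson(codeine, solvent_ab="fixed",
                                 fixed_ab=(0.39, 2.67e-5))
        theta = m_crit.start_params()
        y_crit = m_crit.predict_y2(theta)
        y_fixed = m_fixed.predict_y2(theta)
        assert np.all(np.isfinite(y_crit)) and np.all(np.isfinite(y_fixed))
        assert not np.allclose(y_crit, y_fixed)
        with pytest.raises(s.DomainError):
            s.PengRobinson(codeine, solvent_ab="fixed")
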