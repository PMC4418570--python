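"""Organism-level energy-budget model: rates, identities and integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from daniopond.deb import (
    DEBParams,
    DEBState,
    compound_parameters,
    effective_f,
    growth_rate,
    ingestion_reduction,
    length_mass,
    mass_length,
    reproduction_rate,
    reserve_rate,
    simulate_trajectory,
    step_deb,
    temperature_correction,
)


class TestTemperatureCorrection:
    @pytest.mark.parametrize(
        "T, expected",
        [
            (19.85, 1.0),        # reference temperature, 293 K
            (29.85, 1.4020),     # exp(3000·(1/293 − 1/303))
            (9.85, 0.6964),      # exp(3000·(1/293 − 1/283))
        ],
    )
    def test_reference_values(self, deb, T, expected):
        assert temperature_correction(T, deb) == pytest.approx(expected, abs=1e-4)

    def test_rejects_nonfinite_and_subzero(self, deb):
        with pytest.raises(ValueError):
            temperature_correction(float("nan"), deb)
        with pytest.raises(ValueError):
            temperature_correction(-300.0, deb)


class TestCompoundParameters:
    def test_zebrafish_values(self, comp):
        assert comp.g == pytest.approx(0.4268, abs=2e-4)
        assert comp.k_M == pytest.approx(0.18723, abs=1e-5)
        assert comp.L_inf == pytest.approx(37.55, abs=0.01)

    def test_identity_inputs(self):
        p = DEBParams(delta=1.0, p_Am=1.0, v_dot=1.0, p_M=1.0, E_G=1.0, kappa=1.0,
                      l_b=0.079, l_f=0.163, l_p=0.58)
        c = compound_parameters(p)
        assert (c.g, c.k_M, c.L_inf) == (1.0, 1.0, 1.0)

    def test_L_inf_is_L_m_over_delta(self, deb, comp):
        assert comp.L_inf == pytest.approx(comp.L_m / deb.delta)


class TestIngestionReduction:
    @pytest.mark.parametrize(
        "l, expected",
        [(0.163, 0.42), (0.079, 0.7541), (1.0, 0.00362)],
    )
    def test_values(self, deb, l, expected):
        assert ingestion_reduction(l, deb) == pytest.approx(expected, abs=1e-4)

    def test_rejects_nonpositive(self, deb):
        with pytest.raises(ValueError):
            ingestion_reduction(0.0, deb)

    @given(st.floats(min_value=0.01, max_value=1.5))
    @settings(deadline=None, derandomize=True)
    def test_strictly_decreasing_and_bounded(self, l):
        deb = DEBParams()
        s = ingestion_reduction(l, deb)
        assert 0.0 < s < deb.alpha
        assert ingestion_reduction(l * 1.05, deb) < s


class TestRates:
    def test_reserve_equilibrium(self, deb):
        l = 0.3
        f = 0.8
        e_star = (1.0 - ingestion_reduction(l, deb)) * f
        state = DEBState(e=e_star, l=l)
        assert reserve_rate(state, f, 19.85, deb) == pytest.approx(0.0, abs=1e-12)

    def test_reserve_rate_value(self, deb):
        state = DEBState(e=0.5, l=0.3)
        assert reserve_rate(state, 1.0, 19.85, deb) == pytest.approx(0.10225, abs=1e-4)

    def test_prefeeding_forces_f_zero(self, deb, comp):
        state = DEBState(e=0.4, l=0.05)  # below l_b
        expected = -comp.k_M * comp.g * 0.4 / 0.05
        assert reserve_rate(state, 1.0, 19.85, deb) == pytest.approx(expected)
        assert reserve_rate(state, 0.0, 19.85, deb) == pytest.approx(expected)

    def test_growth_equilibrium_and_values(self, deb):
        assert growth_rate(DEBState(e=0.5, l=0.5), 19.85, deb) == 0.0
        assert growth_rate(DEBState(e=1.0, l=0.5), 19.85, deb) == pytest.approx(
            0.009334, abs=1e-5
        )
        assert growth_rate(DEBState(e=0.5, l=0.3), 19.85, deb) == pytest.approx(
            0.005748, abs=2e-6
        )

    def test_reproduction_max_and_puberty_gate(self, deb):
        full = DEBState(e=1.0, l=1.0)
        assert reproduction_rate(full, 19.85, deb) == pytest.approx(deb.R_M, rel=1e-12)
        assert reproduction_rate(DEBState(e=1.0, l=0.5), 19.85, deb) == 0.0

    def test_reproduction_value(self, deb):
        state = DEBState(e=0.9, l=0.8)
        assert reproduction_rate(state, 19.85, deb) == pytest.approx(170.2, abs=0.1)


class TestEffectiveF:
    def test_zero_food(self, deb):
        assert effective_f(0.0, DEBState(is_male=True, past_puberty=True), 1.0, deb) == 0.0

    def test_male_appetite(self, deb):
        state = DEBState(is_male=True, past_puberty=True)
        assert effective_f(0.8, state, 1.0, deb) == pytest.approx(0.8 * 0.92)

    def test_female_unaffected(self, deb):
        state = DEBState(is_male=False, past_puberty=True)
        assert effective_f(0.8, state, 1.0, deb) == pytest.approx(0.8)

    def test_clamped_to_unit(self, deb):
        assert effective_f(0.9, DEBState(), 2.0, deb) == 1.0


class TestStepDeb:
    def test_fixed_point(self, deb):
        l_star = 0.5
        f = l_star / (1.0 - ingestion_reduction(l_star, deb))
        state = DEBState(e=l_star, l=l_star)
        out = step_deb(state, f, 19.85, dt=1.0, substeps=10, params=deb)
        assert out.e == pytest.approx(l_star, abs=1e-12)
        assert out.l == pytest.approx(l_star, abs=1e-12)

    def test_von_bertalanffy_closed_form(self):
        # with the ingestion reduction off and full reserves the model is
        # exactly von Bertalanffy: l(t) = 1 − (1 − l0)·exp(−r_B·t)
        deb = DEBParams(alpha=1e-12)
        comp = compound_parameters(deb)
        r_B = comp.k_M * comp.g / (3.0 * (1.0 + comp.g))
        state = DEBState(e=1.0, l=0.2)
        t = 0.0
        for _ in range(400):
            state = step_deb(state, 1.0, 19.85, dt=1.0, substeps=10, params=deb)
            t += 1.0
        expected = 1.0 - (1.0 - 0.2) * np.exp(-r_B * t)
        assert state.l == pytest.approx(expected, abs=1e-3)

    def test_matches_adaptive_oracle(self, deb, comp):
        # independent reference: adaptive RK45 on the same ODEs
        f, T = 0.8, 27.0
        cT = temperature_correction(T, deb)

        def rhs(t, y):
            e, l = y
            s_f = deb.alpha * (1.0 - 1.0 / (1.0 + (deb.l_f / l) ** 3))
            fe = 0.0 if l < deb.l_b else f
            de = cT * comp.k_M * comp.g / l * ((1.0 - s_f) * fe - e)
            r_B = cT * comp.k_M * comp.g / (3.0 * (e + comp.g))
            return [de, r_B * (e - l)]

        sol = solve_ivp(rhs, (0, 400), [1.0, deb.l_b], rtol=1e-10, atol=1e-12,
                        t_eval=np.arange(0, 401, 50.0))
        L_oracle = sol.y[1] * comp.L_inf
        L_euler, _ = simulate_trajectory(deb, f=f, T=T, days=np.arange(0, 401, 50.0))
        assert np.max(np.abs(L_euler - L_oracle)) < 0.1

    def test_euler_first_order_convergence(self, deb, comp):
        days = np.array([200.0])
        ref, _ = simulate_trajectory(deb, 0.8, 27.0, days, dt=0.003125)
        errs = []
        for dt in (0.4, 0.2, 0.1, 0.05):
            L, _ = simulate_trajectory(deb, 0.8, 27.0, days, dt=dt)
            errs.append(abs(L[0] - ref[0]))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders > 0.8) and np.all(orders < 1.5)

    def test_arrhenius_time_rescaling(self, deb):
        # simulating warm for t days equals reference-temperature dynamics
        # run for cT·t days: all rates carry the same factor
        cT = temperature_correction(29.85, deb)
        warm, _ = simulate_trajectory(deb, 0.9, 29.85, np.array([100.0]), dt=0.01)
        cold, _ = simulate_trajectory(deb, 0.9, 19.85, np.array([100.0 * cT]), dt=0.01)
        assert warm[0] == pytest.approx(cold[0], abs=0.05)

    def test_sigmoid_physical_growth(self, deb):
        # the ingestion reduction makes fully fed growth sigmoid: the daily
        # length increment first rises, then falls
        days = np.arange(0.0, 301.0)
        # start from the hatchling reserve equilibrium to avoid the initial
        # reserve transient masking the inflection
        L, _ = simulate_trajectory(deb, 1.0, 27.0, days, e0=0.25)
        dL = np.diff(L)
        peak = int(np.argmax(dL))
        assert 2 < peak < 250

    def test_nan_aborts(self, deb):
        with pytest.raises((FloatingPointError, ValueError)):
            step_deb(DEBState(e=np.nan, l=0.5), 1.0, 27.0, params=deb)


class TestAllometry:
    def test_reference_mass(self):
        assert length_mass(30.0) == pytest.approx(301.4, abs=0.2)

    def test_unit_mass_length(self):
        L = np.exp(5.193 / 3.205)
        assert length_mass(L) == pytest.approx(1.0, rel=1e-10)

    @given(st.floats(min_value=0.5, max_value=60.0))
    @settings(deadline=None, derandomize=True)
    def test_round_trip(self, L):
        assert mass_length(length_mass(L)) == pytest.approx(L, rel=1e-10)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            length_mass(0.0)
        with pytest.raises(ValueError):
            mass_length(-1.0)


class TestParamValidation:
    def test_rejects_bad_ordering(self):
        with pytest.raises(ValueError):
            DEBParams(l_b=0.2, l_f=0.1)

    def test_rejects_kappa_above_one(self):
        with pytest.raises(ValueError):
            DEBParams(kappa=1.5)
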