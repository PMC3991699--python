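"""Motif model right-hand sides, equilibria, conservation laws."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pulsemotif import (
    ABModel,
    BModel,
    DimerModel,
    GoldbeterKoshlandModel,
    InvalidStateError,
    ReceptorModel,
    b_model_mean,
    gk_steady_state_curve,
    hill,
    linear,
    make_pulse_train,
    numeric_periodic_mean,
    saturating,
)
from pulsemotif.models import ab_model_rhs, b_model_rhs, gk_half_activation_input


def _integrate(model, train, t_end, y0=None, rtol=1e-10, atol=1e-12):
    y0 = model.initial_state() if y0 is None else np.asarray(y0, float)
    return solve_ivp(lambda t, y: model.rhs(y, train(t)), (0.0, t_end), y0,
                     method="LSODA", rtol=rtol, atol=atol, dense_output=True,
                     max_step=train.duration)


class TestSingleAndTwoStage:
    @pytest.mark.parametrize("F,A,expected", [(saturating(1), 1.0, 0.5),
                                              (hill(1), 1.0, 0.5),
                                              (hill(1), 0.0, 0.0)])
    def test_b_equilibrium_is_F_of_input(self, F, A, expected):
        model = BModel(F=F)
        assert model.equilibrium(A)[0] == pytest.approx(expected)
        assert model.rhs(model.equilibrium(A), A)[0] == pytest.approx(0.0, abs=1e-15)

    def test_first_stage_has_unit_gain(self):
        model = ABModel(F=hill(1))
        a, b = model.equilibrium(2.5)
        assert a == pytest.approx(2.5)
        assert np.allclose(model.rhs(np.array([a, b]), 2.5), 0.0)

    def test_fast_first_stage_reduces_to_single_stage(self):
        """In the τ_a → 0 limit, a(t) tracks the input and the cascade's
        period mean collapses onto the single-stage closed form."""
        train = make_pulse_train(3, 10, 100)
        F = hill(1)
        fast = ABModel(F=F, tau_a=1e-4)
        assert fast.periodic_mean(train) == pytest.approx(
            b_model_mean(F, train), rel=1e-4)

    def test_functional_rhs_wrappers_use_signal(self, ref_train):
        model = BModel(F=linear(1))
        assert b_model_rhs(0.0, 5.0, ref_train, model) == pytest.approx(1.0)
        assert b_model_rhs(0.0, 50.0, ref_train, model) == pytest.approx(0.0)
        dab = ab_model_rhs([0.0, 0.0], 5.0, ref_train, ABModel(F=linear(1)))
        assert dab[0] == pytest.approx(1.0 / 10.0)


class TestReceptor:
    def test_equilibrium_under_constant_ligand(self):
        m = ReceptorModel()
        A = 1.0
        expected = m.k_on * A / (m.k_on * A + m.k_off)
        assert m.equilibrium(A)[0] == pytest.approx(expected)
        assert m.rhs(m.equilibrium(A), A)[0] == pytest.approx(0.0, abs=1e-15)

    def test_decay_without_ligand(self):
        m = ReceptorModel()
        sol = _integrate(m, make_pulse_train(1e-12, 1, 100), 200.0, y0=[0.8])
        t = 150.0
        assert sol.sol(t)[0] == pytest.approx(0.8 * np.exp(-m.k_off * t), rel=1e-6)

    def test_trajectory_matches_piecewise_exponential(self, ref_train):
        """The numeric trajectory under pulsed ligand must follow the analytic
        solution of the scalar linear ODE: relaxation toward the bound-state
        equilibrium at rate k_on·A + k_off during the pulse, pure exponential
        dissociation at k_off between pulses."""
        m = ReceptorModel()
        sol = _integrate(m, ref_train, 100.0)
        A, d = ref_train.amplitude, ref_train.duration
        r_on = m.k_on * A + m.k_off
        eq = m.k_on * A / r_on
        for t in np.linspace(0.5, 99.5, 40):
            if t < d:
                expected = eq * (1.0 - np.exp(-r_on * t))
            else:
                RL_d = eq * (1.0 - np.exp(-r_on * d))
                expected = RL_d * np.exp(-m.k_off * (t - d))
            assert sol.sol(t)[0] == pytest.approx(expected, abs=1e-8)

    def test_bound_fraction_stays_in_unit_interval(self, ref_train):
        m = ReceptorModel()
        sol = _integrate(m, ref_train, 500.0)
        assert np.all(sol.y >= -1e-9) and np.all(sol.y <= 1.0 + 1e-9)
        with pytest.raises(InvalidStateError):
            m.validate_state(np.array([1.5]))


class TestDimer:
    def test_dimer_equilibrium_ratio(self):
        """At steady state dD/dt = 0 forces D = (k_dim_on/k_dim_off)·RL²."""
        m = DimerModel()
        for L in (0.2, 1.0):
            RL, D = m.steady_state(L)
            assert D == pytest.approx(m.k_dim_on / m.k_dim_off * RL ** 2, rel=1e-12)
            assert np.allclose(m.rhs(np.array([RL, D]), L), 0.0, atol=1e-12)

    def test_zero_ligand_empties_all_pools(self):
        m = DimerModel()
        sol = _integrate(m, make_pulse_train(1e-12, 1, 100), 2000.0, y0=[0.05, 0.2])
        assert np.all(np.abs(sol.y[:, -1]) < 1e-3)

    def test_receptor_conservation_along_trajectory(self, ref_train):
        m = DimerModel()
        sol = _integrate(m, ref_train, 400.0)
        total_bound = sol.y[0] + 2.0 * sol.y[1]
        assert np.all(total_bound <= 1.0 + 1e-9)
        assert np.all(sol.y >= -1e-9)

    def test_steady_state_dimer_curve_is_sigmoidal(self):
        """One concavity switch of D(L) on (0, 1]: superlinear onset from the
        RL² mass-action term, saturation from receptor depletion."""
        m = DimerModel()
        L = np.linspace(1e-3, 1.0, 300)
        D = np.array([m.steady_state(x)[1] for x in L])
        assert np.all(np.diff(D) > 0)
        curv = np.diff(D, 2)
        changes = np.sum(np.diff(np.sign(curv[np.abs(curv) > 1e-12])) != 0)
        assert changes == 1

    def test_invalid_initial_state_rejected(self, ref_train):
        m = DimerModel()
        with pytest.raises(InvalidStateError):
            numeric_periodic_mean(m, ref_train, initial_state=[0.8, 0.4])


class TestGoldbeterKoshland:
    def test_zero_kinase_keeps_protein_dephosphorylated(self):
        m = GoldbeterKoshlandModel()
        sol = _integrate(m, make_pulse_train(0, 1, 100), 50.0)
        assert np.all(np.abs(sol.y) < 1e-9)

    def test_protein_conservation_along_trajectory(self):
        from pulsemotif import numeric_periodic_solution

        m = GoldbeterKoshlandModel()
        train = make_pulse_train(350, 10, 100)
        sol = numeric_periodic_solution(m, train)
        states = sol(np.linspace(0.0, train.period, 200, endpoint=False))
        W = m.W_T - states.sum(axis=0)
        assert np.all(W > -1e-5)
        assert np.all(states[1] <= m.E2_T + 1e-5)  # C2 cannot exceed phosphatase
        assert np.all(states >= -1e-5)

    def test_steady_state_curve_is_steep_sigmoid(self):
        """Zero-order ultrasensitivity: the phosphorylated fraction jumps from
        near 0 to near its ceiling within a narrow window around E2_T, and the
        curve is non-decreasing in the kinase input."""
        m = GoldbeterKoshlandModel()
        E1T = np.array([0.0, 10.0, 40.0, 50.0, 60.0, 100.0, 600.0])
        frac = gk_steady_state_curve(m, E1T)
        assert frac[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(np.diff(frac) >= -1e-9)
        assert frac[1] < 0.01          # well below threshold
        assert frac[-1] > 0.85         # saturated (complexes hold the rest)
        assert frac[4] - frac[2] > 0.5  # steep rise across E2_T

    def test_half_activation_sits_at_phosphatase_level(self):
        m = GoldbeterKoshlandModel()
        e_half = gk_half_activation_input(m)
        assert e_half == pytest.approx(m.E2_T, rel=0.05)

    def test_symmetric_input_balances_modification_cycle(self):
        """At E1T = E2_T with symmetric rates the fixed point has W* = W
        (the fraction is slightly below 1/2 because complexes hold protein)."""
        m = GoldbeterKoshlandModel()
        C1, C2, Wstar = m.steady_state(m.E2_T)
        W = m.W_T - Wstar - C1 - C2
        assert Wstar == pytest.approx(W, rel=1e-6)
        assert C1 == pytest.approx(C2, rel=1e-6)

    def test_kinetic_scale_is_a_time_rescaling(self):
        """Scaling all six rate constants by λ is equivalent to running the
        unit-λ cycle on a λ-compressed time axis: period means match when the
        input is stretched accordingly."""
        lam = 2.0
        train = make_pulse_train(350, 10, 100)
        stretched = make_pulse_train(350, 10 * lam, 100 * lam)
        fast = GoldbeterKoshlandModel(lam=lam)
        base = GoldbeterKoshlandModel()
        m_fast = numeric_periodic_mean(fast, train)["Wstar"]
        m_base = numeric_periodic_mean(base, stretched)["Wstar"]
        assert m_fast == pytest.approx(m_base, rel=1e-6)


class TestGlobalStability:
    @pytest.mark.parametrize(
        "model,y1",
        [
            (ReceptorModel(), [0.9]),
            (DimerModel(), [0.1, 0.3]),
            (BModel(F=hill(1)), [0.8]),
            (ABModel(F=hill(1)), [2.0, 0.9]),
        ],
    )
    def test_period_mean_independent_of_initial_condition(self, model, y1, ref_train):
        """Feedforward + periodic forcing → a unique attracting periodic
        solution: the asymptotic period mean cannot depend on where the
        trajectory starts."""
        from_zero = numeric_periodic_mean(model, ref_train)
        from_y1 = numeric_periodic_mean(model, ref_train, initial_state=y1)
        for name in model.state_names:
            assert from_zero[name] == pytest.approx(from_y1[name], rel=1e-6)
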