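"""Closed-form compartment PK against numerical ODE oracles and invariants."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pkpdsim.pk import (
    CompartmentPK,
    OneCompartmentParams,
    PKState,
    TwoCompartmentParams,
    apply_dose,
    step_one_compartment,
    step_two_compartment,
    two_compartment_propagator,
)


def ode_oracle_2c(params, c0, p0, dt):
    sol = solve_ivp(
        lambda t, y: params.generator() @ y,
        (0.0, dt),
        [c0, p0],
        rtol=1e-12,
        atol=1e-14,
        method="DOP853",
    )
    return sol.y[:, -1]


class TestOneCompartment:
    def test_zero_rate_is_identity(self):
        out = step_one_compartment(PKState(5.0), OneCompartmentParams(0.0), 100.0)
        assert out.circulation == 5.0
        assert out.time == 100.0

    def test_matches_exponential_decay(self):
        out = step_one_compartment(PKState(1.0), OneCompartmentParams(0.1), 10.0)
        assert out.circulation == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_zero_concentration_is_fixed_point(self):
        out = step_one_compartment(PKState(0.0), OneCompartmentParams(0.3), 42.0)
        assert out.circulation == 0.0

    def test_negative_dt_rejected(self):
        with pytest.raises(ValueError):
            step_one_compartment(PKState(1.0), OneCompartmentParams(0.1), -1.0)

    def test_monotone_decay_to_zero(self):
        state = PKState(3.0)
        params = OneCompartmentParams(0.05)
        prev = state.circulation
        for _ in range(200):
            state = step_one_compartment(state, params, 5.0)
            assert 0.0 <= state.circulation < prev
            prev = state.circulation
        assert state.circulation < 1e-12


class TestTwoCompartment:
    def test_zero_generator_identity(self):
        params = TwoCompartmentParams(0.0, 0.0, 0.0, 1.0)
        out = step_two_compartment(PKState(2.0, 3.0), params, 50.0)
        assert out.circulation == pytest.approx(2.0, rel=1e-14)
        assert out.periphery == pytest.approx(3.0, rel=1e-14)

    def test_conservation_without_elimination(self):
        params = TwoCompartmentParams(0.0, 0.5, 0.2, 2.0)
        state = PKState(1.0, 0.25)
        invariant = state.circulation + state.periphery / 2.0
        out = step_two_compartment(state, params, 37.0)
        assert out.circulation + out.periphery / 2.0 == pytest.approx(
            invariant, rel=1e-12
        )

    def test_matches_ode_oracle(self):
        params = TwoCompartmentParams(0.05, 0.5, 0.2, 2.0)
        out = step_two_compartment(PKState(1.0, 0.0), params, 30.0)
        ref = ode_oracle_2c(params, 1.0, 0.0, 30.0)
        assert out.circulation == pytest.approx(ref[0], rel=1e-8)
        assert out.periphery == pytest.approx(ref[1], rel=1e-8)

    def test_oracle_over_random_draws(self, rng):
        for _ in range(50):
            params = TwoCompartmentParams(
                rng.uniform(0, 0.1),
                rng.uniform(0, 0.1),
                rng.uniform(0, 0.1),
                rng.uniform(0.2, 5.0),
            )
            c0, p0 = rng.uniform(0, 10, 2)
            for dt in (0.01, 1.0, 60.0):
                out = step_two_compartment(PKState(c0, p0), params, dt)
                ref = ode_oracle_2c(params, c0, p0, dt)
                assert np.allclose(
                    [out.circulation, out.periphery], ref, rtol=1e-8, atol=1e-12
                )

    def test_repeated_eigenvalue_branch_is_continuous(self):
        # k12 = k21 = 0 with lam = 0 gives a doubly-degenerate zero eigenvalue
        degenerate = TwoCompartmentParams(0.0, 0.0, 0.0, 1.0)
        nearby = TwoCompartmentParams(1e-9, 1e-9, 0.0, 1.0)
        out_d = step_two_compartment(PKState(1.0, 1.0), degenerate, 10.0)
        out_n = step_two_compartment(PKState(1.0, 1.0), nearby, 10.0)
        assert out_d.circulation == pytest.approx(out_n.circulation, abs=1e-6)

    def test_invalid_volume_ratio(self):
        with pytest.raises(ValueError):
            TwoCompartmentParams(0.1, 0.1, 0.1, 0.0)

    def test_total_mass_nonincreasing_with_elimination(self):
        params = TwoCompartmentParams(0.01, 0.3, 0.1, 1.5)
        state = PKState(5.0, 0.0)
        prev = state.circulation + state.periphery / params.volume_ratio
        for _ in range(100):
            state = step_two_compartment(state, params, 10.0)
            total = state.circulation + state.periphery / params.volume_ratio
            assert total <= prev + 1e-12
            prev = total

    def test_precomputed_propagator_bit_identical(self):
        params = TwoCompartmentParams(0.02, 0.3, 0.15, 2.0)
        prop = two_compartment_propagator(params, 0.5)
        a = PKState(4.0, 1.0)
        b = PKState(4.0, 1.0)
        for _ in range(1000):
            a = step_two_compartment(a, params, 0.5, propagator=prop)
            b = step_two_compartment(b, params, 0.5)
        assert a.circulation == b.circulation
        assert a.periphery == b.periphery

    def test_biphasic_elimination_slopes(self):
        # with well-separated eigenvalues the log-concentration after a bolus
        # decays at the fast rate early and the slow rate late
        params = TwoCompartmentParams(0.1, 0.05, 0.001, 1.0)
        eigs = np.linalg.eigvals(params.generator())
        fast, slow = sorted(-eigs, reverse=True)
        state = PKState(1.0, 0.0)
        times, concs = [0.0], [1.0]
        for _ in range(6000):
            state = step_two_compartment(state, params, 1.0)
            times.append(state.time)
            concs.append(state.circulation)
        logc = np.log(concs)
        early = -(logc[5] - logc[1]) / 4.0
        late = -(logc[-1] - logc[-500]) / 499.0
        assert early == pytest.approx(fast, rel=0.15)
        assert late == pytest.approx(slow, rel=0.05)
        assert fast / slow > 10


class TestDosing:
    def test_bolus_adds_to_circulation(self):
        assert apply_dose(PKState(0.0), 10.0).circulation == 10.0
        assert apply_dose(PKState(3.0), 0.0).circulation == 3.0

    def test_two_boluses_are_additive(self):
        state = apply_dose(apply_dose(PKState(1.0), 5.0), 5.0)
        assert state.circulation == 11.0

    def test_negative_amount_rejected(self):
        with pytest.raises(ValueError):
            apply_dose(PKState(1.0), -1.0)


def test_compartment_pk_wrapper_matches_functional_path():
    params = TwoCompartmentParams(0.01, 0.2, 0.1, 1.5)
    wrapper = CompartmentPK(params)
    wrapper.dose(10.0)
    state = apply_dose(PKState(0.0, 0.0), 10.0)
    for _ in range(100):
        wrapper.step(0.1)
        state = step_two_compartment(state, params, 0.1)
    assert wrapper.circulation == state.circulation
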