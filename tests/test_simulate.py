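"""Occupancy propagation: conservation, analytic limits, oracle agreement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rho1kin import (
    ConcentrationProtocol,
    GatingScheme,
    ProtocolError,
    simulate,
    steady_state,
)

from conftest import max_oracle_difference, ode_simulate, random_protocol, random_scheme


def test_resting_receptor_stays_at_rest(wt_like_scheme):
    protocol = ConcentrationProtocol(segments=((5.0, 0.0),), dt=0.01)
    trace = simulate(wt_like_scheme, protocol)
    np.testing.assert_allclose(trace.occupancy[:, 0], 1.0, atol=1e-12)
    np.testing.assert_allclose(trace.p_open, 0.0, atol=1e-12)


def test_two_state_relaxation_matches_analytic_solution(two_state_scheme):
    conc = 2e-6
    k_on, k_off = two_state_scheme.k1 * conc, two_state_scheme.k_minus1
    ss = k_on / (k_on + k_off)
    protocol = ConcentrationProtocol(segments=((3.0, conc),), dt=0.001)
    trace = simulate(two_state_scheme, protocol)
    expected = ss * (1.0 - np.exp(-(k_on + k_off) * trace.time))
    np.testing.assert_allclose(trace.occupancy[:, 1], expected, atol=1e-10)


def test_two_state_relaxation_rate_recovered_by_fit(two_state_scheme):
    """Fitting a mono-exponential to the simulated rise recovers k1[A]+k_minus1."""
    from scipy.optimize import curve_fit

    conc = 2e-6
    expected_rate = two_state_scheme.k1 * conc + two_state_scheme.k_minus1
    protocol = ConcentrationProtocol(segments=((3.0, conc),), dt=0.001)
    trace = simulate(two_state_scheme, protocol)
    popt, _ = curve_fit(
        lambda t, a, r: a * (1 - np.exp(-r * t)),
        trace.time, trace.occupancy[:, 1], p0=[0.5, 1.0],
    )
    assert popt[1] == pytest.approx(expected_rate, rel=1e-3)


def test_matches_independent_stiff_ode_integration():
    """Matrix-exponential propagation vs LSODA on random schemes/protocols."""
    assert max_oracle_difference(n_pairs=10, seed=42) <= 1e-6


def test_occupancy_conservation_on_random_protocols():
    rng = np.random.default_rng(11)
    for _ in range(20):
        trace = simulate(random_scheme(rng), random_protocol(rng))
        assert np.max(np.abs(trace.occupancy.sum(axis=1) - 1.0)) < 1e-8
        assert trace.occupancy.min() > -1e-10
        assert trace.occupancy.max() < 1.0 + 1e-10


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    log_rates=st.lists(st.floats(min_value=-2, max_value=3), min_size=9, max_size=9),
    log_k1=st.floats(min_value=5, max_value=8),
    log_conc=st.floats(min_value=-8, max_value=-3),
)
def test_conservation_and_bounds_property(log_rates, log_k1, log_conc):
    """Occupancies stay a probability vector for arbitrary rate combinations."""
    names = ["k_minus1", "f1", "f_minus1", "beta", "alpha",
             "dAF_on", "dAF_off", "dAO_on", "dAO_off"]
    scheme = GatingScheme(k1=10 ** log_k1, **{n: 10 ** v for n, v in zip(names, log_rates)})
    protocol = ConcentrationProtocol(segments=((0.5, 10 ** log_conc), (0.5, 0.0)), dt=0.01)
    trace = simulate(scheme, protocol)
    assert np.max(np.abs(trace.occupancy.sum(axis=1) - 1.0)) < 1e-8
    assert np.all(trace.occupancy > -1e-10)
    assert np.all(trace.p_open == trace.occupancy[:, 3])


def test_segment_boundaries_not_duplicated(wt_like_scheme):
    protocol = ConcentrationProtocol(segments=((1.0, 0.0), (2.0, 1e-6), (1.0, 0.0)), dt=0.1)
    trace = simulate(wt_like_scheme, protocol)
    assert np.all(np.diff(trace.time) > 0)
    np.testing.assert_allclose(np.diff(trace.time), 0.1, atol=1e-9)
    assert trace.time[0] == 0.0
    assert trace.time[-1] == pytest.approx(4.0)
    assert len(trace.time) == 41


def test_equilibrium_initial_condition_is_stationary(wt_like_scheme):
    conc = 1e-5
    protocol = ConcentrationProtocol(
        segments=((10.0, conc),), dt=0.01, initial_condition="equilibrium"
    )
    trace = simulate(wt_like_scheme, protocol)
    pi = steady_state(wt_like_scheme, conc)
    assert np.max(np.abs(trace.occupancy - pi)) < 1e-9


def test_explicit_initial_occupancy_vector(two_state_scheme):
    p0 = (0.0, 1.0, 0.0, 0.0, 0.0, 0.0)
    protocol = ConcentrationProtocol(segments=((5.0, 0.0),), dt=0.01, initial_condition=p0)
    trace = simulate(two_state_scheme, protocol)
    np.testing.assert_allclose(trace.occupancy[0], p0, atol=1e-12)
    # unbinds at k_minus1 = 1/s: occupancy of R after 5 s is 1 - e^-5
    assert trace.occupancy[-1, 0] == pytest.approx(1 - np.exp(-5.0), abs=1e-9)


@pytest.mark.parametrize(
    "segments, dt",
    [(((0.05, 1e-6),), 0.1),  # dt longer than the segment
     ((), 0.01),  # no segments
     (((1.0, -1e-6),), 0.01),  # negative concentration
     (((-1.0, 1e-6),), 0.01)],  # negative duration
)
def test_invalid_protocols_rejected(segments, dt):
    with pytest.raises(ProtocolError):
        ConcentrationProtocol(segments=segments, dt=dt)


def test_oracle_helper_agrees_with_itself(two_state_scheme):
    """The ODE oracle reproduces the analytic two-state solution."""
    conc = 2e-6
    protocol = ConcentrationProtocol(segments=((1.0, conc),), dt=0.01)
    occ = ode_simulate(two_state_scheme, protocol)
    k_on, k_off = two_state_scheme.k1 * conc, two_state_scheme.k_minus1
    times = simulate(two_state_scheme, protocol).time
    expected = (k_on / (k_on + k_off)) * (1 - np.exp(-(k_on + k_off) * times))
    np.testing.assert_allclose(occ[:, 1], expected, atol=1e-8)
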