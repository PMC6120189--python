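"""Peak response, desensitization extent, deactivation convention, model CRC."""

import numpy as np
import pytest

from rho1kin import (
    ConcentrationProtocol,
    GatingScheme,
    MetricsError,
    OccupancyTrace,
    crc_from_model,
    desensitization_extent,
    extract_deactivation,
    fit_hill_activation,
    peak_response,
    simulate,
)


def make_trace(time, p_open):
    occ = np.zeros((len(time), 6))
    occ[:, 3] = p_open
    occ[:, 0] = 1.0 - p_open
    return OccupancyTrace(time=np.asarray(time, float), occupancy=occ)


def test_peak_of_constant_trace_is_window_start():
    t = np.arange(0, 10, 0.01)
    trace = make_trace(t, np.full(t.shape, 0.3))
    value, t_peak = peak_response(trace, (2.0, 8.0))
    assert value == pytest.approx(0.3)
    assert t_peak == pytest.approx(2.0)


def test_peak_of_constructed_biexponential_curve():
    # p(t) = a(e^{-t/tau2} - e^{-t/tau1}) peaks at t* = log(tau1/tau2)... with
    # tau_rise=0.5, tau_decay=5: t* = ln(10)*0.5/(1-0.1) analytic below
    tau_r, tau_d = 0.5, 5.0
    t = np.arange(0, 30, 0.001)
    curve = np.exp(-t / tau_d) - np.exp(-t / tau_r)
    t_star = np.log(tau_d / tau_r) * tau_r * tau_d / (tau_d - tau_r)
    p_max = np.exp(-t_star / tau_d) - np.exp(-t_star / tau_r)
    scale = 0.8 / p_max  # analytic max rescaled to 0.8
    trace = make_trace(t, scale * curve)
    value, t_peak = peak_response(trace, (0.0, 30.0))
    assert value == pytest.approx(0.8, abs=1e-6)
    assert t_peak == pytest.approx(t_star, abs=0.002)


def test_peak_of_monotone_decay_is_window_start():
    t = np.arange(0, 5, 0.01)
    trace = make_trace(t, 0.9 * np.exp(-t))
    value, t_peak = peak_response(trace, (1.0, 4.0))
    assert t_peak == pytest.approx(1.0)
    assert value == pytest.approx(0.9 * np.exp(-1.0), rel=1e-6)


def test_peak_empty_window_rejected():
    t = np.arange(0, 5, 0.01)
    trace = make_trace(t, np.full(t.shape, 0.1))
    with pytest.raises(MetricsError):
        peak_response(trace, (10.0, 20.0))


def test_desensitization_extent_arithmetic():
    t = np.arange(0, 60.01, 0.01)
    p = np.where(t < 1.0, 0.8 * t, 0.8)  # rise to peak 0.8
    p = np.where(t > 30, 0.2, p)  # settle at residual 0.2
    trace = make_trace(t, p)
    assert desensitization_extent(trace, 0.0, 60.0) == pytest.approx(75.0)


def test_desensitization_zero_when_residual_equals_peak():
    t = np.arange(0, 60.01, 0.01)
    trace = make_trace(t, np.full(t.shape, 0.4))
    assert desensitization_extent(trace, 0.0, 60.0) == pytest.approx(0.0)


def test_no_desensitized_states_means_no_desensitization(wt_like_scheme):
    scheme = wt_like_scheme.with_rates(dAF_on=0.0, dAO_on=0.0)
    protocol = ConcentrationProtocol(segments=((60.0, 1e-3),), dt=0.01)
    trace = simulate(scheme, protocol)
    assert desensitization_extent(trace, 0.0, 60.0) == pytest.approx(0.0, abs=0.5)


def test_desensitization_invariant_to_uniform_scaling():
    t = np.arange(0, 60.01, 0.01)
    p = 0.8 * np.exp(-t / 20.0) + 0.1
    a = desensitization_extent(make_trace(t, p), 0.0, 60.0)
    b = desensitization_extent(make_trace(t, 0.31 * p), 0.0, 60.0)
    assert a == pytest.approx(b, rel=1e-12)


def test_desensitization_zero_peak_rejected():
    t = np.arange(0, 60.01, 0.01)
    trace = make_trace(t, np.zeros(t.shape))
    with pytest.raises(MetricsError):
        desensitization_extent(trace, 0.0, 60.0)


def test_extract_deactivation_starts_at_minus_100_and_scales():
    t = np.arange(0, 10, 0.01)
    p = np.where(t < 5.0, 0.4, 0.4 * np.exp(-(t - 5.0)))
    seg = extract_deactivation(make_trace(t, p), 5.0)
    assert seg.percent_current[0] == pytest.approx(-100.0)
    assert seg.time[0] == 0.0
    # halving p_open corresponds to -50 percent
    k = int(np.argmin(np.abs(seg.time - np.log(2.0))))
    assert seg.percent_current[k] == pytest.approx(-50.0, abs=0.5)


def test_extract_deactivation_amplitude_invariance():
    t = np.arange(0, 10, 0.01)
    decay = np.where(t < 5.0, 1.0, np.exp(-(t - 5.0) / 2.0))
    seg_hi = extract_deactivation(make_trace(t, 0.8 * decay), 5.0)
    seg_lo = extract_deactivation(make_trace(t, 0.008 * decay), 5.0)
    np.testing.assert_allclose(seg_hi.percent_current, seg_lo.percent_current, atol=1e-9)


def test_extract_deactivation_roundtrip_recovers_tau():
    from rho1kin import fit_biexponential

    t = np.arange(0, 20.001, 0.01)
    p = np.where(t < 2.0, 0.5, 0.5 * np.exp(-(t - 2.0) / 2.0))
    seg = extract_deactivation(make_trace(t, p), 2.0)
    fit = fit_biexponential(seg)
    assert fit.weighted_tau == pytest.approx(2.0, rel=1e-6)


def test_extract_deactivation_zero_current_rejected():
    t = np.arange(0, 10, 0.01)
    trace = make_trace(t, np.zeros(t.shape))
    with pytest.raises(MetricsError):
        extract_deactivation(trace, 5.0)


def test_crc_responses_normalized_and_monotone_without_desensitization(
    binding_limited_scheme,
):
    conc = np.logspace(-7, -3, 9)
    crc = crc_from_model(binding_limited_scheme, conc, application_duration=5.0, dt=0.01)
    assert crc.responses.max() == pytest.approx(1.0)
    assert np.all(np.diff(crc.responses) >= -1e-12)


def test_binding_limited_ec50_approaches_kd(binding_limited_scheme):
    # weak gating: peak occupancy tracks binding, EC50 -> k_minus1/k1 = 10 uM
    kd = binding_limited_scheme.k_minus1 / binding_limited_scheme.k1
    conc = np.logspace(-7, -3, 13)
    crc = crc_from_model(binding_limited_scheme, conc, application_duration=30.0, dt=0.01)
    fit = fit_hill_activation(crc)
    assert fit.half_max == pytest.approx(kd, rel=0.05)


def test_crc_grid_refinement_leaves_ec50_unchanged(binding_limited_scheme):
    coarse = np.logspace(-7, -3, 9)
    fine = np.logspace(-7, -3, 17)  # doubles every grid interval
    ec50_coarse = fit_hill_activation(
        crc_from_model(binding_limited_scheme, coarse, 10.0, dt=0.01)
    ).half_max
    ec50_fine = fit_hill_activation(
        crc_from_model(binding_limited_scheme, fine, 10.0, dt=0.01)
    ).half_max
    assert ec50_fine == pytest.approx(ec50_coarse, rel=0.01)


def test_crc_monotone_in_concentration_over_random_desensitization_free_schemes():
    rng = np.random.default_rng(5)
    for _ in range(5):
        rates = {name: 10 ** rng.uniform(-1, 2) for name in
                 ("k_minus1", "f1", "f_minus1", "beta", "alpha")}
        scheme = GatingScheme(k1=10 ** rng.uniform(5, 7), dAF_on=0, dAF_off=1,
                              dAO_on=0, dAO_off=1, **rates)
        crc = crc_from_model(scheme, np.logspace(-7, -3, 9), 5.0, dt=0.01)
        assert np.all(np.diff(crc.responses) >= -1e-9)
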