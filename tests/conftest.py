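"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from rho1kin import (
    ConcentrationProtocol,
    GatingScheme,
    build_generator,
    simulate,
)
from rho1kin.scheme import RATE_NAMES


@pytest.fixture
def wt_like_scheme() -> GatingScheme:
    """A plausible WT-like parameter set: seconds-scale desensitization and
    deactivation, micromolar potency."""
    return GatingScheme(
        k1=5e5, k_minus1=1.5, f1=100.0, f_minus1=50.0, beta=100.0, alpha=20.0,
        dAF_on=0.02, dAF_off=0.02, dAO_on=0.05, dAO_off=0.02,
    )


@pytest.fixture
def two_state_scheme() -> GatingScheme:
    """Pure binding: every rate beyond R <-> AR is zero."""
    return GatingScheme(
        k1=1e6, k_minus1=1.0, f1=0.0, f_minus1=1.0, beta=0.0, alpha=1.0,
        dAF_on=0.0, dAF_off=1.0, dAO_on=0.0, dAO_off=1.0,
    )


@pytest.fixture
def binding_limited_scheme() -> GatingScheme:
    """Weak gating: occupancy-limited activation, EC50 -> k_minus1/k1."""
    return GatingScheme(
        k1=1e6, k_minus1=10.0, f1=1.0, f_minus1=1000.0, beta=1.0, alpha=1000.0,
        dAF_on=0.0, dAF_off=1.0, dAO_on=0.0, dAO_off=1.0,
    )


def random_scheme(rng: np.random.Generator) -> GatingScheme:
    """Log-uniform random rates: k1 in [1e5, 1e8] /M/s, others in [1e-2, 1e3] /s."""
    rates = {name: 10 ** rng.uniform(-2, 3) for name in RATE_NAMES}
    rates["k1"] = 10 ** rng.uniform(5, 8)
    return GatingScheme(**rates)


def random_protocol(rng: np.random.Generator, dt: float = 0.01) -> ConcentrationProtocol:
    """Two to four short segments with concentrations spanning 0 to ~1 mM."""
    n_seg = int(rng.integers(2, 5))
    segments = []
    for _ in range(n_seg):
        dur = float(rng.uniform(5 * dt, 0.8))
        conc = 0.0 if rng.random() < 0.3 else 10 ** rng.uniform(-7, -3)
        segments.append((dur, conc))
    return ConcentrationProtocol(segments=tuple(segments), dt=dt)


def ode_simulate(scheme: GatingScheme, protocol: ConcentrationProtocol) -> np.ndarray:
    """Independent oracle: stiff ODE integration of the same master equation.

    Integrates dp/dt = Q^T p segment by segment with LSODA at tight
    tolerances, evaluated on the same output grid as ``simulate``.
    """
    ref = simulate(scheme, protocol)  # only for the output time grid
    times = ref.time
    p = np.zeros(6)
    p[0] = 1.0
    if protocol.initial_condition == "equilibrium":
        from rho1kin import steady_state

        p = steady_state(scheme, protocol.segments[0][1])
    occ = np.empty((len(times), 6))
    t_start = 0.0
    for dur, conc in protocol.segments:
        a = build_generator(scheme, conc).T
        t_end = t_start + dur
        in_seg = (times >= t_start - 1e-12) & (times < t_end - 1e-12)
        t_eval = times[in_seg]
        sol = solve_ivp(
            lambda t, y: a @ y,
            (t_start, t_end),
            p,
            method="LSODA",
            t_eval=np.concatenate([t_eval, [t_end]]),
            rtol=1e-10,
            atol=1e-13,
            jac=lambda t, y: a,
        )
        occ[in_seg] = sol.y[:, :-1].T
        p = sol.y[:, -1]
        t_start = t_end
    # final protocol end point, if sampled
    at_end = np.abs(times - t_start) <= 1e-12
    occ[at_end] = p
    return occ


def max_oracle_difference(n_pairs: int, seed: int = 2024) -> float:
    """Worst-case |simulate - ODE oracle| over random scheme/protocol pairs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        scheme = random_scheme(rng)
        protocol = random_protocol(rng)
        ours = simulate(scheme, protocol).occupancy
        ref = ode_simulate(scheme, protocol)
        worst = max(worst, float(np.max(np.abs(ours - ref))))
    return worst
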