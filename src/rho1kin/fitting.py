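"""Hill concentration-response fits and bi-exponential deactivation fits.

Activation:  I/Imax = 1 / (1 + (EC50/[A])^n)
Inhibition:  I/Imax = 1 - 1 / (1 + (IC50/[B])^n)
Deactivation: I/Imax(%) = -100 + A1 (1 - e^{-t/tau1}) + A2 (1 - e^{-t/tau2}),
              with A1 + A2 = 100 (forced by the -100 offset), i.e. the decay
              -(A1 e^{-t/tau1} + A2 e^{-t/tau2}) from -100 toward 0.

All fits are deterministic multi-start least squares: half-max constants and
time constants are searched in log space from a fixed list of starting
points spanning the data range, and the start with the lowest residual sum
of squares wins.  Standard errors come from the linearized covariance at the
optimum.  The weighted deactivation time constant is the amplitude-weighted
mean (A1 tau1 + A2 tau2) / (A1 + A2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .metrics import CRCData, DeactivationSegment

# stop the multi-start loop early once a start attains an essentially exact
# fit; later starts cannot improve a zero-residual solution
_EXACT_RSS = 1e-16

_XTOL = 1e-12  # relative parameter-change tolerance


class FitError(RuntimeError):
    """Curve fit failed or was called on unusable data."""


def _same_optimum(a, b, rtol: float = 1e-8) -> bool:
    """True when two local fits landed on the same optimum."""
    scale = 1.0 + np.abs(b.x)
    return (
        np.all(np.abs(a.x - b.x) <= rtol * scale)
        and abs(a.cost - b.cost) <= rtol * (1.0 + b.cost)
    )


@dataclass
class HillFit:
    """Result of an activation (EC50) or inhibition (IC50) Hill fit."""

    half_max: float  # molar
    slope: float
    se_half_max: float
    se_slope: float
    rss: float
    mode: str

    def predict(self, conc: np.ndarray) -> np.ndarray:
        return _hill_curve(np.asarray(conc, float), self.half_max, self.slope, self.mode)


@dataclass
class BiExpFit:
    """Constrained bi-exponential deactivation fit (A1 + A2 = 100)."""

    A1: float  # percent
    A2: float  # percent
    tau1: float  # s, tau1 <= tau2
    tau2: float  # s
    weighted_tau: float  # s
    se_A1: float
    se_tau1: float
    se_tau2: float
    rss: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return -(self.A1 * np.exp(-t / self.tau1) + self.A2 * np.exp(-t / self.tau2))


def _hill_curve(conc: np.ndarray, half_max: float, n: float, mode: str) -> np.ndarray:
    frac = 1.0 / (1.0 + (half_max / conc) ** n)
    return frac if mode == "activation" else 1.0 - frac


def _covariance(result, n_obs: int) -> np.ndarray:
    n_par = result.x.size
    dof = max(n_obs - n_par, 1)
    rss = 2.0 * result.cost
    jtj = result.jac.T @ result.jac
    # pinv handles parameters pinned at a bound (singular J^T J); negative
    # diagonal round-off is reported as NaN rather than a warning
    cov = np.linalg.pinv(jtj) * rss / dof
    diag = np.diagonal(cov).copy()
    diag[diag < 0] = np.nan
    cov = cov.copy()
    np.fill_diagonal(cov, diag)
    return cov


def _fit_hill(data: CRCData, mode: str) -> HillFit:
    if data.mode != mode:
        raise FitError(f"expected {mode} data, got mode={data.mode!r}")
    conc = data.concentrations
    y = data.responses
    if conc.size < 4:
        raise FitError(f"Hill fit needs >= 4 points, got {conc.size}")

    lo, hi = conc.min(), conc.max()
    log_bounds = (np.log(lo / 100.0), np.log(hi * 100.0))
    n_bounds = (0.1, 10.0)

    log_conc = np.log(conc)
    sign = 1.0 if mode == "activation" else -1.0

    def residuals(x):
        return _hill_curve(conc, np.exp(x[0]), x[1], mode) - y

    def jacobian(x):
        frac = 1.0 / (1.0 + np.exp(np.clip(x[1] * (x[0] - log_conc), -500, 500)))
        d = frac * (1.0 - frac)
        return sign * np.column_stack([-x[1] * d, -(x[0] - log_conc) * d])

    geo_mean = np.sqrt(lo * hi)
    # data-driven start: concentration closest to half-maximal response
    h_data = conc[int(np.argmin(np.abs(y - 0.5)))]
    starts = [np.log(h_data), np.log(geo_mean)] + list(np.linspace(np.log(lo), np.log(hi), 7))
    best = None
    diagnostics = []
    for logh0 in starts:
        try:
            res = least_squares(
                residuals,
                jac=jacobian,
                x0=[logh0, 1.0],
                bounds=([log_bounds[0], n_bounds[0]], [log_bounds[1], n_bounds[1]]),
                xtol=_XTOL, ftol=1e-14, gtol=1e-14,
            )
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append(f"start {logh0:.3g}: {exc}")
            continue
        if not np.isfinite(res.cost):
            diagnostics.append(f"start {logh0:.3g}: non-finite cost")
            continue
        if best is not None and _same_optimum(res, best):
            best = res if res.cost < best.cost else best
            break  # optimum confirmed from a second basin
        if best is None or res.cost < best.cost:
            best = res
        if 2.0 * best.cost <= _EXACT_RSS:
            break
    if best is None:
        raise FitError("Hill fit failed for all starts: " + "; ".join(diagnostics))

    half_max, slope = float(np.exp(best.x[0])), float(best.x[1])
    cov = _covariance(best, conc.size)
    return HillFit(
        half_max=half_max,
        slope=slope,
        se_half_max=half_max * float(np.sqrt(cov[0, 0])),  # delta method for log-param
        se_slope=float(np.sqrt(cov[1, 1])),
        rss=float(2.0 * best.cost),
        mode=mode,
    )


def fit_hill_activation(data: CRCData) -> HillFit:
    """Fit the activation Hill equation; ``half_max`` is the GABA EC50."""
    return _fit_hill(data, "activation")


def fit_hill_inhibition(data: CRCData) -> HillFit:
    """Fit the inhibition Hill equation; ``half_max`` is the blocker IC50."""
    return _fit_hill(data, "inhibition")


def _biexp_percent(t: np.ndarray, a1: float, tau1: float, tau2: float) -> np.ndarray:
    return -(a1 * np.exp(-t / tau1) + (100.0 - a1) * np.exp(-t / tau2))


def fit_biexponential(seg: DeactivationSegment) -> BiExpFit:
    """Constrained bi-exponential fit of a deactivation segment.

    Components are ordered ``tau1 <= tau2``.  If the two time constants
    degenerate (within 1%), the fit collapses to a mono-exponential with
    ``A1 = 100``.
    """
    t = np.asarray(seg.time, float)
    y = np.asarray(seg.percent_current, float)
    if t.size < 20:
        raise FitError(f"bi-exponential fit needs >= 20 samples, got {t.size}")
    if abs(t[0]) > 1e-12:
        raise FitError("segment must start at t=0 (washout)")
    if abs(y[0] + 100.0) > 1e-6:
        raise FitError(f"segment must start at -100 percent, got {y[0]!r}")

    span = t[-1]
    dt_min = float(np.min(np.diff(t)))
    tau_lo, tau_hi = dt_min, 10.0 * span

    def residuals(x):
        return _biexp_percent(t, x[0], np.exp(x[1]), np.exp(x[2])) - y

    def jacobian(x):
        tau1, tau2 = np.exp(x[1]), np.exp(x[2])
        e1, e2 = np.exp(-t / tau1), np.exp(-t / tau2)
        return np.column_stack([
            -(e1 - e2),
            -x[0] * e1 * t / tau1,
            -(100.0 - x[0]) * e2 * t / tau2,
        ])

    # data-driven start: time of decay to 1/e of the initial amplitude
    below = np.flatnonzero(y >= -100.0 / np.e)
    t_e = t[below[0]] if below.size and below[0] > 0 else span / 10.0
    tau_pairs = [
        (t_e / 3.0, 3.0 * t_e),
        (span / 300.0, span / 30.0),
        (span / 100.0, span / 10.0),
        (span / 30.0, span / 3.0),
        (span / 10.0, span),
    ]
    starts = [
        (a1, np.log(np.clip(p[0], tau_lo, tau_hi)), np.log(np.clip(p[1], tau_lo, tau_hi)))
        for p in tau_pairs
        for a1 in (30.0, 70.0)
    ]
    lb = [0.0, np.log(tau_lo), np.log(tau_lo)]
    ub = [100.0, np.log(tau_hi), np.log(tau_hi)]
    best = None
    diagnostics = []
    for x0 in starts:
        try:
            res = least_squares(residuals, jac=jacobian, x0=list(x0), bounds=(lb, ub),
                                xtol=_XTOL, ftol=1e-14, gtol=1e-14)
        except Exception as exc:  # pragma: no cover - defensive
            diagnostics.append(f"start {x0}: {exc}")
            continue
        if not np.isfinite(res.cost):
            continue
        if best is not None and _same_optimum(res, best):
            best = res if res.cost < best.cost else best
            break  # optimum confirmed from a second basin
        if best is None or res.cost < best.cost:
            best = res
        if 2.0 * best.cost <= _EXACT_RSS * t.size:
            break
    if best is None:
        raise FitError("bi-exponential fit failed for all starts: " + "; ".join(diagnostics))

    a1 = float(best.x[0])
    tau_a, tau_b = float(np.exp(best.x[1])), float(np.exp(best.x[2]))
    cov = _covariance(best, t.size)
    se_a1 = float(np.sqrt(cov[0, 0]))
    se_tau_a = tau_a * float(np.sqrt(cov[1, 1]))
    se_tau_b = tau_b * float(np.sqrt(cov[2, 2]))
    if tau_a > tau_b:
        a1, tau_a, tau_b = 100.0 - a1, tau_b, tau_a
        se_tau_a, se_tau_b = se_tau_b, se_tau_a

    if abs(tau_b - tau_a) <= 0.01 * tau_b:
        return _fit_monoexponential(t, y, tau_guess=tau_b)

    weighted = (a1 * tau_a + (100.0 - a1) * tau_b) / 100.0
    return BiExpFit(
        A1=a1, A2=100.0 - a1, tau1=tau_a, tau2=tau_b, weighted_tau=weighted,
        se_A1=se_a1, se_tau1=se_tau_a, se_tau2=se_tau_b,
        rss=float(2.0 * best.cost),
    )


def _fit_monoexponential(t: np.ndarray, y: np.ndarray, tau_guess: float) -> BiExpFit:
    def residuals(x):
        return -100.0 * np.exp(-t / np.exp(x[0])) - y

    def jacobian(x):
        tau = np.exp(x[0])
        return (-100.0 * np.exp(-t / tau) * t / tau).reshape(-1, 1)

    res = least_squares(residuals, jac=jacobian, x0=[np.log(tau_guess)],
                        xtol=_XTOL, ftol=1e-14, gtol=1e-14)
    tau = float(np.exp(res.x[0]))
    cov = _covariance(res, t.size)
    se_tau = tau * float(np.sqrt(cov[0, 0]))
    return BiExpFit(
        A1=100.0, A2=0.0, tau1=tau, tau2=tau, weighted_tau=tau,
        se_A1=0.0, se_tau1=se_tau, se_tau2=se_tau, rss=float(2.0 * res.cost),
    )


def weighted_tau(a1: float, tau1: float, a2: float, tau2: float) -> float:
    """Amplitude-weighted mean time constant ``(a1 tau1 + a2 tau2)/(a1 + a2)``."""
    return (a1 * tau1 + a2 * tau2) / (a1 + a2)
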