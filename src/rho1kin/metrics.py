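"""Trace-level summary statistics: peak response, desensitization extent,
deactivation segments and model concentration-response curves.

Conventions follow common whole-cell electrophysiology practice: the extent
of desensitization is the fractional loss of current between the peak and a
stated time during a sustained saturating application, expressed in percent
of the peak (0% = no desensitization).  Deactivation is the current decay
after agonist washout, normalized to the current at the moment of washout
and expressed as a negative-going percentage that starts at -100 and relaxes
toward 0, so that bi-exponential fits report amplitudes in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import GatingScheme
from .simulate import ConcentrationProtocol, OccupancyTrace, simulate


class MetricsError(ValueError):
    """Invalid metric request (empty window, zero peak, ...)."""


@dataclass
class DeactivationSegment:
    """Current decay after agonist removal, in the -100 -> 0 percent convention.

    ``time`` is seconds since washout; ``percent_current`` is
    ``-100 * p_open(t) / p_open(0)``, so the segment starts at exactly -100
    and relaxes toward 0 for a decaying current.
    """

    time: np.ndarray
    percent_current: np.ndarray


@dataclass
class CRCData:
    """Concentration-response dataset (normalized response vs concentration)."""

    concentrations: np.ndarray
    responses: np.ndarray
    mode: str  # "activation" | "inhibition"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.mode not in ("activation", "inhibition"):
            raise MetricsError(f"mode must be activation or inhibition, got {self.mode!r}")
        if self.concentrations.shape != self.responses.shape:
            raise MetricsError("concentrations and responses must have equal length")
        if np.any(self.concentrations <= 0):
            raise MetricsError("concentrations must be strictly positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise MetricsError("concentrations must be strictly increasing")


def _window_indices(trace: OccupancyTrace, t0: float, t1: float) -> np.ndarray:
    eps = 0.5 * trace.dt
    idx = np.flatnonzero((trace.time >= t0 - eps) & (trace.time <= t1 + eps))
    if idx.size == 0:
        raise MetricsError(f"window [{t0}, {t1}] contains no trace samples")
    return idx


def peak_response(trace: OccupancyTrace, window: tuple[float, float]) -> tuple[float, float]:
    """Maximum ``p_open`` in the window and the time at which it occurs.

    Ties are broken by the earliest time; the search uses the sampled grid
    without interpolation.
    """
    t0, t1 = window
    if t1 < t0:
        raise MetricsError(f"empty window [{t0}, {t1}]")
    idx = _window_indices(trace, t0, t1)
    p = trace.p_open[idx]
    k = int(np.argmax(p))  # argmax returns the first maximum
    return float(p[k]), float(trace.time[idx[k]])


def desensitization_extent(
    trace: OccupancyTrace, application_start: float, measure_at: float
) -> float:
    """Percent desensitization at ``measure_at`` (absolute trace time).

    ``(1 - residual/peak) * 100`` where the peak is searched between the
    start of the application and the measurement time, and the residual is
    ``p_open`` at the measurement time.  0% means no desensitization.
    """
    if measure_at <= application_start:
        raise MetricsError("measure_at must lie after application_start")
    peak, _ = peak_response(trace, (application_start, measure_at))
    if peak <= 0:
        raise MetricsError("peak response is zero; desensitization undefined")
    k = int(np.argmin(np.abs(trace.time - measure_at)))
    residual = float(trace.p_open[k])
    return (1.0 - residual / peak) * 100.0


def extract_deactivation(trace: OccupancyTrace, washout_start: float) -> DeactivationSegment:
    """Deactivation segment re-zeroed at washout, in percent of the washout current.

    ``washout_start`` must be a sample of the trace at which the current is
    nonzero (normally the boundary where the agonist concentration drops to
    zero).  The first sample of the returned segment is exactly -100.
    """
    k0 = int(np.argmin(np.abs(trace.time - washout_start)))
    if abs(trace.time[k0] - washout_start) > 0.5 * trace.dt:
        raise MetricsError(f"washout_start {washout_start} is not on the trace grid")
    p0 = float(trace.p_open[k0])
    if p0 <= 0:
        raise MetricsError("p_open at washout is zero; deactivation undefined")
    time = trace.time[k0:] - trace.time[k0]
    percent = -100.0 * trace.p_open[k0:] / p0
    return DeactivationSegment(time=time, percent_current=percent)


def crc_from_model(
    scheme: GatingScheme,
    concentrations: np.ndarray,
    application_duration: float = 60.0,
    dt: float = 0.01,
) -> CRCData:
    """Peak-response concentration-response curve of the model.

    For each concentration the receptor is stepped from rest into agonist for
    ``application_duration`` seconds; the peak open probability over the
    application is recorded and all peaks are normalized to their maximum.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
        raise MetricsError("concentrations must be positive and strictly increasing")
    peaks = np.empty(conc.shape)
    for i, c in enumerate(conc):
        protocol = ConcentrationProtocol(
            segments=((application_duration, c),), dt=dt, initial_condition="all-R"
        )
        trace = simulate(scheme, protocol)
        peaks[i], _ = peak_response(trace, (0.0, application_duration))
    pmax = peaks.max()
    if pmax <= 0:
        raise MetricsError("all peak responses are zero; cannot normalize")
    return CRCData(concentrations=conc, responses=peaks / pmax, mode="activation")
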