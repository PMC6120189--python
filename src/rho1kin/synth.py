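"""Synthetic test-data generators: noisy current traces, Hill-shaped
concentration-response datasets, and confocal-like two-channel cell images
with exact ground-truth masks.

Everything is seeded and bit-reproducible.  Noise is additive Gaussian
throughout — adequate for exercising the fitting and quantification
pipeline, without pretending to emulate shot noise, filtering or optics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fitting import _hill_curve
from .metrics import CRCData
from .simulate import OccupancyTrace


class SynthError(ValueError):
    """Invalid synthetic-data parameters."""


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: standard deviation (signal units) and seed."""

    sigma: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise SynthError(f"sigma must be >= 0, got {self.sigma!r}")


def gen_noisy_trace(trace: OccupancyTrace, noise: NoiseSpec) -> OccupancyTrace:
    """Add i.i.d. Gaussian noise to the open-probability channel of a trace.

    The clean state occupancies are retained; only the reported ``p_open``
    carries noise, mimicking an acquired current on top of a known model.
    """
    rng = np.random.default_rng(noise.seed)
    clean = trace.p_open
    noisy = clean + rng.normal(0.0, noise.sigma, size=clean.shape) if noise.sigma > 0 else clean.copy()
    metadata = dict(trace.metadata)
    metadata.update({"noise_sigma": noise.sigma, "noise_seed": noise.seed})
    return OccupancyTrace(
        time=trace.time.copy(),
        occupancy=trace.occupancy.copy(),
        metadata=metadata,
        _p_open=noisy,
    )


def gen_hill_dataset(
    half_max: float,
    n: float,
    concentrations: np.ndarray,
    mode: str = "activation",
    noise: NoiseSpec = NoiseSpec(0.0),
) -> CRCData:
    """Concentration-response dataset drawn from the Hill equation plus noise.

    Responses are not clamped to [0, 1]; fits must tolerate small excursions.
    """
    if half_max <= 0 or n <= 0:
        raise SynthError("half_max and n must be > 0")
    conc = np.asarray(concentrations, dtype=float)
    y = _hill_curve(conc, half_max, n, mode)
    if noise.sigma > 0:
        rng = np.random.default_rng(noise.seed)
        y = y + rng.normal(0.0, noise.sigma, size=y.shape)
    return CRCData(concentrations=conc, responses=y, mode=mode)


@dataclass(frozen=True)
class ImageParams:
    """Geometry and intensities of the synthetic two-channel cell image.

    The scene is a single disk-shaped cell on a uniform background.  The
    marker channel (a cytoplasmic fill such as eGFP) is bright over the whole
    cell; the label channel (surface receptor stain) has a bright membrane
    ring of ``ring_width`` pixels just inside the cell edge, a diffuse
    intracellular level, and a uniform background outside the cell.
    """

    shape: tuple[int, int] = (256, 256)
    center: tuple[float, float] | None = None  # defaults to the frame center
    radius: float = 60.0
    ring_width: float = 4.0
    membrane_intensity: float = 1000.0
    interior_intensity: float = 300.0
    background_intensity: float = 200.0
    marker_cell_intensity: float = 500.0
    marker_background_intensity: float = 50.0
    sigma: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "membrane_intensity", "interior_intensity", "background_intensity",
            "marker_cell_intensity", "marker_background_intensity",
        ):
            if getattr(self, name) < 0:
                raise SynthError(f"{name} must be >= 0")
        if self.radius <= 0 or not 0 < self.ring_width < self.radius:
            raise SynthError("need 0 < ring_width < radius")
        if self.sigma < 0:
            raise SynthError("sigma must be >= 0")
        cy, cx = self.center if self.center is not None else (
            (self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0
        )
        object.__setattr__(self, "center", (float(cy), float(cx)))
        h, w = self.shape
        if not (
            self.radius <= cy <= h - 1 - self.radius
            and self.radius <= cx <= w - 1 - self.radius
        ):
            raise SynthError("cell geometry exceeds the image frame")


@dataclass
class SyntheticImage:
    """Two-channel synthetic image with exact ground-truth masks.

    ``pixels`` has shape (2, H, W): channel 0 is the cell marker, channel 1
    the receptor label.  The three masks partition the frame.
    """

    pixels: np.ndarray
    membrane_mask: np.ndarray
    interior_mask: np.ndarray
    background_mask: np.ndarray
    params: ImageParams
    seed: int

    @property
    def marker(self) -> np.ndarray:
        return self.pixels[0]

    @property
    def label(self) -> np.ndarray:
        return self.pixels[1]


def gen_image(params: ImageParams = ImageParams(), seed: int = 0) -> SyntheticImage:
    """Render the synthetic cell image described by ``params``.

    Masks are computed on exact pixel-center distances: a pixel belongs to
    the membrane ring iff ``radius - ring_width < r <= radius``, to the
    interior iff ``r <= radius - ring_width``, and to the background
    otherwise, so the three masks are disjoint and exhaustive.
    """
    h, w = params.shape
    cy, cx = params.center
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - cy, xx - cx)
    cell = r <= params.radius
    membrane = cell & (r > params.radius - params.ring_width)
    interior = cell & ~membrane
    background = ~cell

    label = np.full((h, w), params.background_intensity, dtype=float)
    label[interior] = params.interior_intensity
    label[membrane] = params.membrane_intensity
    marker = np.full((h, w), params.marker_background_intensity, dtype=float)
    marker[cell] = params.marker_cell_intensity

    pixels = np.stack([marker, label])
    if params.sigma > 0:
        rng = np.random.default_rng(seed)
        pixels = pixels + rng.normal(0.0, params.sigma, size=pixels.shape)
    return SyntheticImage(
        pixels=pixels,
        membrane_mask=membrane,
        interior_mask=interior,
        background_mask=background,
        params=params,
        seed=seed,
    )
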